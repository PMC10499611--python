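"""Seeded generator of complete synthetic screens with planted ground truth.

Every downstream stage of the readout can be exercised without any real
data: the generator emits cell metadata with planted compositional
effects, clone structure with log-normally sized clones, amplicon reads
(guide + clone-barcode inserts between the real extraction anchors, with
substitution errors and planted equal-UMI doublets), negative-binomial
expression with planted fold changes, per-pool guide representation
fractions, and Dirichlet fate-probability matrices with a planted fate
bias. All randomness flows from one integer seed through numpy
Generators, so identical seeds give identical screens.

Defaults mirror the screen design they emulate: 36 targeted genes plus a
non-targeting control spiked in at 4% (a 96:4 mix), libraries of a few
thousand cells pooled over two batches, and clones of highly variable
(log-normal) size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as msio
from .amplicon import (
    DEFAULT_GRNA_FLANK3,
    DEFAULT_GRNA_FLANK5,
    DEFAULT_UCB_FLANK3,
    DEFAULT_UCB_FLANK5,
    DEFAULT_UCB_PATTERN,
    GuideLibrary,
    IUPAC,
)
from .model import (
    CONTROL_LABEL,
    DEFAULT_TRAJECTORY_MAP,
    ExpressionMatrix,
)

__all__ = [
    "ScreenConfig",
    "TruthTable",
    "default_composition",
    "make_guide_library",
    "simulate_cells",
    "simulate_reads",
    "simulate_expression",
    "simulate_fates",
    "simulate_representation",
    "simulate_screen",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_composition() -> dict[str, float]:
    """Baseline cell-type composition of a telencephalon organoid pool."""
    return {
        "RGC": 0.14, "ccRGC": 0.06, "oRGC": 0.05, "IPC": 0.08,
        "L5/6": 0.10, "CThPN": 0.05, "L4": 0.07, "L2/3": 0.12,
        "v-RGC": 0.07, "ccv-RGC": 0.04, "INP": 0.07, "LGE-IN": 0.06,
        "CGE-IN": 0.04, "LGE PAX6+ IN": 0.02, "astrocyte": 0.02, "OPC": 0.01,
    }


@dataclass(frozen=True)
class ScreenConfig:
    """Study conditions of one synthetic screen."""

    seed: int
    n_libraries: int = 6
    n_batches: int = 2
    cells_per_library: int = 2000
    n_grnas: int = 36
    control_fraction: float = 0.04
    composition: dict[str, float] = field(default_factory=default_composition)
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    clone_size_log_mean: float = 1.0
    clone_size_log_sd: float = 0.8
    umis_per_cell_mean: float = 4.0
    reads_per_umi_mean: float = 20.0
    substitution_rate: float = 0.01
    doublet_fraction: float = 0.02
    ucb_pattern: str = DEFAULT_UCB_PATTERN
    spacer_length: int = 20

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"composition sums to {total}, expected 1")
        if not 0 <= self.control_fraction < 1:
            raise ValueError("control_fraction must lie in [0, 1)")
        for grna, ctype, shift in self.planted_effects:
            if ctype not in self.composition:
                raise ValueError(f"planted effect on unknown cell type {ctype}")
            if not np.isfinite(shift):
                raise ValueError("planted log-odds shifts must be finite")

    @property
    def grna_labels(self) -> list[str]:
        return [f"g{i + 1:02d}" for i in range(self.n_grnas)]


@dataclass
class TruthTable:
    """Planted ground truth backing a simulated screen."""

    cell_grna: pd.Series            # cell_id -> true guide label
    cell_ucb: pd.Series             # cell_id -> true clone barcode
    doublet_cells: set[str]         # cells carrying a planted second guide
    doublet_partner: dict[str, str]  # doublet cell -> second guide label
    planted_effects: pd.DataFrame   # grna, cell_type, log_odds


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _sample_pattern(rng: np.random.Generator, pattern: str) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)


def make_guide_library(config: ScreenConfig,
                       rng: np.random.Generator) -> GuideLibrary:
    """Random spacer pairs for every guide label plus the control."""
    spacers: dict[str, tuple[str, str]] = {}
    seen: set[str] = set()
    for label in config.grna_labels + [CONTROL_LABEL]:
        pair = []
        while len(pair) < 2:
            sp = _random_seq(rng, config.spacer_length)
            if sp not in seen:
                seen.add(sp)
                pair.append(sp)
        spacers[label] = tuple(pair)
    return GuideLibrary(
        spacers=spacers,
        control_labels=frozenset({CONTROL_LABEL}),
        ucb_pattern=config.ucb_pattern,
    )


def _assign_clones(
    cells: pd.DataFrame,
    config: ScreenConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Partition each guide's cells into log-normally sized clones."""
    ucb = pd.Series(index=cells.index, dtype=object)
    used: set[str] = set()
    for _, idx in cells.groupby("grna_label", sort=False).groups.items():
        idx = list(idx)
        rng.shuffle(idx)
        pos = 0
        while pos < len(idx):
            size = max(1, int(round(rng.lognormal(
                config.clone_size_log_mean, config.clone_size_log_sd))))
            size = min(size, len(idx) - pos)
            bc = _sample_pattern(rng, config.ucb_pattern)
            while bc in used:
                bc = _sample_pattern(rng, config.ucb_pattern)
            used.add(bc)
            ucb.loc[idx[pos:pos + size]] = bc
            pos += size
    return ucb


def simulate_cells(config: ScreenConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Cell metadata with planted compositional effects and clone labels.

    Guides are assigned uniformly (control at ``control_fraction``); each
    cell's type is drawn from the baseline composition with the planted
    per-guide log-odds shifts applied on the logit scale, so a planted
    shift delta multiplies the odds of the shifted type by exp(delta)
    exactly. Libraries are split evenly across batches.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_libraries * config.cells_per_library
    labels = config.grna_labels
    p_guide = np.full(len(labels), (1.0 - config.control_fraction) / len(labels))
    p = np.concatenate([p_guide, [config.control_fraction]])
    all_labels = labels + [CONTROL_LABEL]
    guide_idx = rng.choice(len(all_labels), size=n, p=p)
    grna = np.array(all_labels, dtype=object)[guide_idx]

    types = list(config.composition)
    base_logit = np.log(np.array([config.composition[t] for t in types]))
    shift_lookup: dict[str, np.ndarray] = {}
    for g, ctype, delta in config.planted_effects:
        shifts = shift_lookup.setdefault(g, np.zeros(len(types)))
        shifts[types.index(ctype)] += delta

    cell_type = np.empty(n, dtype=object)
    for g in np.unique(grna):
        mask = grna == g
        logits = base_logit + shift_lookup.get(g, 0.0)
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        cell_type[mask] = rng.choice(types, size=int(mask.sum()), p=probs)

    library = np.repeat(
        [f"lib{i + 1}" for i in range(config.n_libraries)],
        config.cells_per_library,
    )
    lib_to_batch = {
        f"lib{i + 1}": f"batch{i % config.n_batches + 1}"
        for i in range(config.n_libraries)
    }
    meta = pd.DataFrame({
        "cell_id": [f"cell{i:06d}" for i in range(n)],
        "library_id": library,
        "batch_id": [lib_to_batch[lb] for lb in library],
        "induced": True,
        "cell_type": cell_type,
        "trajectory": [DEFAULT_TRAJECTORY_MAP[t] for t in cell_type],
        "grna_label": grna,
    })
    ucb = _assign_clones(meta, config, rng)
    truth = TruthTable(
        cell_grna=pd.Series(grna, index=meta["cell_id"].to_numpy()),
        cell_ucb=pd.Series(ucb.to_numpy(), index=meta["cell_id"].to_numpy()),
        doublet_cells=set(),
        doublet_partner={},
        planted_effects=pd.DataFrame(
            list(config.planted_effects),
            columns=["grna", "cell_type", "log_odds"],
        ),
    )
    return meta, truth


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for i in rng.choice(arr.size, size=min(n_subs, arr.size), replace=False):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _emit_umi(
    rng: np.random.Generator,
    rows: list,
    cell: str,
    seq: str,
    rate: float,
    reads_mean: float,
) -> None:
    """Emit the read records of one UMI.

    Substitution errors are per sequenced read: reads split into an
    error-free record and (collapsed) one mutated variant record, so a
    molecule is essentially never lost wholesale — mirroring how
    per-read errors wash out at realistic read depth.
    """
    umi = _random_seq(rng, 12)
    reads = 1 + rng.poisson(reads_mean - 1.0)
    if rate <= 0:
        rows.append((cell, umi, seq, int(reads)))
        return
    p_clean = (1.0 - rate) ** len(seq)
    r_clean = int(rng.binomial(reads, p_clean))
    if r_clean:
        rows.append((cell, umi, seq, r_clean))
    if reads - r_clean:
        n_subs = max(1, int(rng.binomial(len(seq), rate)))
        rows.append((cell, umi, _mutate(rng, seq, n_subs), int(reads - r_clean)))


def simulate_reads(
    meta: pd.DataFrame,
    truth: TruthTable,
    config: ScreenConfig,
    library: GuideLibrary,
) -> pd.DataFrame:
    """Amplicon read table (cbc, umi, seq, reads) for a simulated screen.

    Per cell, guide UMIs carry one of the cell's two spacers between the
    guide flanks and UCB UMIs carry the clone barcode between the UCB
    flanks; substitution errors hit each emitted molecule at the
    configured per-base rate. A ``doublet_fraction`` of cells receives a
    second guide at exactly the same UMI count (planted ambiguity —
    these must be removed by the one-to-one rule). ``truth`` is updated
    in place with the planted doublets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    labels = list(library.spacers)
    rows: list[tuple[str, str, str, int]] = []
    is_doublet = rng.random(len(meta)) < config.doublet_fraction

    for pos, (cell, grna, ucb) in enumerate(zip(
        meta["cell_id"], meta["grna_label"], truth.cell_ucb.to_numpy()
    )):
        n_umi = 1 + rng.poisson(config.umis_per_cell_mean - 1.0)
        guides = [grna]
        if is_doublet[pos]:
            other = labels[rng.integers(0, len(labels))]
            while other == grna:
                other = labels[rng.integers(0, len(labels))]
            guides.append(other)
            truth.doublet_cells.add(cell)
            truth.doublet_partner[cell] = other
        for g in guides:
            pair = library.spacers[g]
            for _ in range(n_umi):
                spacer = pair[rng.integers(0, 2)]
                insert = library.flank5 + spacer + library.flank3
                seq = _random_seq(rng, 4) + insert + _random_seq(rng, 4)
                _emit_umi(rng, rows, cell, seq, config.substitution_rate,
                          config.reads_per_umi_mean)
        n_umi_ucb = 1 + rng.poisson(config.umis_per_cell_mean - 1.0)
        for _ in range(n_umi_ucb):
            insert = library.ucb_flank5 + ucb + library.ucb_flank3
            seq = _random_seq(rng, 4) + insert + _random_seq(rng, 4)
            _emit_umi(rng, rows, cell, seq, config.substitution_rate,
                      config.reads_per_umi_mean)
    return pd.DataFrame(rows, columns=["cbc", "umi", "seq", "reads"])


def simulate_expression(
    meta: pd.DataFrame,
    n_genes: int = 200,
    planted_effects: tuple[tuple[str, str, float], ...] = (),
    mean_depth: float = 5000.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> ExpressionMatrix:
    """Negative-binomial counts with planted per-gene fold changes.

    ``planted_effects`` entries are (guide label, gene name, log2 fold
    change) applied to cells carrying that guide. Counts are drawn as
    gamma-Poisson with per-cell log-normal size factors, then
    log-normalized to 10,000 counts per cell; genes are named
    ``G0001``... and per-cell totals are recorded as n_UMI.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    n = len(meta)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gidx = {g: i for i, g in enumerate(genes)}
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    base /= base.sum()
    sf = rng.lognormal(np.log(mean_depth), 0.3, size=n)

    fc = np.ones((n, n_genes))
    grna = meta["grna_label"].to_numpy()
    for label, gene, log2fc in planted_effects:
        fc[grna == label, gidx[gene]] = 2.0 ** log2fc
    mu = sf[:, None] * base[None, :] * fc
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)
    n_umi = counts.sum(axis=1)
    n_umi = np.maximum(n_umi, 1)
    X = np.log1p(counts / n_umi[:, None] * 1e4)
    return ExpressionMatrix(
        X=X, genes=genes, cells=meta["cell_id"].tolist(), n_umi=n_umi,
    )


def simulate_fates(
    meta: pd.DataFrame,
    states: tuple[str, ...] = ("OPC", "LGE-IN", "CGE-IN", "INP"),
    shifted_grna: str | None = None,
    shifted_state: str | None = None,
    concentration: float = 1.0,
    shift: float = 3.0,
    embedding_noise: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Dirichlet fate-probability rows with an optional planted fate bias.

    Cells carrying ``shifted_grna`` get their Dirichlet concentration for
    ``shifted_state`` raised by ``shift``, pushing probability mass — and
    hence the circular projection — toward that terminal state. The
    returned embedding is fate space plus Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    n = len(meta)
    alpha = np.full((n, len(states)), concentration)
    if shifted_grna is not None:
        if shifted_state not in states:
            raise ValueError(f"{shifted_state!r} not in states")
        mask = (meta["grna_label"] == shifted_grna).to_numpy()
        alpha[mask, states.index(shifted_state)] += shift
    gams = rng.gamma(alpha)
    F = gams / gams.sum(axis=1, keepdims=True)
    fates = pd.DataFrame(F, index=pd.Index(meta["cell_id"], name="cell_id"),
                         columns=list(states))
    embedding = F + rng.normal(0.0, embedding_noise, size=F.shape)
    return fates, embedding


def simulate_representation(
    n_induced: int = 14,
    n_uninduced: int = 8,
    labels: tuple[str, ...] | None = None,
    fold_changes: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pool guide detection fractions with planted representation shifts.

    Uninduced pools sample around the uniform library composition;
    induced pools multiply each guide's expected fraction by its planted
    fold change (default 1) before renormalization. Log-normal
    multiplicative noise models pool-to-pool variability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    if labels is None:
        labels = tuple(f"g{i + 1:02d}" for i in range(36))
    fold_changes = fold_changes or {}
    base = np.full(len(labels), 1.0 / len(labels))
    rows = []
    for s in range(n_induced + n_uninduced):
        induced = s < n_induced
        expect = base.copy()
        if induced:
            for g, f in fold_changes.items():
                expect[labels.index(g)] *= f
        noisy = expect * rng.lognormal(0.0, noise_sd, size=len(labels))
        noisy /= noisy.sum()
        sample_id = f"{'ind' if induced else 'unind'}{s + 1}"
        rows.extend(
            (sample_id, induced, g, float(fr))
            for g, fr in zip(labels, noisy)
        )
    return pd.DataFrame(rows, columns=["sample_id", "induced", "grna", "fraction"])


def simulate_screen(config: ScreenConfig, outdir) -> dict[str, str]:
    """Emit a complete synthetic screen as plain-text files.

    Writes cell metadata, truth, whitelist, amplicon FASTQ + read table,
    expression (MTX + sidecars), and a fate matrix; returns the file
    paths. Every file round-trips through the package's own readers.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    meta, truth = simulate_cells(config)
    library = make_guide_library(config, rng)
    reads = simulate_reads(meta, truth, config, library)
    expr = simulate_expression(meta, seed=config.seed)
    fates, _ = simulate_fates(meta, seed=config.seed)

    paths = {
        "meta": outdir / "meta.tsv",
        "truth": outdir / "truth.tsv",
        "whitelist": outdir / "whitelist.tsv",
        "reads": outdir / "reads.tsv",
        "fastq": outdir / "reads.fastq",
        "mtx": outdir / "expression.mtx",
        "genes": outdir / "genes.tsv",
        "cells": outdir / "cells.tsv",
        "n_umi": outdir / "n_umi.tsv",
        "fates": outdir / "fates.tsv",
    }
    msio.write_cell_meta(meta, paths["meta"])
    truth_df = pd.DataFrame({
        "cell_id": truth.cell_grna.index,
        "true_grna": truth.cell_grna.to_numpy(),
        "true_ucb": truth.cell_ucb.to_numpy(),
        "is_doublet": [c in truth.doublet_cells for c in truth.cell_grna.index],
    })
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    msio.write_whitelist(library.to_whitelist(), paths["whitelist"])
    msio.write_read_table(reads, paths["reads"])
    msio.write_fastq_reads(reads, paths["fastq"])
    msio.write_expression_mtx(expr, paths["mtx"], paths["genes"],
                              paths["cells"], paths["n_umi"])
    msio.write_fate_matrix(fates, paths["fates"])
    return {k: str(v) for k, v in paths.items()}
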