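"""Guide-RNA and clone-barcode recovery from amplicon reads.

The screen encodes each perturbation as a dual-sgRNA cassette and each
lentiviral integration (clone) as a degenerate unique clone barcode (UCB)
carried on the same cassette. Both are read out from targeted amplicon
sequencing of the single-cell cDNA library. Recovery runs a fixed filter
cascade per insert type:

1. extract the insert between 5'/3' flanking anchors (substitution-only
   matching, 10% error rate, partial overlap at read ends allowed);
2. length filter (guides 15-21 nt; UCBs exactly 12 nt matching the IUPAC
   synthesis pattern);
3. whitelist matching for guides (Hamming distance <= 2, partial
   overlaps, ambiguous hits discarded);
4. a read-count cutoff of 1% of the median (across cells) of the read
   count of each cell's highest-read UMI;
5. within each cell-barcode/UMI group, only entries with more than 20% of
   the group's maximal read count are kept;
6. UMIs are counted per cell and label; only labels tied at the maximal
   UMI count survive, and a cell is assigned only when exactly one label
   survives with more than one supporting read (one-to-one rule).

Cells failing the one-to-one rule are reported as ambiguous; guide and
UCB cascades run independently and are joined at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GuideLibrary",
    "DEFAULT_GRNA_FLANK5",
    "DEFAULT_GRNA_FLANK3",
    "DEFAULT_UCB_FLANK5",
    "DEFAULT_UCB_FLANK3",
    "DEFAULT_UCB_PATTERN",
    "extract_insert",
    "length_filter",
    "matches_iupac",
    "match_whitelist",
    "apply_read_filters",
    "call_cell_assignments",
    "resolve_ucb",
    "assign_screen",
    "clone_stats",
]

# Extraction anchors. The guide flanks are the U6 priming region and the
# invariant sgRNA scaffold head; the UCB flanks come from the barcoded
# amplification primer (AscI site upstream, vector sequence downstream).
DEFAULT_GRNA_FLANK5 = "TGGAAAGGACGAAACACCG"
DEFAULT_GRNA_FLANK3 = "GTTTTAGAGCTAGAAATAGC"
DEFAULT_UCB_FLANK5 = "CAGTAGGGCGCGCC"
DEFAULT_UCB_FLANK3 = "CCGGCGAACCATGATCAAA"
DEFAULT_UCB_PATTERN = "NVDNHBNVDNHB"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class GuideLibrary:
    """Guide whitelist plus the sequences that anchor insert extraction."""

    spacers: dict[str, tuple[str, str]]  # gene label -> (spacer1, spacer2)
    control_labels: frozenset[str] = frozenset()
    flank5: str = DEFAULT_GRNA_FLANK5
    flank3: str = DEFAULT_GRNA_FLANK3
    ucb_flank5: str = DEFAULT_UCB_FLANK5
    ucb_flank3: str = DEFAULT_UCB_FLANK3
    ucb_pattern: str = DEFAULT_UCB_PATTERN

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, pair in self.spacers.items():
            for sp in pair:
                if sp in seen and seen[sp] != label:
                    raise ValueError(
                        f"spacer {sp} shared by labels {seen[sp]} and {label}"
                    )
                seen[sp] = label
        bad = set(self.ucb_pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"UCB pattern has non-IUPAC codes: {sorted(bad)}")
        overlap = set(self.control_labels) & (
            set(self.spacers) - set(self.control_labels)
        )
        if overlap:
            raise ValueError(f"control labels overlap gene labels: {overlap}")

    @classmethod
    def from_whitelist(cls, whitelist: pd.DataFrame, **kwargs) -> "GuideLibrary":
        spacers = {
            str(r.gene): (str(r.spacer1), str(r.spacer2))
            for r in whitelist.itertuples(index=False)
        }
        controls = frozenset(
            str(r.gene) for r in whitelist.itertuples(index=False) if r.is_control
        )
        return cls(spacers=spacers, control_labels=controls, **kwargs)

    def to_whitelist(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (label, s1, s2, label in self.control_labels)
                for label, (s1, s2) in self.spacers.items()
            ],
            columns=["gene", "spacer1", "spacer2", "is_control"],
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_flank(
    read: np.ndarray,
    flank: np.ndarray,
    max_error_rate: float,
    min_overlap: int,
) -> tuple[int, int] | None:
    """Best substitution-only match of ``flank`` inside/overhanging ``read``.

    Returns ``(start, end)`` positions of the matched region within the
    read, or None. Partial overlaps at either read end down to
    ``min_overlap`` nt are allowed; mismatches must not exceed
    floor(max_error_rate * overlap length). Best match maximizes overlap
    length, then minimizes mismatches, then takes the leftmost position.
    """
    R, L = read.size, flank.size
    best = None  # (overlap, -mismatches, -start)
    # full-length placements, vectorized over all interior offsets
    if R >= L:
        windows = np.lib.stride_tricks.sliding_window_view(read, L)
        mism = (windows != flank).sum(axis=1)
        allowed = int(max_error_rate * L)
        hits = np.flatnonzero(mism <= allowed)
        if hits.size:
            i = int(hits[np.argmin(mism[hits])])  # first minimum = leftmost tie
            best = (L, -int(mism[i]), -i, i, i + L)
    # partial overlap hanging off the left end (flank suffix vs read prefix)
    for ov in range(min_overlap, min(L, R)):
        if (read[:ov] != flank[L - ov:]).sum() <= int(max_error_rate * ov):
            m = int((read[:ov] != flank[L - ov:]).sum())
            cand = (ov, -m, 0, 0, ov)
            if best is None or cand[:3] > best[:3]:
                best = cand
    # partial overlap hanging off the right end (flank prefix vs read suffix)
    for ov in range(min_overlap, min(L, R)):
        s = R - ov
        if (read[s:] != flank[:ov]).sum() <= int(max_error_rate * ov):
            m = int((read[s:] != flank[:ov]).sum())
            cand = (ov, -m, -s, s, R)
            if best is None or cand[:3] > best[:3]:
                best = cand
    if best is None:
        return None
    return best[3], best[4]


def extract_insert(
    seq: str,
    flank5: str,
    flank3: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
    max_overlap_probe: int | None = None,
) -> str | None:
    """Extract the insert between two flanking anchors, or None.

    Substitution-only matching (no indels): each flank may match anywhere
    in the read, or partially at a read end down to ``min_overlap`` nt
    (``max_overlap_probe`` caps the partial-overlap probing length; by
    default the full flank length is probed). Mismatches are limited to
    floor(max_error_rate x matched length). Returns the subsequence
    between the 5' flank's end and the 3' flank's start; None when either
    flank cannot be located or the matches overlap each other.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must lie in [0, 0.5)")
    read = _encode(seq)
    probe5 = _encode(flank5)
    probe3 = _encode(flank3)
    if max_overlap_probe is not None:
        # cap anchor length: only the insert-proximal part of each flank
        # is probed (5' flank: suffix; 3' flank: prefix)
        probe5 = probe5[-max_overlap_probe:]
        probe3 = probe3[:max_overlap_probe]
    m5 = _match_flank(read, probe5, max_error_rate, min_overlap)
    if m5 is None:
        return None
    m3 = _match_flank(read[m5[1]:], probe3, max_error_rate, min_overlap)
    if m3 is None:
        return None
    start = m5[1]
    end = m5[1] + m3[0]
    return seq[start:end]


def matches_iupac(seq: str, pattern: str) -> bool:
    """Position-wise membership of ``seq`` in an IUPAC degenerate pattern."""
    if len(seq) != len(pattern):
        return False
    return all(base in IUPAC[code] for base, code in zip(seq, pattern))


def length_filter(seq: str, kind: str,
                  ucb_pattern: str = DEFAULT_UCB_PATTERN) -> bool:
    """Insert length gate: guides 15-21 nt, UCBs 12 nt + synthesis pattern."""
    if not seq:
        raise ValueError("seq must be non-empty")
    if kind == "grna":
        return 15 <= len(seq) <= 21
    if kind == "ucb":
        return len(seq) == len(ucb_pattern) and matches_iupac(seq, ucb_pattern)
    raise ValueError(f"unknown insert kind: {kind!r}")


def _match_whitelist_batch(
    seqs: list[str],
    library: GuideLibrary,
    max_hamming: int = 2,
) -> tuple[list[str | None], int]:
    """Vectorized whitelist matching; returns labels and ambiguity count.

    The shorter of (insert, spacer) slides over the longer requiring an
    aligned window of at least len(shorter) - 2; distance is counted over
    the window. The unique best label within ``max_hamming`` wins; a tie
    between two labels at the best distance is ambiguous (None, counted).
    """
    spacer_list = [
        (label, _encode(sp))
        for label, pair in library.spacers.items()
        for sp in pair
    ]
    labels_out: list[str | None] = [None] * len(seqs)
    ambiguous = 0

    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)

    for L, idxs in by_len.items():
        if L == 0:
            continue
        arr = np.empty((len(idxs), L), dtype=np.uint8)
        for row, i in enumerate(idxs):
            arr[row] = _encode(seqs[i])
        # best distance per (insert, label)
        n_labels = len(library.spacers)
        label_names = list(library.spacers)
        label_pos = {name: j for j, name in enumerate(label_names)}
        best = np.full((len(idxs), n_labels), np.inf)
        for label, sp in spacer_list:
            S = sp.size
            min_ov = max(min(L, S) - 2, 1)
            dists = np.full(len(idxs), np.inf)
            # offset t: insert position i aligns with spacer position i + t
            for t in range(-(L - min_ov), S - min_ov + 1):
                lo = max(0, -t)
                hi = min(L, S - t)
                if hi - lo < min_ov:
                    continue
                d = (arr[:, lo:hi] != sp[lo + t:hi + t]).sum(axis=1)
                dists = np.minimum(dists, d)
            j = label_pos[label]
            best[:, j] = np.minimum(best[:, j], dists)
        finite = best <= max_hamming
        for row, i in enumerate(idxs):
            cand = np.flatnonzero(finite[row])
            if cand.size == 0:
                continue
            d = best[row, cand]
            winners = cand[d == d.min()]
            if winners.size == 1:
                labels_out[i] = label_names[int(winners[0])]
            else:
                ambiguous += 1
    return labels_out, ambiguous


def match_whitelist(
    seq: str,
    library: GuideLibrary,
    max_hamming: int = 2,
    counters: dict | None = None,
) -> str | None:
    """Match one insert against the guide whitelist (see batch docstring)."""
    labels, ambiguous = _match_whitelist_batch([seq], library, max_hamming)
    if counters is not None:
        counters["ambiguous"] = counters.get("ambiguous", 0) + ambiguous
    return labels[0]


def apply_read_filters(
    counts: pd.DataFrame,
    cutoff_fraction: float = 0.01,
    within_umi_fraction: float = 0.2,
) -> pd.DataFrame:
    """Read-support filters on (cbc, umi, label, reads) count entries.

    1. Per cell, take the read count of its highest-count UMI (reads
       summed within a cbc-umi pair); the global cutoff is
       ``cutoff_fraction`` times the median of these per-cell maxima, and
       entries with reads <= cutoff are dropped.
    2. Within each surviving cbc-umi group, labels with reads <=
       ``within_umi_fraction`` x the group's maximal read count are
       dropped.
    """
    required = {"cbc", "umi", "label", "reads"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    if counts.empty:
        import warnings

        warnings.warn("apply_read_filters: empty input", stacklevel=2)
        return counts.copy()
    umi_reads = counts.groupby(["cbc", "umi"], sort=False)["reads"].transform("sum")
    per_umi = counts.assign(_umi_reads=umi_reads)
    cell_max = (
        per_umi.groupby(["cbc", "umi"], sort=False)["_umi_reads"]
        .first()
        .groupby("cbc", sort=False)
        .max()
    )
    cutoff = cutoff_fraction * float(np.median(cell_max.to_numpy()))
    kept = counts[counts["reads"] > cutoff].copy()
    if kept.empty:
        return kept
    group_max = kept.groupby(["cbc", "umi"], sort=False)["reads"].transform("max")
    kept = kept[kept["reads"] > within_umi_fraction * group_max]
    return kept.reset_index(drop=True)


def call_cell_assignments(filtered: pd.DataFrame) -> pd.DataFrame:
    """Resolve one label per cell from filtered counts (one-to-one rule).

    UMIs are counted per (cbc, label); only labels tied at the cell's
    maximal UMI count are retained. A cell is ``assigned`` when exactly
    one label is retained and that label has more than one supporting
    read in at least one UMI (labels seen only as single-read molecules
    are treated as noise and left unassigned); ``ambiguous`` when
    several labels tie; ``unassigned`` otherwise.
    """
    if filtered.empty:
        return pd.DataFrame(
            columns=["cbc", "label", "umi_count", "read_count", "status"]
        )
    per_umi = (
        filtered.groupby(["cbc", "label", "umi"], sort=False)["reads"]
        .sum()
        .reset_index()
    )
    per_label = (
        per_umi.groupby(["cbc", "label"], sort=False)
        .agg(umi_count=("umi", "nunique"), read_count=("reads", "sum"),
             max_umi_reads=("reads", "max"))
        .reset_index()
    )
    max_umis = per_label.groupby("cbc", sort=False)["umi_count"].transform("max")
    top = per_label[per_label["umi_count"] == max_umis]
    n_top = top.groupby("cbc", sort=False)["label"].transform("size")

    rows = []
    for cbc, group in top.groupby("cbc", sort=False):
        if len(group) > 1:
            rows.append((cbc, np.nan, 0, 0, "ambiguous"))
        else:
            r = group.iloc[0]
            if r.max_umi_reads > 1:
                rows.append((cbc, r.label, int(r.umi_count),
                             int(r.read_count), "assigned"))
            else:
                rows.append((cbc, np.nan, 0, 0, "unassigned"))
    return pd.DataFrame(
        rows, columns=["cbc", "label", "umi_count", "read_count", "status"]
    )


def _extract_batch(
    seqs: pd.Series,
    flank5: str,
    flank3: str,
    max_error_rate: float,
    min_overlap: int,
) -> pd.Series:
    uniq = seqs.drop_duplicates()
    mapping = {
        s: extract_insert(s, flank5, flank3, max_error_rate, min_overlap)
        for s in uniq
    }
    return seqs.map(mapping)


def _guide_counts(
    reads: pd.DataFrame,
    library: GuideLibrary,
    max_error_rate: float,
    min_overlap: int,
    max_hamming: int,
    counters: dict,
) -> pd.DataFrame:
    inserts = _extract_batch(
        reads["seq"], library.flank5, library.flank3, max_error_rate, min_overlap
    )
    ok = inserts.map(
        lambda s: isinstance(s, str) and bool(s) and length_filter(s, "grna")
    ).to_numpy(dtype=bool)
    sub = reads[ok].copy()
    sub["insert"] = inserts[ok]
    uniq = sub["insert"].drop_duplicates().tolist()
    labels, ambiguous = _match_whitelist_batch(uniq, library, max_hamming)
    counters["whitelist_ambiguous"] = ambiguous
    label_map = dict(zip(uniq, labels))
    sub["label"] = sub["insert"].map(label_map)
    sub = sub[sub["label"].notna()]
    return (
        sub.groupby(["cbc", "umi", "label"], sort=False)["reads"]
        .sum()
        .reset_index()
    )


def _ucb_counts(
    reads: pd.DataFrame,
    library: GuideLibrary,
    max_error_rate: float,
    min_overlap: int,
) -> pd.DataFrame:
    inserts = _extract_batch(
        reads["seq"], library.ucb_flank5, library.ucb_flank3,
        max_error_rate, min_overlap,
    )
    pattern = library.ucb_pattern
    ok = inserts.map(
        lambda s: isinstance(s, str) and bool(s) and matches_iupac(s, pattern)
    ).to_numpy(dtype=bool)
    sub = reads[ok].copy()
    sub["label"] = inserts[ok]
    return (
        sub.groupby(["cbc", "umi", "label"], sort=False)["reads"]
        .sum()
        .reset_index()
    )


def resolve_ucb(
    reads: pd.DataFrame,
    library: GuideLibrary,
    max_error_rate: float = 0.1,
    min_overlap: int = 6,
    cutoff_fraction: float = 0.01,
    within_umi_fraction: float = 0.2,
) -> pd.DataFrame:
    """Run the UCB cascade: per-cell clone barcode or missing.

    Identical to the guide cascade with the IUPAC pattern filter in place
    of whitelist matching (extraction requires at least 6 nt flank
    overlap); the same one-to-one rule applies.
    """
    counts = _ucb_counts(reads, library, max_error_rate, min_overlap)
    if counts.empty:
        return pd.DataFrame(
            columns=["cbc", "label", "umi_count", "read_count", "status"]
        )
    filtered = apply_read_filters(counts, cutoff_fraction, within_umi_fraction)
    return call_cell_assignments(filtered)


def assign_screen(
    reads: pd.DataFrame,
    library: GuideLibrary,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
    ucb_min_overlap: int = 6,
    max_hamming: int = 2,
    cutoff_fraction: float = 0.01,
    within_umi_fraction: float = 0.2,
    counters: dict | None = None,
) -> pd.DataFrame:
    """Full assignment: one guide label and one clone barcode per cell.

    Returns the assignment table with columns cbc, grna_label, ucb,
    umi_count, read_count, status. The guide and UCB cascades run
    independently; a cell keeps status ``assigned`` even when no UCB
    resolves (abundance analyses need the guide only).
    """
    counters = counters if counters is not None else {}
    gcounts = _guide_counts(
        reads, library, max_error_rate, min_overlap, max_hamming, counters
    )
    filtered = apply_read_filters(gcounts, cutoff_fraction, within_umi_fraction)
    calls = call_cell_assignments(filtered)
    calls = calls.rename(columns={"label": "grna_label"})

    ucb = resolve_ucb(
        reads, library, max_error_rate, ucb_min_overlap,
        cutoff_fraction, within_umi_fraction,
    )
    ucb_map = (
        ucb[ucb["status"] == "assigned"].set_index("cbc")["label"]
        if not ucb.empty
        else pd.Series(dtype=object)
    )

    all_cells = pd.Index(reads["cbc"].unique(), name="cbc")
    out = calls.set_index("cbc").reindex(all_cells)
    out["status"] = out["status"].fillna("unassigned")
    out["umi_count"] = out["umi_count"].fillna(0).astype(int)
    out["read_count"] = out["read_count"].fillna(0).astype(int)
    out["ucb"] = ucb_map.reindex(all_cells)
    out = out.reset_index()
    return out[["cbc", "grna_label", "ucb", "umi_count", "read_count", "status"]]


@dataclass
class CloneStats:
    """Clone complexity summary: clone = unique (guide label, UCB) pair."""

    clones: pd.DataFrame          # grna_label, ucb, n_cells
    per_label: pd.DataFrame       # grna_label, n_clones, mean_cells_per_clone
    mean_cells_per_clone: float
    library_sharing: pd.DataFrame = field(default_factory=pd.DataFrame)


def clone_stats(assignments: pd.DataFrame, meta: pd.DataFrame | None = None
                ) -> CloneStats:
    """Clone counts, size distribution and per-library sharing."""
    ok = assignments[
        (assignments["status"] == "assigned") & assignments["ucb"].notna()
    ]
    if ok.empty:
        raise ValueError("no assigned cells with a resolved UCB")
    clones = (
        ok.groupby(["grna_label", "ucb"], sort=False)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    per_label = (
        clones.groupby("grna_label", sort=False)
        .agg(n_clones=("ucb", "size"), mean_cells_per_clone=("n_cells", "mean"))
        .reset_index()
    )
    sharing = pd.DataFrame()
    if meta is not None:
        merged = ok.merge(
            meta[["cell_id", "library_id"]], left_on="cbc", right_on="cell_id"
        )
        sharing = (
            merged.groupby(["grna_label", "ucb", "library_id"], sort=False)
            .size()
            .rename("n_cells")
            .reset_index()
            .pivot_table(
                index=["grna_label", "ucb"], columns="library_id",
                values="n_cells", fill_value=0,
            )
        )
    return CloneStats(
        clones=clones,
        per_label=per_label,
        mean_cells_per_clone=float(clones["n_cells"].mean()),
        library_sharing=sharing,
    )
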