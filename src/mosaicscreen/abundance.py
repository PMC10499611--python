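"""Screen-level differential abundance of perturbations.

Three complementary readouts:

* guide representation — per-guide detection fractions compared between
  eCas9-induced and uninduced pools (fold change + Welch t-test + BH),
  a proliferation/depletion phenotype;
* stratified enrichment — for each guide and cell state (or the
  dorsal-versus-ventral split), a CMH test of guide-versus-control counts
  in versus out of the state, stratified by library/pool, summarized as a
  signed -log10 FDR score;
* cross-pool consistency — per-pool cell-type fold enrichments of guide
  versus control, tested against a permutation background of shuffled
  guide labels.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .model import CONTROL_LABEL
from .stats import (
    StratifiedTable,
    bh_adjust,
    cmh_test,
    signed_score,
    welch_t_test,
)

__all__ = [
    "grna_representation_test",
    "build_strata",
    "abundance_scan",
    "dorsoventral_scan",
    "pool_fold_enrichment",
    "batch_consistency_test",
]

logger = logging.getLogger(__name__)


def grna_representation_test(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-guide representation fold change between induced and uninduced.

    ``samples`` has one row per (sample_id, grna) with columns sample_id,
    induced (bool), grna, fraction (detected-cell fraction in that pool).
    Fold change is mean(induced fractions) / mean(uninduced fractions);
    p-values come from a Welch t-test on the two fraction samples and are
    BH-adjusted across guides. A guide absent from every uninduced sample
    gets an infinite fold change and is flagged.
    """
    required = {"sample_id", "induced", "grna", "fraction"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(required)}")
    n_ind = samples.loc[samples["induced"], "sample_id"].nunique()
    n_unind = samples.loc[~samples["induced"], "sample_id"].nunique()
    if n_ind < 2 or n_unind < 2:
        raise ValueError("need >= 2 induced and >= 2 uninduced samples")

    rows = []
    for grna, group in samples.groupby("grna", sort=False):
        ind = group.loc[group["induced"], "fraction"].to_numpy()
        unind = group.loc[~group["induced"], "fraction"].to_numpy()
        mean_unind = unind.mean() if unind.size else 0.0
        if mean_unind == 0:
            rows.append((grna, math.inf, np.nan, True))
            continue
        fc = ind.mean() / mean_unind
        if ind.size >= 2 and unind.size >= 2 and (ind.var() > 0 or unind.var() > 0):
            p = welch_t_test(ind, unind).p_value
        elif ind.size >= 2 and unind.size >= 2:
            # degenerate constant samples: no evidence either way
            p = 1.0 if ind.mean() == unind.mean() else 0.0
        else:
            p = np.nan
        rows.append((grna, fc, p, False))
    out = pd.DataFrame(rows, columns=["grna", "fold_change", "p_value", "flagged"])
    testable = out["p_value"].notna()
    out["fdr"] = np.nan
    if testable.any():
        out.loc[testable, "fdr"] = bh_adjust(out.loc[testable, "p_value"])
    return out


def _category_mask(meta: pd.DataFrame, category) -> tuple[np.ndarray, np.ndarray]:
    """(in-category mask, eligible mask) for a cell type or region label."""
    if category in ("dorsal", "ventral"):
        eligible = meta["trajectory"].isin(["dorsal", "ventral"]).to_numpy()
        mask = (meta["trajectory"] == category).to_numpy()
        return mask, eligible
    eligible = np.ones(len(meta), dtype=bool)
    return (meta["cell_type"] == category).to_numpy(), eligible


def build_strata(
    meta: pd.DataFrame,
    grna: str,
    category,
    control=frozenset({CONTROL_LABEL}),
) -> StratifiedTable:
    """One 2x2 stratum per library for a guide-versus-control comparison.

    Rows: {guide cells, control cells}; columns: {in category, not}.
    ``category`` is a cell-type label, or "dorsal"/"ventral" for the
    trajectory split (trajectory "none" cells are then excluded).
    Libraries lacking either group are dropped; having no shared library
    is an error.
    """
    control = {control} if isinstance(control, str) else set(control)
    in_cat, eligible = _category_mask(meta, category)
    is_g = (meta["grna_label"] == grna).to_numpy() & eligible
    is_c = meta["grna_label"].isin(control).to_numpy() & eligible
    libs = meta["library_id"].to_numpy()

    tables = []
    strata = []
    for lib in pd.unique(libs[pd.notna(libs)]):
        in_lib = libs == lib
        g_cat = int((is_g & in_lib & in_cat).sum())
        g_not = int((is_g & in_lib & ~in_cat).sum())
        c_cat = int((is_c & in_lib & in_cat).sum())
        c_not = int((is_c & in_lib & ~in_cat).sum())
        if g_cat + g_not == 0 or c_cat + c_not == 0:
            continue
        tables.append([[g_cat, g_not], [c_cat, c_not]])
        strata.append(lib)
    if not tables:
        raise ValueError(
            f"no library contains both {grna!r} and control cells"
        )
    return StratifiedTable(counts=np.array(tables), strata=tuple(strata))


def abundance_scan(
    meta: pd.DataFrame,
    grnas=None,
    control=frozenset({CONTROL_LABEL}),
    categories=None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """CMH enrichment of every guide in every category, BH across the scan.

    Returns one row per (grna, category) with the stratified counts
    totals, MH log odds ratio, p, FDR, signed -log10 FDR score and a
    significance flag at ``fdr_threshold``. Failures of single pairs
    (degenerate strata) are recorded with NaN p and the scan continues.
    """
    control = {control} if isinstance(control, str) else set(control)
    if grnas is None:
        labels = meta["grna_label"].dropna().unique()
        grnas = [g for g in labels if g not in control]
    if categories is None:
        categories = list(pd.unique(meta["cell_type"].dropna()))

    rows = []
    for grna in grnas:
        for category in categories:
            try:
                table = build_strata(meta, grna, category, control)
                res = cmh_test(table)
                totals = table.counts.sum(axis=0)
                rows.append((
                    grna, category, *totals.ravel().astype(int),
                    res.log_odds, res.p_value,
                ))
            except ValueError as exc:
                logger.warning("scan skipped (%s, %s): %s", grna, category, exc)
                rows.append((grna, category, 0, 0, 0, 0, np.nan, np.nan))
    out = pd.DataFrame(
        rows,
        columns=["grna", "category", "a", "b", "c", "d", "log_odds", "p_value"],
    )
    testable = out["p_value"].notna()
    out["fdr"] = np.nan
    out.loc[testable, "fdr"] = bh_adjust(out.loc[testable, "p_value"])
    out["signed_score"] = [
        signed_score(lo, q) if q == q and lo == lo else np.nan
        for lo, q in zip(out["log_odds"], out["fdr"])
    ]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def dorsoventral_scan(meta: pd.DataFrame, grnas=None,
                      control=frozenset({CONTROL_LABEL}),
                      fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Guide enrichment in dorsal versus ventral telencephalon cells."""
    return abundance_scan(meta, grnas=grnas, control=control,
                          categories=["dorsal"], fdr_threshold=fdr_threshold)


def pool_fold_enrichment(
    meta: pd.DataFrame,
    control=frozenset({CONTROL_LABEL}),
) -> pd.DataFrame:
    """Cell-type fold enrichment per (pool, guide): guide fraction of the
    type within the pool over the control fraction. Entries with a zero
    control fraction are undefined and excluded."""
    control = {control} if isinstance(control, str) else set(control)
    labels = meta["grna_label"]
    rows = []
    for lib, pool in meta[labels.notna()].groupby("library_id", sort=False):
        ctrl = pool[pool["grna_label"].isin(control)]
        if ctrl.empty:
            continue
        ctrl_frac = ctrl["cell_type"].value_counts(normalize=True)
        for grna, cells in pool.groupby("grna_label", sort=False):
            if grna in control:
                continue
            frac = cells["cell_type"].value_counts(normalize=True)
            for ctype, f in frac.items():
                cf = ctrl_frac.get(ctype, 0.0)
                if cf > 0:
                    rows.append((lib, grna, ctype, f / cf))
    return pd.DataFrame(rows, columns=["library_id", "grna", "cell_type", "fe"])


def batch_consistency_test(
    meta: pd.DataFrame,
    control=frozenset({CONTROL_LABEL}),
    n_permutations: int = 100,
    seed: int = 0,
    log2: bool = True,
) -> pd.DataFrame:
    """Consistency of per-pool fold enrichments against a permuted background.

    The background distribution is built by recomputing fold enrichments
    after permuting guide labels within each pool (``n_permutations``
    rounds, seeded); each observed (guide, cell type) sample of per-pool
    (log2) fold enrichments is compared to its pooled background with a
    Welch t-test. Pairs observed in fewer than two pools are skipped.
    """
    control = {control} if isinstance(control, str) else set(control)
    observed = pool_fold_enrichment(meta, control)
    rng = np.random.default_rng(seed)

    bg_frames = []
    perm = meta.copy()
    has_label = meta["grna_label"].notna()
    for _ in range(n_permutations):
        shuffled = perm["grna_label"].copy()
        for _, idx in meta[has_label].groupby("library_id", sort=False).groups.items():
            vals = perm.loc[idx, "grna_label"].to_numpy()
            shuffled.loc[idx] = rng.permutation(vals)
        perm["grna_label"] = shuffled
        bg_frames.append(pool_fold_enrichment(perm, control))
    background = pd.concat(bg_frames, ignore_index=True)

    transform = np.log2 if log2 else (lambda v: v)
    rows = []
    for (grna, ctype), group in observed.groupby(["grna", "cell_type"], sort=False):
        if len(group) < 2:
            logger.info("consistency skipped (%s, %s): <2 pools", grna, ctype)
            continue
        bg = background.loc[background["cell_type"] == ctype, "fe"]
        if len(bg) < 2:
            continue
        res = welch_t_test(transform(group["fe"].to_numpy()),
                           transform(bg.to_numpy()))
        rows.append((grna, ctype, len(group), res.statistic, res.p_value))
    return pd.DataFrame(
        rows, columns=["grna", "cell_type", "n_pools", "t", "p_value"]
    )
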