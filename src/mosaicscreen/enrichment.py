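"""Fisher-exact gene-set enrichment in TF regulatory modules.

Gene sets produced by the screen (per-perturbation TOP-DEGs, pooled DEG
sets) or curated risk-gene lists are tested for over-representation in
transcription-factor regulatory modules (consumed here as plain gene
sets from upstream network inference). Every test intersects query and
module with an explicit background universe — e.g. "genes expressed in
more than 5% of cells" or "genes in the inferred network" — and the
screen's significance rule is FDR < 0.01 together with more than
twofold enrichment (odds ratio).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExpressionMatrix
from .stats import bh_adjust, fisher_exact

__all__ = [
    "Background",
    "normalize_gene",
    "expressed_background",
    "set_enrichment",
    "risk_gene_enrichment",
]

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene(gene: str) -> str:
    """Uppercase and strip trailing version suffixes (e.g. ``.12``)."""
    return _VERSION_SUFFIX.sub("", str(gene).strip()).upper()


def _normset(genes) -> frozenset[str]:
    return frozenset(normalize_gene(g) for g in genes)


@dataclass(frozen=True)
class Background:
    """Gene universe against which overlaps are tested."""

    genes: frozenset[str]
    rule: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", _normset(self.genes))
        if not self.genes:
            raise ValueError("background universe is empty")


def expressed_background(expr: ExpressionMatrix,
                         min_fraction: float = 0.05) -> Background:
    """Genes with nonzero expression in strictly more than ``min_fraction``
    of cells."""
    frac = expr.detection_fraction()
    genes = [g for g, f in zip(expr.genes, frac) if f > min_fraction]
    return Background(
        genes=frozenset(genes),
        rule=f"expressed in >{min_fraction:.0%} of cells",
    )


def set_enrichment(
    query,
    modules: dict[str, set[str]],
    background: Background,
    fdr_threshold: float = 0.01,
    min_odds_ratio: float = 2.0,
) -> pd.DataFrame:
    """Fisher-exact enrichment of a query gene set in each module.

    Per module, the 2x2 table of (in query) x (in module) over the
    background universe is tested; p-values are BH-adjusted across the
    modules of the scan, and a module is flagged significant iff
    FDR < ``fdr_threshold`` and odds ratio > ``min_odds_ratio``. Genes
    outside the background never influence the result; modules entirely
    disjoint from the background are skipped with a log entry.
    """
    universe = background.genes
    q = _normset(query) & universe
    if not q:
        raise ValueError("query does not intersect the background universe")
    rows = []
    for name, genes in modules.items():
        mod = _normset(genes) & universe
        if not mod:
            logger.warning("module %s disjoint from background; skipped", name)
            continue
        a = len(q & mod)
        b = len(q - mod)
        c = len(mod - q)
        d = len(universe) - a - b - c
        res = fisher_exact([[a, b], [c, d]])
        rows.append((name, a, len(mod), res.odds_ratio, res.p_value))
    out = pd.DataFrame(
        rows, columns=["module", "n_overlap", "n_module", "odds_ratio", "p_value"]
    )
    if out.empty:
        return out.assign(fdr=[], significant=[])
    out["fdr"] = bh_adjust(out["p_value"])
    out["significant"] = (out["fdr"] < fdr_threshold) & (
        out["odds_ratio"] > min_odds_ratio
    )
    return out


def risk_gene_enrichment(
    deg_sets: dict[str, set[str]],
    risk_list,
    background: Background,
    fdr_threshold: float = 0.01,
    min_odds_ratio: float = 2.0,
) -> pd.DataFrame:
    """Risk-gene overlap of per-perturbation DEG sets and their pooled union.

    Each perturbation's gene set — and the pooled union under the label
    ``"pooled"`` — is Fisher-tested against the risk list over the
    background universe.
    """
    risk = {"risk": set(risk_list)}
    queries = dict(deg_sets)
    queries["pooled"] = set().union(*deg_sets.values()) if deg_sets else set()
    frames = []
    for label, genes in queries.items():
        if not (_normset(genes) & background.genes):
            logger.warning("query %s disjoint from background; skipped", label)
            continue
        res = set_enrichment(genes, risk, background,
                             fdr_threshold, min_odds_ratio)
        res = res.rename(columns={"module": "risk_set"})
        res.insert(0, "query", label)
        frames.append(res)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
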