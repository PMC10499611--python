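"""Circular projection of terminal-fate probabilities and fate-space tests.

Upstream trajectory analysis provides a row-stochastic matrix F of each
cell's probability of being absorbed in each terminal state. Terminal
states are evenly spaced around the unit circle at angles alpha_t, and
each cell is placed at

    x_i = sum_t f_it cos(alpha_t),    y_i = sum_t f_it sin(alpha_t),

the convex combination of the state anchor points — a one-hot cell sits
exactly on the circle, maximal uncertainty sits at the center.
Enrichment of perturbed cells in fate space reuses the neighborhood
machinery with the fate matrix itself as the embedding (k = 100), and
group differences in single transition probabilities (e.g. progenitors
toward OPC) use the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ValidationError
from .neighborhood import local_enrichment
from .stats import TestResult, wilcoxon_rank_sum

__all__ = [
    "assign_angles",
    "validate_fate_matrix",
    "circular_coords",
    "fate_space_enrichment",
    "compare_transition_probabilities",
    "TransitionComparison",
]

_ROW_SUM_TOL = 1e-6


def assign_angles(states, order=None) -> dict[str, float]:
    """Evenly spaced angles alpha_t = 2 pi t / n_t for the terminal states.

    ``order`` fixes the placement around the circle; default is
    alphabetical for determinism (the circular layout is a presentation
    choice, not a property of the data).
    """
    states = list(states)
    if len(states) != len(set(states)):
        raise ValueError("duplicate terminal state names")
    if len(states) < 2:
        raise ValueError("need at least 2 terminal states")
    ordered = list(order) if order is not None else sorted(states)
    if set(ordered) != set(states):
        raise ValueError("order must be a permutation of the state names")
    n = len(ordered)
    return {s: 2.0 * math.pi * t / n for t, s in enumerate(ordered)}


def validate_fate_matrix(fates: pd.DataFrame) -> pd.DataFrame:
    """Check rows sum to 1 (tol 1e-6) and probabilities lie in [0, 1]."""
    F = fates.to_numpy(dtype=float)
    if ((F < 0) | (F > 1)).any():
        bad = fates.index[((F < 0) | (F > 1)).any(axis=1)][:5].tolist()
        raise ValidationError(f"fate probabilities outside [0,1] for {bad}")
    sums = F.sum(axis=1)
    off = np.abs(sums - 1.0) > _ROW_SUM_TOL
    if off.any():
        bad = fates.index[off][:5].tolist()
        raise ValidationError(f"fate rows do not sum to 1 for cells {bad}")
    return fates


def circular_coords(fates: pd.DataFrame,
                    angles: dict[str, float] | None = None) -> np.ndarray:
    """N x 2 circular-projection coordinates of a fate matrix."""
    validate_fate_matrix(fates)
    if angles is None:
        angles = assign_angles(fates.columns)
    alpha = np.array([angles[s] for s in fates.columns])
    F = fates.to_numpy(dtype=float)
    return np.column_stack([F @ np.cos(alpha), F @ np.sin(alpha)])


def fate_space_enrichment(
    fates: pd.DataFrame,
    meta: pd.DataFrame,
    target,
    control,
    k: int = 100,
    restart: float = 0.5,
) -> pd.DataFrame:
    """Neighborhood enrichment with fate-probability space as the embedding.

    The kNN graph (k = 100) is built on Euclidean distances between fate
    probability rows; scoring and smoothing are identical to the
    transcriptome-space neighborhood test.
    """
    validate_fate_matrix(fates)
    meta = meta.set_index("cell_id").loc[fates.index].reset_index()
    return local_enrichment(
        fates.to_numpy(dtype=float), meta, target, control,
        k=k, restart=restart,
    )


@dataclass(frozen=True)
class TransitionComparison:
    """Wilcoxon comparison of two transition-probability samples."""

    test: TestResult
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    n_a: int
    n_b: int


def compare_transition_probabilities(probs_a, probs_b) -> TransitionComparison:
    """Two-sided Wilcoxon rank-sum on two samples of transition probabilities.

    Medians and interquartile ranges are reported alongside the test for
    box-plot parity.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    for name, v in (("a", a), ("b", b)):
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"sample {name} has values outside [0, 1]")
    res = wilcoxon_rank_sum(a, b)
    qa = np.percentile(a, [25, 75])
    qb = np.percentile(b, [25, 75])
    return TransitionComparison(
        test=res,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=(float(qa[0]), float(qa[1])),
        iqr_b=(float(qb[0]), float(qb[1])),
        n_a=int(a.size),
        n_b=int(b.size),
    )
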