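"""Self-contained statistical primitives used throughout the screen readout.

The pipeline leans on a small number of classical tests: the
Cochran–Mantel–Haenszel (CMH) test with the Mantel–Haenszel common odds
ratio for stratified 2x2 tables (strata are organoid pools / sequencing
libraries), the two-sided Fisher exact test for gene-set overlaps,
Benjamini–Hochberg FDR control, the Welch t-test and the Wilcoxon rank-sum
test. They are implemented here directly — only distribution functions
(chi-square, t, normal tails and the log-gamma function) come from scipy —
so that every downstream score is reproducible from first principles and
can be cross-checked against independent implementations in the test
suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import special
from scipy import stats as _spstats

__all__ = [
    "StratifiedTable",
    "TestResult",
    "cmh_test",
    "cmh_from_counts",
    "fisher_exact",
    "bh_adjust",
    "welch_t_test",
    "wilcoxon_rank_sum",
    "signed_score",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``odds_ratio``/``log_odds`` are populated for association tests and are
    NaN for location tests (t, Wilcoxon) where they have no meaning.
    """

    statistic: float
    p_value: float
    odds_ratio: float = math.nan
    log_odds: float = math.nan
    df: float = math.nan
    method: str = ""


@dataclass(frozen=True)
class StratifiedTable:
    """K strata of 2x2 counts ``[[a_k, b_k], [c_k, d_k]]``.

    Rows are {target, control} group membership and columns are
    {in category, not in category}. Strata with an empty margin are
    tolerated; they contribute nothing to the CMH statistic.
    """

    counts: np.ndarray  # shape (K, 2, 2)
    strata: tuple = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim == 2 and arr.shape == (2, 2):
            arr = arr[None, :, :]
        if arr.ndim != 3 or arr.shape[1:] != (2, 2):
            raise ValueError("counts must have shape (K, 2, 2)")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)
        if not self.strata:
            object.__setattr__(self, "strata", tuple(range(arr.shape[0])))

    @property
    def n_strata(self) -> int:
        return self.counts.shape[0]


def cmh_from_counts(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    axis: int = -1,
    correction: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized CMH statistic, p-value and MH common odds ratio.

    ``a, b, c, d`` are broadcastable arrays of per-stratum cell counts with
    the stratum dimension along ``axis``. Returns ``(statistic, p, or_mh)``
    with the stratum axis reduced. Degenerate strata (n_k <= 1 or an empty
    margin) contribute zero to every sum. Entirely degenerate inputs yield
    NaN statistics (callers decide whether that is an error).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (a + b) * (a + c) / n
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1.0))
        r = a * d / n
        s = b * c / n
    ok = (n > 1) & np.isfinite(v)
    e = np.where(ok, e, 0.0)
    v = np.where(ok, v, 0.0)
    r = np.where(n > 0, r, 0.0)
    s = np.where(n > 0, s, 0.0)
    a_eff = np.where(ok, a, 0.0)

    sum_v = v.sum(axis=axis)
    diff = a_eff.sum(axis=axis) - e.sum(axis=axis)
    if correction:
        diff = np.sign(diff) * np.maximum(np.abs(diff) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(sum_v > 0, diff * diff / sum_v, np.nan)
    p = np.where(np.isnan(stat), np.nan, _spstats.chi2.sf(stat, df=1))

    sum_r = r.sum(axis=axis)
    sum_s = s.sum(axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        or_mh = np.where(
            sum_s > 0,
            sum_r / sum_s,
            np.where(sum_r > 0, np.inf, np.nan),
        )
    return stat, p, or_mh


def cmh_test(table: StratifiedTable, correction: bool = False) -> TestResult:
    """Two-sided Cochran–Mantel–Haenszel test for K stratified 2x2 tables.

    statistic = (sum a_k - sum E_k)^2 / sum V_k with
    E_k = (a_k+b_k)(a_k+c_k)/n_k and
    V_k = (a_k+b_k)(c_d+d_k)(a_k+c_k)(b_k+d_k) / (n_k^2 (n_k-1));
    p from the chi-square distribution with 1 df; effect size is the
    Mantel–Haenszel common odds ratio sum(a_k d_k/n_k) / sum(b_k c_k/n_k).
    ``correction`` applies the optional 0.5 continuity correction (off by
    default).
    """
    t = table.counts
    margins_ok = (
        (t.sum(axis=2) > 0).all(axis=1) & (t.sum(axis=1) > 0).all(axis=1)
    )
    if not margins_ok.any():
        raise ValueError("no informative strata: every stratum has an empty margin")
    stat, p, or_mh = cmh_from_counts(
        t[:, 0, 0], t[:, 0, 1], t[:, 1, 0], t[:, 1, 1], axis=0,
        correction=correction,
    )
    with np.errstate(divide="ignore"):
        log_odds = float(np.log(or_mh)) if or_mh == or_mh else math.nan
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        odds_ratio=float(or_mh),
        log_odds=log_odds,
        df=1.0,
        method="cmh",
    )


_LOGFACT = special.gammaln(np.arange(1024, dtype=float) + 1.0)


def _logfact(n: int) -> np.ndarray:
    """Cached log-factorial table covering 0..n (grown on demand)."""
    global _LOGFACT
    if n >= _LOGFACT.size:
        _LOGFACT = special.gammaln(np.arange(2 * n, dtype=float) + 1.0)
    return _LOGFACT


def _hypergeom_logpmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """log P(a = k) for a 2x2 table with margins (r1, n-r1) x (c1, n-c1)."""
    lf = _logfact(n)
    const = lf[r1] + lf[n - r1] + lf[c1] + lf[n - c1] - lf[n]
    return const - (lf[k] + lf[r1 - k] + lf[c1 - k] + lf[n - r1 - c1 + k])


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table of counts ``[[a,b],[c,d]]``.

    The two-sided p-value sums hypergeometric probabilities of all tables
    (with the observed margins) whose probability does not exceed the
    observed one, using a relative tolerance of 1e-7 for ties — the same
    convention as R's fisher.test. The reported odds ratio is the sample OR
    a*d/(b*c), with the Haldane 0.5 continuity correction applied only when
    a zero in b or c would make it undefined; the p-value is always exact.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if (arr < 0).any() or (arr != np.round(arr)).any():
            raise ValueError("counts must be non-negative integers")
        arr = arr.astype(int)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c

    if n == 0 or r1 in (0, n) or c1 in (0, n):
        p = 1.0
    else:
        lo = max(0, r1 + c1 - n)
        hi = min(r1, c1)
        support = np.arange(lo, hi + 1)
        logpmf = _hypergeom_logpmf(support, n, r1, c1)
        log_obs = logpmf[a - lo]
        mask = logpmf <= log_obs + math.log1p(1e-7)
        if mask.all():
            p = 1.0
        else:
            sel = logpmf[mask]
            m = sel.max()
            p = min(float(np.exp(m) * np.exp(sel - m).sum()), 1.0)

    if b == 0 or c == 0:
        # Haldane correction keeps the effect size finite and rankable
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    log_odds = math.log(odds) if odds > 0 else -math.inf
    return TestResult(
        statistic=float(a),
        p_value=p,
        odds_ratio=odds,
        log_odds=log_odds,
        method="fisher",
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} (p_(j) * m / j) over the sorted p-values, capped at
    1, returned in the original input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test requires at least 2 observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(_spstats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p_value=min(p, 1.0), df=float(df),
                      method="welch_t")


def _wilcoxon_exact_p(ranks: np.ndarray, nx: int, w_obs: float) -> float:
    """Exact two-sided p by enumerating all nx-subsets of the rank vector."""
    n = ranks.size
    mu = nx * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n), nx):
        total += 1
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration of the rank-sum distribution when n_x + n_y <= 12
    (valid with ties, since the realized rank vector is conditioned upon);
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = _spstats.rankdata(combined)
    w = float(ranks[:nx].sum())
    if n <= 12:
        p = _wilcoxon_exact_p(ranks, nx, w)
        return TestResult(statistic=w, p_value=p, method="wilcoxon_exact")
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1.0))
    var = nx * ny / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return TestResult(statistic=w, p_value=1.0, method="wilcoxon_normal")
    dev = abs(w - mu)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    p = 2.0 * float(_spstats.norm.sf(z))
    return TestResult(statistic=w, p_value=min(p, 1.0), method="wilcoxon_normal")


def signed_score(log_odds: float, fdr: float) -> float:
    """sign(log odds ratio) x (-log10 of the FDR-adjusted p-value).

    The screen's effect score: direction from the (MH) odds ratio,
    magnitude from significance. Zero log-odds or fdr == 1 give 0.
    """
    if not fdr <= 1.0:
        raise ValueError("fdr must lie in (0, 1]")
    if fdr <= 0.0:
        warnings.warn("fdr of 0 clipped to smallest positive float",
                      RuntimeWarning, stacklevel=2)
        fdr = float(np.nextafter(0.0, 1.0))
    if log_odds == 0.0 or math.isnan(log_odds):
        return 0.0
    return float(math.copysign(-math.log10(fdr), log_odds))
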