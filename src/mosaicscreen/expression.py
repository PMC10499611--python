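"""Logistic-regression differential expression per perturbation.

Each perturbation is contrasted with control cells by modelling the cell
condition (perturbed = 1, control = 0) as a logistic function of the
gene's log-normalized expression on top of nuisance covariates —
log(total UMI count), library and cell type as one-hot factors — and
testing the gene coefficient with a likelihood-ratio test (chi-square,
1 df). Trajectory-restricted contrasts omit the cell-type covariate.
The reported effect size is the difference in mean log-normalized
expression (perturbed minus control). Genes are pre-filtered by
detection fraction, significant genes are BH-corrected, and the
per-perturbation "TOP-DEG" set keeps the 30 largest absolute fold
changes among FDR < 0.05 genes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as _spstats

from .model import CONTROL_LABEL, ExpressionMatrix
from .stats import bh_adjust

__all__ = ["lr_de_test", "select_top_degs"]

logger = logging.getLogger(__name__)

_MAX_ABS_COEF = 30.0  # |beta| beyond this signals quasi-separation


def _logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    ridge_idx: int | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    """Newton-Raphson logistic fit; returns (beta, unpenalized llf, ok).

    ``ridge`` applies an L2 penalty to the single coefficient
    ``ridge_idx`` only (used as a fallback under quasi-separation); the
    returned log-likelihood is always the unpenalized one evaluated at
    the solution, so likelihood-ratio statistics stay interpretable.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        if ridge > 0 and ridge_idx is not None:
            grad[ridge_idx] -= ridge * beta[ridge_idx]
            hess[ridge_idx, ridge_idx] += ridge
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, _bernoulli_llf(X, y, beta), False
        beta = beta + step
        ll = _bernoulli_llf(X, y, beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    ok = np.all(np.abs(beta) < _MAX_ABS_COEF) and np.isfinite(ll)
    return beta, ll, bool(ok)


def _bernoulli_llf(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -500, 500)
    return float((y * eta - np.log1p(np.exp(eta))).sum())


def _design_matrix(meta: pd.DataFrame, n_umi: np.ndarray,
                   covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(meta))]
    if "n_UMI" in covariates:
        lu = np.log(n_umi.astype(float))
        if lu.std() > 0:  # constant depth carries no information
            cols.append((lu - lu.mean()) / lu.std())
    for factor in ("library", "cell_type"):
        if factor in covariates:
            col = "library_id" if factor == "library" else "cell_type"
            dummies = pd.get_dummies(meta[col], drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def lr_de_test(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    target: str,
    control=frozenset({CONTROL_LABEL}),
    covariates: tuple[str, ...] = ("n_UMI", "library", "cell_type"),
    min_detection: float = 0.05,
    trajectory: str | None = None,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Likelihood-ratio differential expression of target versus control.

    Fits, per gene, condition ~ covariates + gene expression against the
    covariate-only null (fitted once per contrast) and reports the
    1-df chi-square LRT p, mean log-expression difference, and BH FDR.
    ``trajectory`` restricts cells to one trajectory and drops the
    cell_type covariate (within-trajectory testing). Genes detected in
    fewer than ``min_detection`` of tested cells are excluded. Fits that
    diverge are retried with a small ridge on the gene coefficient;
    unrecoverable fits get NaN p and a flag.
    """
    control = {control} if isinstance(control, str) else set(control)
    m = meta.set_index("cell_id").loc[expr.cells].reset_index()
    keep = m["grna_label"].eq(target) | m["grna_label"].isin(control)
    if trajectory is not None:
        keep &= m["trajectory"] == trajectory
        covariates = tuple(c for c in covariates if c != "cell_type")
    m = m[keep.to_numpy()]
    sub = expr.subset_cells(keep.to_numpy())
    if sub.n_umi is None:
        raise ValueError("expression matrix must carry per-cell n_UMI")
    y = m["grna_label"].eq(target).to_numpy(dtype=float)
    n_target = int(y.sum())
    n_control = int(len(y) - n_target)
    if n_target < 20 or n_control < 20:
        raise ValueError(
            f"need >= 20 cells per group (target {n_target}, control {n_control})"
        )

    detected = (sub.X > 0).mean(axis=0) >= min_detection
    genes = [g for g, ok in zip(sub.genes, detected) if ok]
    gidx = np.flatnonzero(detected)

    X0 = _design_matrix(m, sub.n_umi, covariates)
    beta0, ll0, ok0 = _logistic_fit(X0, y)
    if not ok0:
        logger.warning("null model fit did not converge cleanly")

    X1 = np.column_stack([X0, np.zeros(len(y))])
    gene_col = X1.shape[1] - 1
    rows = []
    for g, j in zip(genes, gidx):
        x = sub.X[:, j]
        X1[:, gene_col] = x
        beta, ll1, ok = _logistic_fit(X1, y)
        if not ok:
            beta, ll1, ok = _logistic_fit(X1, y, ridge=ridge,
                                          ridge_idx=gene_col)
        if ok:
            lrt = max(2.0 * (ll1 - ll0), 0.0)
            p = float(_spstats.chi2.sf(lrt, df=1))
        else:
            lrt, p = np.nan, np.nan
        log_fc = float(x[y == 1].mean() - x[y == 0].mean())
        rows.append((g, log_fc, float(beta[gene_col]), lrt, p, ok))
    out = pd.DataFrame(
        rows, columns=["gene", "log_fc", "beta", "lrt", "p_value", "converged"]
    )
    testable = out["p_value"].notna()
    out["fdr"] = np.nan
    out.loc[testable, "fdr"] = bh_adjust(out.loc[testable, "p_value"])
    out["target"] = target
    out["trajectory"] = trajectory if trajectory is not None else "all"
    return out


def select_top_degs(de: pd.DataFrame, n: int = 30,
                    fdr_threshold: float = 0.05) -> list[str]:
    """Top-n significant genes by absolute fold change (ties retained).

    Among genes with FDR below the threshold, keeps the ``n`` largest by
    |log fold change|; a tie straddling rank n keeps every tied gene
    (logged), and fewer than n significant genes are all returned.
    """
    if "fdr" not in de.columns:
        raise ValueError("DE table lacks an fdr column")
    sig = de[de["fdr"] < fdr_threshold].copy()
    if len(sig) <= n:
        return sig["gene"].tolist()
    sig["abs_fc"] = sig["log_fc"].abs()
    sig = sig.sort_values(["abs_fc", "gene"], ascending=[False, True])
    threshold = sig["abs_fc"].iloc[n - 1]
    chosen = sig[sig["abs_fc"] >= threshold]
    if len(chosen) > n:
        logger.info("tie at rank %d: returning %d genes", n, len(chosen))
    return chosen["gene"].tolist()
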