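"""Per-variant covariate-adjusted association scans.

Quantitative traits use OLS; the dosage term is obtained by
Frisch–Waugh–Lovell residualization so thousands of variants share one
covariate decomposition. Binary traits use logistic regression fitted by
Newton–Raphson IRLS, warm-started from the covariate-only fit. Both routes
are exact maximum-likelihood / least-squares fits and are cross-checked
against statsmodels in the test suite.

P-values are two-sided normal (Wald): ``p = 2·Φ(−|beta/se|)``, so every
record's p is reproducible from its beta and se.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SummaryStats, normal_p_from_z

__all__ = ["scan_quantitative", "scan_binary", "stratified_scan", "design_matrix"]


def design_matrix(covariates: Optional[np.ndarray], n: int) -> np.ndarray:
    """Intercept plus covariates, with collinear columns dropped (warned)."""
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    X = np.column_stack([np.ones(n), C])
    # rank-deficiency check via pivoted QR on the scaled design
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    keep = diag > tol
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} collinear covariate column(s)")
        X = X[:, keep]
    return X


def _records_frame(variants: pd.DataFrame, eaf: np.ndarray,
                   beta: np.ndarray, se: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    rec = variants.loc[:, ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    rec["eaf"] = eaf
    rec["beta"] = beta
    rec["se"] = se
    rec["pvalue"] = p
    return rec.reset_index(drop=True)


def scan_quantitative(
    trait: np.ndarray,
    dosages: np.ndarray,
    covariates: Optional[np.ndarray],
    variants: pd.DataFrame,
    trait_name: str = "trait",
) -> SummaryStats:
    """OLS of trait on each variant's dosage plus covariates.

    Complete-case: rows with any missing value are dropped before fitting.
    Degenerate variants (constant dosage after residualization) and a
    constant trait yield NaN se/p and beta 0, flagged in
    ``result.records.attrs['degenerate']``.
    """
    y = np.asarray(trait, dtype=float)
    G = np.asarray(dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n = y.shape[0]
    C = covariates
    mask = np.isfinite(y) & np.all(np.isfinite(G), axis=1)
    if C is not None:
        Cc = np.atleast_2d(np.asarray(C, dtype=float))
        if Cc.shape[0] != n:
            Cc = Cc.T
        mask &= np.all(np.isfinite(Cc), axis=1)
        C = Cc[mask]
    y, G = y[mask], G[mask]
    n = y.shape[0]

    X = design_matrix(C, n)
    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = y_res @ G_res
    yy = float(y_res @ y_res)
    df = n - X.shape[1] - 1

    degenerate = gg <= np.finfo(float).eps * n
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(degenerate, np.nan, gy / np.where(degenerate, 1.0, gg))
        rss = yy - beta**2 * gg
        sigma2 = np.maximum(rss, 0.0) / max(df, 1)
        se = np.sqrt(sigma2 / gg)
    trait_constant = yy <= np.finfo(float).eps * n
    if trait_constant:
        beta = np.zeros_like(beta)
        se = np.full_like(se, np.nan)
    se = np.where(degenerate | (se <= 0), np.nan, se)
    with np.errstate(invalid="ignore"):
        z = beta / se
    p = np.where(np.isfinite(z), normal_p_from_z(np.where(np.isfinite(z), z, 0.0)), np.nan)
    if trait_constant:
        p = np.full_like(p, np.nan)

    eaf = G.mean(axis=0) / 2.0
    rec = _records_frame(variants, eaf, beta, se, p)
    rec.attrs["degenerate"] = degenerate | trait_constant
    return SummaryStats(trait_name=trait_name, trait_type="quantitative", n=n, records=rec)


def _logistic_newton(X: np.ndarray, y: np.ndarray, beta0: np.ndarray,
                     max_iter: int = 30, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic fit. Returns (beta, se, converged)."""
    beta = beta0.copy()
    converged = False
    XtWX = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        XtWX = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(beta.shape, np.nan), False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(beta.shape, np.nan)
    return beta, se, converged


def scan_binary(
    case_status: np.ndarray,
    dosages: np.ndarray,
    covariates: Optional[np.ndarray],
    variants: pd.DataFrame,
    trait_name: str = "disease",
    separation_limit: float = 15.0,
) -> SummaryStats:
    """Logistic regression of case status on each variant plus covariates.

    beta is the log-odds per effect allele. Variants with (quasi-)complete
    separation or non-convergent fits get NaN beta/se/p and are excluded
    downstream. Requires both classes present.
    """
    y = np.asarray(case_status, dtype=float)
    uniq = np.unique(y[np.isfinite(y)])
    if not np.array_equal(uniq, [0.0, 1.0]):
        raise ValueError("case_status must contain both cases (1) and controls (0)")
    G = np.asarray(dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    mask = np.isfinite(y) & np.all(np.isfinite(G), axis=1)
    C = covariates
    if C is not None:
        Cc = np.atleast_2d(np.asarray(C, dtype=float))
        if Cc.shape[0] != y.shape[0]:
            Cc = Cc.T
        mask &= np.all(np.isfinite(Cc), axis=1)
        C = Cc[mask]
    y, G = y[mask], G[mask]
    n = y.shape[0]

    X0 = design_matrix(C, n)
    k0 = X0.shape[1]
    base_beta, _, _ = _logistic_newton(X0, y, np.zeros(k0))

    m = G.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    X = np.column_stack([X0, np.zeros(n)])
    start = np.append(base_beta, 0.0)
    for j in range(m):
        g = G[:, j]
        if g.std() <= 1e-12:
            continue
        X[:, -1] = g
        b, s, conv = _logistic_newton(X, y, start)
        if conv and np.isfinite(b[-1]) and abs(b[-1]) < separation_limit and np.isfinite(s[-1]) and s[-1] > 0:
            beta[j], se[j] = b[-1], s[-1]

    with np.errstate(invalid="ignore"):
        z = beta / se
    p = np.where(np.isfinite(z), normal_p_from_z(np.where(np.isfinite(z), z, 0.0)), np.nan)
    eaf = G.mean(axis=0) / 2.0
    rec = _records_frame(variants, eaf, beta, se, p)
    n_case = int(y.sum())
    return SummaryStats(
        trait_name=trait_name, trait_type="binary", n=n,
        n_case=n_case, n_control=n - n_case, records=rec,
    )


def stratified_scan(
    trait: np.ndarray,
    dosages: np.ndarray,
    covariates: Optional[np.ndarray],
    variants: pd.DataFrame,
    stratum: np.ndarray,
    trait_name: str = "trait",
    binary: bool = False,
    min_stratum_n: int = 50,
) -> dict[str, SummaryStats]:
    """Independent scans within each level of a boolean stratum flag.

    Returns {"stratum_true": ..., "stratum_false": ...}. Refuses empty or
    undersized strata.
    """
    s = np.asarray(stratum, dtype=bool)
    out = {}
    for label, sel in (("stratum_true", s), ("stratum_false", ~s)):
        n_s = int(sel.sum())
        if n_s == 0:
            raise ValueError(f"{label} is empty")
        if n_s < min_stratum_n:
            raise ValueError(f"{label} has {n_s} < {min_stratum_n} individuals")
        cov_s = None
        if covariates is not None:
            Cc = np.atleast_2d(np.asarray(covariates, dtype=float))
            if Cc.shape[0] != len(s):
                Cc = Cc.T
            cov_s = Cc[sel]
        scan = scan_binary if binary else scan_quantitative
        out[label] = scan(
            np.asarray(trait)[sel], np.asarray(dosages)[sel], cov_s, variants,
            trait_name=f"{trait_name}:{label}",
        )
    return out
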