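"""Maximum-likelihood random-intercept/random-slope model for y ~ time.

Specialised two-effect linear mixed model used for the annualized eGFR
slope: fixed intercept and slope, per-person random intercept and slope
with an unstructured 2×2 covariance, and i.i.d. residuals. The marginal
likelihood factorises over persons; persons are batched by visit count so
all per-person 6×6 (or smaller) Cholesky factorisations run as stacked
numpy operations. Estimates agree with statsmodels MixedLM (checked in
the test suite) but run orders of magnitude faster on thousands of
persons, which the repeated synthetic-cohort suites require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import optimize

__all__ = ["FastLMMResult", "fit_random_slope_model"]


@dataclass
class FastLMMResult:
    fixed_intercept: float
    fixed_slope: float
    psi: np.ndarray            # 2x2 random-effect covariance
    sigma2: float              # residual variance
    blups: Dict[object, Tuple[float, float]]  # person -> (intercept dev, slope dev)
    converged: bool
    loglike: float


def _group_by_count(ids: np.ndarray, t: np.ndarray, y: np.ndarray):
    """Split into batches of persons sharing a visit count."""
    order = np.argsort(ids, kind="stable")
    ids, t, y = ids[order], t[order], y[order]
    uniq, starts, counts = np.unique(ids, return_index=True, return_counts=True)
    batches = {}
    for n_i in np.unique(counts):
        sel = counts == n_i
        pid = uniq[sel]
        rows = np.concatenate([np.arange(s, s + n_i) for s in starts[sel]])
        g = sel.sum()
        batches[int(n_i)] = (pid, t[rows].reshape(g, n_i), y[rows].reshape(g, n_i))
    return batches


def _theta_to_cov(theta: np.ndarray) -> Tuple[float, np.ndarray]:
    log_se, log_d1, log_d2, rho_raw = theta
    sigma2 = np.exp(2 * log_se)
    d1, d2 = np.exp(log_d1), np.exp(log_d2)
    rho = np.tanh(rho_raw)
    psi = np.array([[d1 * d1, rho * d1 * d2], [rho * d1 * d2, d2 * d2]])
    return sigma2, psi


def _batched_terms(batches, sigma2: float, psi: np.ndarray):
    """Accumulate GLS sufficient statistics over all person batches."""
    XtViX = np.zeros((2, 2))
    XtViy = np.zeros(2)
    ytViy = 0.0
    logdet = 0.0
    per_batch = []
    for n_i, (pid, T, Y) in batches.items():
        g = T.shape[0]
        Z = np.stack([np.ones_like(T), T], axis=-1)          # (g, n, 2)
        V = sigma2 * np.eye(n_i)[None] + Z @ psi @ np.swapaxes(Z, 1, 2)
        L = np.linalg.cholesky(V)
        logdet += 2.0 * np.sum(np.log(np.einsum("gii->gi", L)))
        # solve V^{-1} [X | y] via cholesky; X per person equals Z here
        rhs = np.concatenate([Z, Y[:, :, None]], axis=2)      # (g, n, 3)
        sol = np.linalg.solve(V, rhs)                         # small n: direct solve
        ViX, Viy = sol[:, :, :2], sol[:, :, 2]
        XtViX += np.einsum("gnk,gnl->kl", Z, ViX)
        XtViy += np.einsum("gnk,gn->k", Z, Viy)
        ytViy += float(np.einsum("gn,gn->", Y, Viy))
        per_batch.append((pid, T, Y, Z, V))
    return XtViX, XtViy, ytViy, logdet, per_batch


def fit_random_slope_model(
    person_ids: np.ndarray,
    times: np.ndarray,
    values: np.ndarray,
    maxiter: int = 200,
) -> FastLMMResult:
    """Fit the random-intercept/random-slope model by marginal ML."""
    ids = np.asarray(person_ids)
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    batches = _group_by_count(ids, t, y)

    # moment-based start from per-person OLS
    slopes, inters, resid_ss, n_obs = [], [], 0.0, 0
    for n_i, (pid, T, Y) in batches.items():
        if n_i >= 2:
            tm = T - T.mean(axis=1, keepdims=True)
            ym = Y - Y.mean(axis=1, keepdims=True)
            sxx = np.einsum("gn,gn->g", tm, tm)
            b = np.einsum("gn,gn->g", tm, ym) / np.where(sxx > 0, sxx, 1.0)
            a = Y.mean(axis=1) - b * T.mean(axis=1)
            pred = a[:, None] + b[:, None] * T
            resid_ss += float(((Y - pred) ** 2).sum())
            n_obs += Y.size
            slopes.extend(b)
            inters.extend(a)
    slopes = np.asarray(slopes) if slopes else np.zeros(1)
    inters = np.asarray(inters) if inters else np.zeros(1)
    sig0 = np.sqrt(max(resid_ss / max(n_obs - 2 * max(len(slopes), 1), 1), 1e-8))
    d1_0 = max(np.std(inters), 1e-4)
    d2_0 = max(np.std(slopes) * 0.5, 1e-4)
    x0 = np.array([np.log(sig0), np.log(d1_0), np.log(d2_0), 0.0])

    def negloglike(theta):
        sigma2, psi = _theta_to_cov(theta)
        try:
            XtViX, XtViy, ytViy, logdet, _ = _batched_terms(batches, sigma2, psi)
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return 1e12
        quad = ytViy - 2 * beta @ XtViy + beta @ XtViX @ beta
        n_tot = ids.shape[0]
        val = 0.5 * (logdet + quad + n_tot * np.log(2 * np.pi))
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        negloglike, x0, method="L-BFGS-B", options={"maxiter": maxiter},
        bounds=[(-12, 6)] * 3 + [(-5, 5)],
    )
    sigma2, psi = _theta_to_cov(res.x)
    XtViX, XtViy, ytViy, logdet, per_batch = _batched_terms(batches, sigma2, psi)
    beta = np.linalg.solve(XtViX, XtViy)

    blups: Dict[object, Tuple[float, float]] = {}
    for pid, T, Y, Z, V in per_batch:
        resid = Y - (beta[0] + beta[1] * T)
        Vir = np.linalg.solve(V, resid[:, :, None])[:, :, 0]
        b = np.einsum("kl,gnl,gn->gk", psi, Z, Vir)
        for p, bi in zip(pid, b):
            blups[p] = (float(bi[0]), float(bi[1]))
    return FastLMMResult(
        fixed_intercept=float(beta[0]), fixed_slope=float(beta[1]),
        psi=psi, sigma2=float(sigma2), blups=blups,
        converged=bool(res.success), loglike=float(-res.fun),
    )
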