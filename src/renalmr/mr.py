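"""Two-sample Mendelian randomization estimators and instrument diagnostics.

Estimators: the Wald ratio for single instruments and multiplicative
random-effects IVW (weighted least squares of outcome on exposure effects
through the origin, weights 1/se_out², SE inflated by
``sqrt(max(1, Q/(k-1)))``) for two or more. Diagnostics: Cochran's Q over
per-SNP Wald ratios, the MR-Egger intercept for directional pleiotropy,
and a z-test for heterogeneity between stratum-specific estimates.

All p-values are two-sided normal, so ``p`` is always reproducible from
``beta`` and ``se``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .instruments import InstrumentSet
from .io import normal_p_from_z

__all__ = ["MRResult", "wald_ratio", "ivw_mre", "egger", "cochran_q",
           "heterogeneity_z", "run_mr"]


@dataclass
class MRResult:
    protein_id: str
    outcome_name: str
    method: str                  # "wald" or "ivw_mre"
    beta: float
    se: float
    pvalue: float
    n_snp: int
    cochran_Q: Optional[float] = None
    Q_pvalue: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    q_flag: bool = False         # heterogeneity concern (Q p < 0.05)
    egger_flag: bool = False     # pleiotropy concern (intercept p < 0.05)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               protein_id: str = "protein", outcome_name: str = "outcome") -> MRResult:
    """Single-instrument ratio estimate with first-order delta-method SE.

    beta = beta_out / beta_exp, se = se_out / |beta_exp|. Undefined when
    beta_exp is zero (callers skip the pair).
    """
    if beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MRResult(protein_id, outcome_name, "wald", beta, se,
                    float(normal_p_from_z(beta / se)), n_snp=1)


def _q_statistic(b_exp, se_exp, b_out, se_out, beta_ivw) -> float:
    """Cochran's Q over per-SNP ratios with first-order ratio weights."""
    ratios = b_out / b_exp
    ratio_se = se_out / np.abs(b_exp)
    w = 1.0 / ratio_se**2
    return float(np.sum(w * (ratios - beta_ivw) ** 2))


def ivw_mre(inst: InstrumentSet, outcome_name: str = "outcome") -> MRResult:
    """Multiplicative random-effects IVW estimate.

    With fewer than 2 usable SNPs, defers to the Wald ratio (both paths
    agree exactly for a single SNP). The random-effects scale factor is
    floored at 1 so the SE never shrinks below the fixed-effect SE.
    """
    snps = inst.snps.dropna(subset=["beta_exp", "beta_out", "se_out"])
    snps = snps[snps["beta_exp"] != 0]
    k = len(snps)
    if k == 0:
        raise ValueError("no usable instruments")
    b_exp = snps["beta_exp"].to_numpy(dtype=float)
    se_exp = snps["se_exp"].to_numpy(dtype=float)
    b_out = snps["beta_out"].to_numpy(dtype=float)
    se_out = snps["se_out"].to_numpy(dtype=float)
    if k == 1:
        res = wald_ratio(b_exp[0], se_exp[0], b_out[0], se_out[0],
                         inst.protein_id, outcome_name)
        res.method = "wald"
        return res

    w = 1.0 / se_out**2
    beta = float(np.sum(w * b_exp * b_out) / np.sum(w * b_exp**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(w * b_exp**2)))
    Q = _q_statistic(b_exp, se_exp, b_out, se_out, beta)
    scale = max(1.0, Q / (k - 1))
    se = se_fixed * np.sqrt(scale)
    q_p = float(stats.chi2.sf(Q, k - 1))
    res = MRResult(inst.protein_id, outcome_name, "ivw_mre", beta, se,
                   float(normal_p_from_z(beta / se)), n_snp=k,
                   cochran_Q=Q, Q_pvalue=q_p, q_flag=q_p < 0.05)
    if k >= 3:
        try:
            intercept, slope, int_se = egger(inst)
            res.egger_intercept = intercept
            res.egger_intercept_p = float(normal_p_from_z(intercept / int_se))
            res.egger_flag = res.egger_intercept_p < 0.05
        except (ValueError, np.linalg.LinAlgError):
            pass
    return res


def egger(inst: InstrumentSet) -> tuple[float, float, float]:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with an
    intercept, weights 1/se_out², exposure effects oriented positive first.

    Returns (intercept, slope, intercept_se). Requires >= 3 SNPs.
    """
    snps = inst.snps.dropna(subset=["beta_exp", "beta_out", "se_out"])
    k = len(snps)
    if k < 3:
        raise ValueError(f"MR-Egger needs >= 3 SNPs, got {k}")
    sign = np.sign(snps["beta_exp"].to_numpy(dtype=float))
    sign[sign == 0] = 1.0
    x = snps["beta_exp"].to_numpy(dtype=float) * sign
    y = snps["beta_out"].to_numpy(dtype=float) * sign
    w = 1.0 / snps["se_out"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones(k), x])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ y)
    resid = y - X @ coef
    # multiplicative overdispersion, floored at 1 (as in the IVW model)
    phi = max(1.0, float(np.sum(w * resid**2) / (k - 2)))
    cov = np.linalg.inv(XtWX) * phi
    intercept, slope = float(coef[0]), float(coef[1])
    return intercept, slope, float(np.sqrt(cov[0, 0]))


def cochran_q(inst: InstrumentSet) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP Wald ratios; returns (Q, df, p).

    Instruments failing the test are flagged, never removed.
    """
    snps = inst.snps.dropna(subset=["beta_exp", "beta_out", "se_out"])
    snps = snps[snps["beta_exp"] != 0]
    k = len(snps)
    if k < 2:
        raise ValueError("Cochran's Q needs >= 2 SNPs")
    b_exp = snps["beta_exp"].to_numpy(dtype=float)
    se_exp = snps["se_exp"].to_numpy(dtype=float)
    b_out = snps["beta_out"].to_numpy(dtype=float)
    se_out = snps["se_out"].to_numpy(dtype=float)
    w = 1.0 / se_out**2
    beta = float(np.sum(w * b_exp * b_out) / np.sum(w * b_exp**2))
    Q = _q_statistic(b_exp, se_exp, b_out, se_out, beta)
    df = k - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def heterogeneity_z(result_a: MRResult, result_b: MRResult) -> tuple[float, float]:
    """z-test for a difference between two stratum-specific MR estimates:
    z = (β₁−β₂)/√(se₁²+se₂²), two-sided normal p."""
    z = (result_a.beta - result_b.beta) / np.sqrt(result_a.se**2 + result_b.se**2)
    return float(z), float(normal_p_from_z(z))


def run_mr(inst: InstrumentSet, outcome_name: str = "outcome") -> MRResult:
    """IVW when >= 2 SNPs are available, otherwise the Wald ratio."""
    return ivw_mre(inst, outcome_name=outcome_name)
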