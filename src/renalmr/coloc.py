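"""Bayesian colocalization via Wakefield approximate Bayes factors.

For two traits measured over the same region, each SNP gets a log
approximate Bayes factor (ABF) per trait; summing appropriately weighted
configurations gives posterior probabilities for the five hypotheses
H0 (no association), H1/H2 (one trait only), H3 (both traits, distinct
causal variants) and H4 (a single shared causal variant). All sums are
done in log space (log-sum-exp) for stability; an exact brute-force
linear-space enumeration is used as the oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .io import SummaryStats

__all__ = ["ColocResult", "wakefield_abf", "colocalize",
           "PRIOR_SD_QUANTITATIVE", "PRIOR_SD_BINARY"]

#: prior SD of the true effect underlying the ABF
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.20


@dataclass
class ColocResult:
    protein_id: str
    outcome_name: str
    n_snps: int
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    p1: float
    p2: float
    p12: float

    @property
    def passed(self) -> bool:
        return self.pp4 > 0.8

    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def wakefield_abf(beta, se, trait_type: str = "quantitative",
                  prior_sd: float | None = None) -> np.ndarray:
    """Log approximate Bayes factor for association at each SNP.

    ``log ABF = ½·[log(V/(V+W)) + z²·W/(V+W)]`` with ``z = beta/se``,
    ``V = se²`` and prior effect variance ``W = prior_sd²`` (0.15 for
    quantitative traits, 0.2 for binary log-odds by default).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    if prior_sd is None:
        prior_sd = PRIOR_SD_BINARY if trait_type == "binary" else PRIOR_SD_QUANTITATIVE
    V = se**2
    W = prior_sd**2
    z2 = (beta / se) ** 2
    labf = 0.5 * (np.log(V / (V + W)) + z2 * W / (V + W))
    return labf if labf.ndim else float(labf)


def colocalize(
    trait1: SummaryStats,
    trait2: SummaryStats,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    protein_id: str = "protein",
    outcome_name: str = "outcome",
) -> ColocResult:
    """Posterior colocalization probabilities for a shared region.

    Variants are intersected on variant_id; with zero shared variants the
    region cannot be evaluated (error). Evidence sums:
    ``H1 ∝ p1·ΣL1ᵢ``, ``H2 ∝ p2·ΣL2ⱼ``, ``H3 ∝ p1·p2·Σ_{i≠j}L1ᵢL2ⱼ``,
    ``H4 ∝ p12·ΣᵢL1ᵢL2ᵢ``, ``H0 ∝ 1``, normalized in log space. A
    single-SNP region has no i≠j term, so PP3 is exactly 0 there.
    """
    r1 = trait1.records.dropna(subset=["beta", "se"]).set_index("variant_id")
    r2 = trait2.records.dropna(subset=["beta", "se"]).set_index("variant_id")
    shared = r1.index.intersection(r2.index)
    if len(shared) == 0:
        raise ValueError("no shared variants between the two traits")
    l1 = wakefield_abf(r1.loc[shared, "beta"].to_numpy(),
                       r1.loc[shared, "se"].to_numpy(), trait1.trait_type)
    l2 = wakefield_abf(r2.loc[shared, "beta"].to_numpy(),
                       r2.loc[shared, "se"].to_numpy(), trait2.trait_type)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lH0 = 0.0
    lH1 = np.log(p1) + lsum1
    lH2 = np.log(p2) + lsum2
    # sum_{i != j} L1_i L2_j = (sum L1)(sum L2) - sum L1 L2
    cross = lsum1 + lsum2
    if len(l1) == 1:
        lH3 = -np.inf
    else:
        # log(exp(cross) - exp(lsum12)); the i=j part never exceeds the full
        # cross product, but roundoff can push the ratio to 1 — clamp it
        ratio = min(np.exp(lsum12 - cross), 1.0 - 1e-16)
        lH3 = np.log(p1) + np.log(p2) + cross + np.log1p(-ratio)
    lH4 = np.log(p12) + lsum12

    logs = np.array([lH0, lH1, lH2, lH3, lH4])
    post = np.exp(logs - logsumexp(logs))
    post = post / post.sum()
    return ColocResult(
        protein_id=protein_id, outcome_name=outcome_name, n_snps=len(shared),
        pp0=float(post[0]), pp1=float(post[1]), pp2=float(post[2]),
        pp3=float(post[3]), pp4=float(post[4]), p1=p1, p2=p2, p12=p12,
    )
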