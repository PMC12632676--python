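"""ACAT p-value aggregation, multiplicity control, directional consistency,
and replication logic.

The Cauchy combination test (ACAT) maps each p-value through
``tan((0.5 - p)·π)``, averages with weights, and inverts the Cauchy CDF;
it stays valid under arbitrary dependence among the component p-values,
which is what makes it appropriate for the four correlated kidney
endpoints (eGFR, eGFR slope, CKD, ESKD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

from .instruments import InstrumentSet
from .mr import MRResult, run_mr

__all__ = ["acat", "bonferroni_threshold", "classify_direction", "replicate",
           "ProteinVerdict", "ENDPOINT_ORIENTATION"]

_P_CLIP = 1e-15

#: sign that maps each endpoint's beta onto the common "kidney benefit" axis
ENDPOINT_ORIENTATION = {
    "egfr": +1.0,    # higher eGFR is protective
    "slope": +1.0,   # less-negative slope = slower decline
    "ckd": -1.0,     # lower CKD risk is protective
    "eskd": -1.0,
}


def acat(pvalues: Sequence[float], weights: Optional[Sequence[float]] = None) -> float:
    """Aggregated Cauchy association test.

    ``T = Σ wᵢ·tan((0.5−pᵢ)π)``, combined p = ``0.5 − arctan(T)/π``.
    Inputs are clipped to [1e-15, 1−1e-15] before the tangent transform;
    weights are normalized to sum to 1 (equal by default). Identical inputs
    pass through unchanged (the Cauchy mean of equal values).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("acat requires at least one p-value")
    if np.any((p <= 0) | (p >= 1)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1)")
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.size != p.size:
            raise ValueError("weights length must match p-values")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    T = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    return float(0.5 - np.arctan(T) / np.pi)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test cutoff alpha/n_tests (n_tests >= 1)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / n_tests


def classify_direction(
    endpoint_results: Dict[str, MRResult],
    endpoint_alpha: float = 0.0125,
    orientation: Optional[Dict[str, float]] = None,
) -> str:
    """Directional-consistency verdict across the four kidney endpoints.

    Each endpoint's beta is oriented onto a common kidney-benefit axis;
    among endpoints significant at ``endpoint_alpha``, the protein is
    ``protective`` if every oriented effect is positive, ``detrimental`` if
    all negative, ``inconsistent`` if mixed, and ``indeterminate`` if no
    endpoint is significant or any endpoint result is missing.
    """
    orientation = orientation or ENDPOINT_ORIENTATION
    if any(k not in endpoint_results or endpoint_results[k] is None for k in orientation):
        return "indeterminate"
    oriented = []
    for name, sign in orientation.items():
        res = endpoint_results[name]
        if res.pvalue < endpoint_alpha:
            oriented.append(sign * res.beta)
    if not oriented:
        return "indeterminate"
    if all(v > 0 for v in oriented):
        return "protective"
    if all(v < 0 for v in oriented):
        return "detrimental"
    return "inconsistent"


def replicate(
    instrument_sets: Dict[str, InstrumentSet],
    n_proteins_attempted: int,
    alpha: float = 0.05,
) -> tuple[float, bool, Dict[str, MRResult]]:
    """External-replication verdict for one protein.

    Runs MR against each external endpoint's harmonized instrument set,
    ACAT-combines the per-endpoint p-values, and declares replication when
    the combined p is below ``alpha / n_proteins_attempted``. Endpoints
    whose MR cannot be computed are skipped; with none computable the
    verdict is indeterminate (NaN p, False flag).
    """
    results: Dict[str, MRResult] = {}
    for name, inst in instrument_sets.items():
        if inst is None or inst.n_snp == 0:
            continue
        try:
            results[name] = run_mr(inst, outcome_name=name)
        except (ValueError, ZeroDivisionError):
            continue
    if not results:
        return float("nan"), False, results
    p = acat([r.pvalue for r in results.values()])
    cutoff = bonferroni_threshold(alpha, n_proteins_attempted)
    return p, p < cutoff, results


@dataclass
class ProteinVerdict:
    """Per-protein summary across endpoints, gates and sensitivity checks."""

    protein_id: str
    dataset_label: str
    endpoint_results: Dict[str, MRResult] = field(default_factory=dict)
    acat_p: float = float("nan")
    significant: bool = False
    direction: str = "indeterminate"
    q_flag: bool = False
    egger_flag: bool = False
    coloc_pp4: float = float("nan")
    replication_acat_p: float = float("nan")
    replicated: bool = False

    @property
    def passes_all(self) -> bool:
        return (
            self.significant
            and self.direction in ("protective", "detrimental")
            and np.isfinite(self.coloc_pp4) and self.coloc_pp4 > 0.8
            and self.replicated
        )

    def to_row(self) -> dict:
        row = {
            "protein_id": self.protein_id,
            "dataset_label": self.dataset_label,
            "acat_p": self.acat_p,
            "significant": self.significant,
            "direction": self.direction,
            "q_flag": self.q_flag,
            "egger_flag": self.egger_flag,
            "coloc_pp4": self.coloc_pp4,
            "replication_acat_p": self.replication_acat_p,
            "replicated": self.replicated,
            "passes_all": self.passes_all,
        }
        for name, res in self.endpoint_results.items():
            row[f"beta_{name}"] = res.beta
            row[f"se_{name}"] = res.se
            row[f"p_{name}"] = res.pvalue
            row[f"nsnp_{name}"] = res.n_snp
        return row
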