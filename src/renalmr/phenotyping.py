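"""Kidney endpoint derivation from longitudinal records.

Implements the 2021 race-free CKD-EPI creatinine equation, persistence-based
CKD/ESKD case calling, the mixed-model annualized relative eGFR slope, and
the two-conjunct diabetes definition.

Endpoint definitions
--------------------
* baseline eGFR — first outpatient value after cohort entry.
* CKD case — two eGFR values < 60 mL/min/1.73 m² at least 90 days apart.
* ESKD case — chronic dialysis or kidney transplant code, or two eGFR
  values < 15 mL/min/1.73 m² at least 90 days apart.
* controls — event-free with ≥ 2 outpatient encounters; persons qualifying
  as neither case nor eligible control are indeterminate and excluded from
  that endpoint.
* eGFR slope — slope of log(eGFR) on time in years from a linear mixed
  model with per-person random intercept and slope, reported as %/year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ckdepi_egfr", "creatinine_from_egfr", "call_ckd", "call_eskd",
    "fit_egfr_slope", "define_diabetes", "derive_endpoints",
]

# 2021 CKD-EPI creatinine constants
_KAPPA = {"female": 0.7, "male": 0.9}
_ALPHA = {"female": -0.241, "male": -0.302}
_FEMALE_FACTOR = 1.012
_AGE_BASE = 0.9938
_SCALE = 142.0
_BETA_HIGH = -1.200


def _norm_sex(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "ifub":  # 0 = male, 1 = female
        return np.where(s.astype(bool), "female", "male")
    out = np.char.lower(s.astype(str))
    bad = ~np.isin(out, ["male", "female"])
    if bad.any():
        raise ValueError(f"unrecognized sex labels: {np.unique(out[bad])}")
    return out


def ckdepi_egfr(scr, age, sex):
    """Estimated GFR (mL/min/1.73 m²) from serum creatinine (mg/dL).

    2021 race-free CKD-EPI creatinine equation:
    ``142 · min(scr/κ, 1)^α · max(scr/κ, 1)^(−1.200) · 0.9938^age ·
    (1.012 if female)`` with κ = 0.7 (F) / 0.9 (M) and α = −0.241 (F) /
    −0.302 (M). Vectorized over all arguments.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    sexn = _norm_sex(sex)
    kappa = np.where(sexn == "female", _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(sexn == "female", _ALPHA["female"], _ALPHA["male"])
    ratio = scr / kappa
    egfr = (
        _SCALE
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** _BETA_HIGH
        * _AGE_BASE ** age
        * np.where(sexn == "female", _FEMALE_FACTOR, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def creatinine_from_egfr(egfr, age, sex):
    """Invert the CKD-EPI equation: serum creatinine giving the target eGFR.

    The equation is strictly decreasing and piecewise log-linear in
    creatinine with a knot at scr = κ, so the inverse is closed-form on each
    branch. Used by the cohort simulator to turn eGFR trajectories into lab
    values.
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")
    sexn = _norm_sex(sex)
    kappa = np.where(sexn == "female", _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(sexn == "female", _ALPHA["female"], _ALPHA["male"])
    knot = _SCALE * _AGE_BASE ** age * np.where(sexn == "female", _FEMALE_FACTOR, 1.0)
    ratio = np.where(
        egfr < knot,
        (egfr / knot) ** (1.0 / _BETA_HIGH),  # scr > kappa branch
        (egfr / knot) ** (1.0 / alpha),       # scr <= kappa branch (alpha < 0)
    )
    scr = kappa * ratio
    return scr if scr.ndim else float(scr)


def _sorted_series(series: Iterable[Tuple[float, float]]) -> np.ndarray:
    arr = np.asarray(sorted(series, key=lambda t: t[0]), dtype=float)
    return arr.reshape(-1, 2)


def _has_persistent_pair(days: np.ndarray, below: np.ndarray, gap_days: float = 90.0) -> bool:
    idx = np.flatnonzero(below)
    if idx.size < 2:
        return False
    return days[idx[-1]] - days[idx[0]] >= gap_days


def call_ckd(
    egfr_series: Iterable[Tuple[float, float]],
    n_encounters: int = 2,
    threshold: float = 60.0,
    gap_days: float = 90.0,
) -> str:
    """CKD status from an eGFR series of (day, value) pairs.

    Case: two values below 60 separated by >= 90 days. Control: no
    qualifying pair and >= 2 encounters. Otherwise indeterminate.
    Input order is irrelevant (sorted internally); an empty series is
    indeterminate.
    """
    arr = _sorted_series(egfr_series)
    if arr.shape[0] == 0:
        return "indeterminate"
    if _has_persistent_pair(arr[:, 0], arr[:, 1] < threshold, gap_days):
        return "case"
    if n_encounters >= 2:
        return "control"
    return "indeterminate"


def call_eskd(
    egfr_series: Iterable[Tuple[float, float]],
    procedure_events: Sequence[str] = (),
    n_encounters: int = 2,
    gap_days: float = 90.0,
) -> str:
    """ESKD status: dialysis/transplant event, or two eGFR < 15 ≥90 days apart."""
    events = {str(e).lower() for e in procedure_events}
    if events & {"dialysis", "transplant"}:
        return "case"
    arr = _sorted_series(egfr_series)
    if arr.shape[0] and _has_persistent_pair(arr[:, 0], arr[:, 1] < 15.0, gap_days):
        return "case"
    if arr.shape[0] == 0 and not events:
        return "indeterminate"
    if n_encounters >= 2:
        return "control"
    return "indeterminate"


@dataclass
class SlopeFit:
    """Per-person annualized relative eGFR slopes plus model summary."""

    slopes: pd.Series              # %/year, indexed by person id
    fixed_slope: float             # population mean slope, %/year
    slope_sd: float                # SD of random slopes, %/year
    resid_sd: float                # residual SD on the log-eGFR scale
    n_excluded: int                # persons with < 2 measurements
    excluded_ids: list
    method: str                    # "mixed" or "ols_fallback"


def _per_person_ols(kept: pd.DataFrame) -> tuple[pd.Series, float]:
    slopes = {}
    rss = 0.0
    for pid, grp in kept.groupby("person_id"):
        coef = np.polyfit(grp["years"], grp["log_egfr"], 1)
        slopes[pid] = coef[0] * 100.0
        rss += float(np.sum((np.polyval(coef, grp["years"]) - grp["log_egfr"]) ** 2))
    return pd.Series(slopes), rss


def fit_egfr_slope(labs: pd.DataFrame, min_visits: int = 2,
                   engine: str = "fast") -> SlopeFit:
    """Fit log(eGFR) ~ time with random intercepts and slopes per person.

    Parameters
    ----------
    labs : DataFrame with columns ``person_id``, ``years`` (time from entry),
        ``egfr``. Persons with fewer than ``min_visits`` measurements are
        excluded and listed in the result.
    engine : "fast" uses the package's batched ML implementation
        (:mod:`renalmr._lmm`); "statsmodels" uses MixedLM (REML). The two
        agree on shared fixtures (test suite) but the fast engine scales to
        repeated large synthetic cohorts.

    Returns
    -------
    SlopeFit with per-person slopes ``(fixed + BLUP) * 100`` in %/year.

    Exactly linear noise-free data short-circuits to per-person OLS (the
    mixed model is degenerate there); a singular or non-convergent mixed
    model falls back to per-person OLS with a warning, flagged in
    ``method``.
    """
    counts = labs.groupby("person_id").size()
    excluded = counts[counts < min_visits].index.tolist()
    kept = labs[~labs["person_id"].isin(excluded)].copy()
    if kept.empty:
        raise ValueError("no person has enough measurements for slope fitting")
    kept["log_egfr"] = np.log(kept["egfr"].to_numpy(dtype=float))

    ids = kept["person_id"].to_numpy()
    t = kept["years"].to_numpy(dtype=float)
    y = kept["log_egfr"].to_numpy(dtype=float)

    ols_slopes, ols_rss = _per_person_ols(kept)
    if ols_rss <= 1e-18 * len(kept):
        # noise-free per-person linear data: slopes are exact
        slopes = ols_slopes
        fixed = float(slopes.mean()) / 100.0
        slope_sd = float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0
        resid_sd = 0.0
        method = "exact"
    elif engine == "statsmodels":
        try:
            import statsmodels.formula.api as smf

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    "log_egfr ~ years", kept, groups=kept["person_id"], re_formula="~years"
                )
                fit = model.fit(reml=True, method="lbfgs")
            if not np.all(np.isfinite(fit.params)):
                raise np.linalg.LinAlgError("non-finite mixed-model parameters")
            fixed = float(fit.params["years"])
            blup = pd.Series({pid: float(eff.get("years", 0.0))
                              for pid, eff in fit.random_effects.items()})
            slopes = (fixed + blup) * 100.0
            cov_re = np.asarray(fit.cov_re)
            slope_sd = float(np.sqrt(max(cov_re[-1, -1], 0.0))) * 100.0
            resid_sd = float(np.sqrt(fit.scale))
            method = "mixed"
        except Exception:
            warnings.warn("mixed model failed; falling back to per-person OLS slopes")
            slopes = ols_slopes
            fixed = float(slopes.mean()) / 100.0
            slope_sd = float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0
            resid_sd = float("nan")
            method = "ols_fallback"
    else:
        from ._lmm import fit_random_slope_model

        try:
            fit = fit_random_slope_model(ids, t, y)
            fixed = fit.fixed_slope
            slopes = pd.Series(
                {pid: (fixed + dev[1]) * 100.0 for pid, dev in fit.blups.items()}
            )
            slope_sd = float(np.sqrt(max(fit.psi[1, 1], 0.0))) * 100.0
            resid_sd = float(np.sqrt(fit.sigma2))
            method = "mixed"
        except np.linalg.LinAlgError:
            warnings.warn("mixed model failed; falling back to per-person OLS slopes")
            slopes = ols_slopes
            fixed = float(slopes.mean()) / 100.0
            slope_sd = float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0
            resid_sd = float("nan")
            method = "ols_fallback"

    slopes.index.name = "person_id"
    return SlopeFit(
        slopes=slopes.sort_index(),
        fixed_slope=fixed * 100.0,
        slope_sd=slope_sd,
        resid_sd=resid_sd,
        n_excluded=len(excluded),
        excluded_ids=excluded,
        method=method,
    )


def define_diabetes(
    phecode_events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diabetes_codes: Sequence[str] = ("250",),
    diabetes_drugs: Sequence[str] = ("metformin", "insulin"),
) -> pd.Series:
    """Two-conjunct diabetes definition per person.

    Conjunct 1: a single diabetes code at a face-to-face PCP outpatient
    visit (``pcp_visit`` flag), or diabetes codes on two different days.
    Conjunct 2: an outpatient prescription of a diabetes drug at any time.

    ``phecode_events`` needs columns person_id, day, phecode and optionally
    pcp_visit; ``prescriptions`` needs person_id, drug.
    """
    ev = phecode_events.copy()
    ev["phecode"] = ev["phecode"].astype(str)
    is_dm = ev["phecode"].str.startswith(tuple(str(c) for c in diabetes_codes))
    dm_ev = ev[is_dm]

    two_days = dm_ev.groupby("person_id")["day"].nunique() >= 2
    if "pcp_visit" in dm_ev.columns:
        pcp = dm_ev.groupby("person_id")["pcp_visit"].any()
    else:
        pcp = pd.Series(dtype=bool)
    conj1_ids = set(two_days[two_days].index) | set(pcp[pcp].index)

    rx = prescriptions.copy()
    drug_ok = rx["drug"].astype(str).str.lower().isin([d.lower() for d in diabetes_drugs])
    conj2_ids = set(rx.loc[drug_ok, "person_id"])

    all_ids = sorted(
        set(phecode_events["person_id"]) | set(prescriptions["person_id"])
    )
    out = pd.Series(
        [pid in conj1_ids and pid in conj2_ids for pid in all_ids],
        index=pd.Index(all_ids, name="person_id"),
        name="diabetes",
    )
    return out


def derive_endpoints(
    persons: pd.DataFrame,
    labs: pd.DataFrame,
    procedures: Optional[pd.DataFrame] = None,
    min_visits: int = 2,
) -> pd.DataFrame:
    """Derive the four kidney endpoints for a cohort.

    Parameters
    ----------
    persons : DataFrame with person_id, age, sex, n_encounters.
    labs : long DataFrame with person_id, day, scr (serum creatinine mg/dL).
    procedures : optional DataFrame with person_id, day, event
        (dialysis/transplant).

    Returns
    -------
    DataFrame indexed by person_id with baseline_egfr, egfr_slope,
    ckd_status, eskd_status. Slope is NaN for persons excluded from the
    mixed model.
    """
    persons = persons.set_index("person_id") if "person_id" in persons.columns else persons
    labs = labs.sort_values(["person_id", "day"]).copy()
    merged = labs.merge(
        persons[["age", "sex"]], left_on="person_id", right_index=True, how="left"
    )
    merged["egfr"] = ckdepi_egfr(
        merged["scr"].to_numpy(),
        # age at measurement
        merged["age"].to_numpy() + merged["day"].to_numpy() / 365.25,
        merged["sex"].to_numpy(),
    )
    merged["years"] = merged["day"] / 365.25

    proc_map: dict = {}
    if procedures is not None and len(procedures):
        proc_map = procedures.groupby("person_id")["event"].apply(list).to_dict()

    rows = {}
    for pid, grp in merged.groupby("person_id"):
        series = list(zip(grp["day"], grp["egfr"]))
        n_enc = int(persons.loc[pid, "n_encounters"]) if "n_encounters" in persons.columns else len(series)
        rows[pid] = {
            "baseline_egfr": float(grp["egfr"].iloc[0]),
            "ckd_status": call_ckd(series, n_encounters=n_enc),
            "eskd_status": call_eskd(series, proc_map.get(pid, ()), n_encounters=n_enc),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "person_id"

    slope_fit = fit_egfr_slope(
        merged.rename(columns={"egfr": "egfr"})[["person_id", "years", "egfr"]],
        min_visits=min_visits,
    )
    out["egfr_slope"] = slope_fit.slopes.reindex(out.index)
    out.attrs["slope_fit_method"] = slope_fit.method
    return out
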