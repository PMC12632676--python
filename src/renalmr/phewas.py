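"""Phenome-wide association scans and organ-domain pleiotropy tiers.

Case/control calling follows the phecode convention: two or more mapped
codes make a case, zero codes a control, exactly one code is excluded.
Phecodes with fewer than 200 cases or 200 controls are skipped as
unstable. A protein's pleiotropy tier is computed from the union of
significant hits over its conditionally independent cis instruments:
kidney-domain-only hits sit at the apex of the specificity pyramid,
kidney-plus-k-domain and extra-renal-only profiles below, and proteins
with no hits are kept separate (absence of hits is not evidence of
kidney specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import bonferroni_threshold
from .assoc import scan_binary

__all__ = [
    "CLINICAL_DOMAINS", "synthetic_phecode_catalog", "define_case_control",
    "run_phewas", "classify_pleiotropy", "PleiotropyProfile",
]

#: 11 clinical domains plus the curated kidney domain
CLINICAL_DOMAINS = [
    "kidney", "circulatory", "endocrine_metabolic", "digestive",
    "respiratory", "neurological", "mental", "musculoskeletal",
    "dermatologic", "hematopoietic", "genitourinary_other", "neoplasms",
]


def synthetic_phecode_catalog(n_phecodes: int = 1020,
                              kidney_fraction: float = 0.04,
                              seed: int = 12345) -> pd.DataFrame:
    """A synthetic phecode catalog spanning the 12 clinical domains.

    Stand-in for a curated phecode map (not a real ICD→phecode table);
    default size 1,020. Each phecode has exactly one domain and a set of
    mapped diagnostic codes.
    """
    rng = np.random.default_rng(seed)
    n_kidney = max(1, int(round(n_phecodes * kidney_fraction)))
    domains = ["kidney"] * n_kidney + list(
        rng.choice(CLINICAL_DOMAINS[1:], size=n_phecodes - n_kidney)
    )
    rows = []
    for i, dom in enumerate(domains):
        code = f"{400 + i // 10}.{i % 10}"
        rows.append({
            "phecode": code,
            "label": f"{dom} condition {i}",
            "domain": dom,
            "mapped_codes": f"ICD{i:04d}a;ICD{i:04d}b",
        })
    return pd.DataFrame(rows)


def define_case_control(phecode: str, events: pd.DataFrame,
                        person_ids: Iterable) -> pd.Series:
    """Per-person status for one phecode: 1=case (>=2 codes), 0=control
    (0 codes), NaN=excluded (exactly 1 code)."""
    ev = events[events["phecode"].astype(str) == str(phecode)]
    counts = ev.groupby("person_id").size()
    idx = pd.Index(list(person_ids), name="person_id")
    n = counts.reindex(idx, fill_value=0)
    status = pd.Series(np.where(n >= 2, 1.0, np.where(n == 0, 0.0, np.nan)),
                       index=idx, name=str(phecode))
    return status


def run_phewas(
    dosage: np.ndarray,
    catalog: pd.DataFrame,
    events: pd.DataFrame,
    persons: pd.DataFrame,
    covariates: Optional[np.ndarray] = None,
    variant_label: str = "variant",
    min_count: int = 200,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Logistic scan of one variant against every eligible phecode.

    Returns one row per catalog phecode with beta/se/p for eligible ones
    and an exclusion reason otherwise. The Bonferroni cutoff is
    ``alpha / n_phecodes`` with n taken from the loaded catalog.
    """
    g = np.asarray(dosage, dtype=float)
    ids = persons["person_id"].to_numpy()
    n_phecodes = len(catalog)
    cutoff = bonferroni_threshold(alpha, n_phecodes)

    counts = events.groupby(["phecode", "person_id"]).size()
    variants_df = pd.DataFrame({
        "variant_id": [variant_label], "chrom": "NA", "pos": 0,
        "effect_allele": "A", "other_allele": "G",
    })

    rows = []
    for _, prow in catalog.iterrows():
        code = str(prow["phecode"])
        base = {
            "variant": variant_label, "phecode": code, "domain": prow["domain"],
            "n_case": 0, "n_control": 0, "beta": np.nan, "se": np.nan,
            "pvalue": np.nan, "significant": False, "excluded_reason": "",
        }
        if code in counts.index.get_level_values(0):
            c = counts.loc[code].reindex(ids, fill_value=0).to_numpy()
        else:
            c = np.zeros(len(ids), dtype=int)
        status = np.where(c >= 2, 1.0, np.where(c == 0, 0.0, np.nan))
        keep = np.isfinite(status)
        n_case = int(np.nansum(status == 1.0))
        n_control = int(np.sum(status[keep] == 0.0))
        base["n_case"], base["n_control"] = n_case, n_control
        if n_case < min_count or n_control < min_count:
            base["excluded_reason"] = "min_count"
            rows.append(base)
            continue
        cov = covariates[keep] if covariates is not None else None
        ss = scan_binary(status[keep], g[keep, None], cov, variants_df,
                         trait_name=code)
        rec = ss.records.iloc[0]
        base.update(beta=rec["beta"], se=rec["se"], pvalue=rec["pvalue"])
        base["significant"] = bool(np.isfinite(rec["pvalue"]) and rec["pvalue"] < cutoff)
        if not np.isfinite(rec["beta"]):
            base["excluded_reason"] = "model_failure"
        rows.append(base)
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_cutoff"] = cutoff
    out.attrs["n_phecodes"] = n_phecodes
    return out


@dataclass
class PleiotropyProfile:
    protein_id: str
    hit_phecodes: list
    hit_domains: list
    tier: str  # kidney_only | kidney_plus_k | extra_renal_only | no_hits


def classify_pleiotropy(protein_id: str,
                        phewas_tables: Sequence[pd.DataFrame]) -> PleiotropyProfile:
    """Tier a protein by the union of significant hits over its instruments.

    kidney_only: hits confined to the kidney domain; kidney_plus_k: kidney
    hits plus k extra-renal domains; extra_renal_only: hits but none renal;
    no_hits: nothing significant (explicitly distinct from kidney
    specificity — it may simply reflect small variant effects).
    """
    hits = pd.concat(phewas_tables, ignore_index=True) if phewas_tables else pd.DataFrame()
    if len(hits):
        hits = hits[hits["significant"].astype(bool)]
    if len(hits) == 0:
        return PleiotropyProfile(protein_id, [], [], "no_hits")
    phecodes = sorted(hits["phecode"].astype(str).unique())
    domains = sorted(hits["domain"].astype(str).unique())
    extra = [d for d in domains if d != "kidney"]
    if "kidney" in domains and not extra:
        tier = "kidney_only"
    elif "kidney" in domains:
        tier = f"kidney_plus_{len(extra)}"
    else:
        tier = "extra_renal_only"
    return PleiotropyProfile(protein_id, phecodes, domains, tier)
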