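"""cis-pQTL instrument selection and exposure/outcome harmonization.

Selection keeps variants within an inclusive ±window of the gene's TSS with
minor allele frequency above the floor, then greedily LD-clumps them in
p-value order so instruments are approximately conditionally independent.
Harmonization aligns outcome effects to the exposure's effect allele,
resolves palindromic variants by allele frequency, substitutes LD proxies
for variants missing from the outcome, and keeps an exact accounting of
every input variant's fate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import SummaryStats

__all__ = ["LDReference", "InstrumentSet", "select_cis_pqtls", "clump", "harmonize"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


class LDReference:
    """Pairwise LD (signed r) lookup backed by a dosage matrix."""

    def __init__(self, dosages: np.ndarray, variant_ids: pd.Series | list):
        self._ids = list(variant_ids)
        self._index = {v: i for i, v in enumerate(self._ids)}
        G = np.asarray(dosages, dtype=float)
        G = G - G.mean(axis=0)
        norm = np.sqrt(np.einsum("ij,ij->j", G, G))
        norm[norm == 0] = np.nan
        self._G = G / norm

    def r(self, a: str, b: str) -> float:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return np.nan
        return float(self._G[:, ia] @ self._G[:, ib])

    def r2(self, a: str, b: str) -> float:
        r = self.r(a, b)
        return r * r

    def best_proxy(self, target: str, candidates: list[str], r2_min: float) -> Optional[tuple[str, float]]:
        """Highest-r² candidate with r² >= r2_min, or None."""
        best, best_r = None, 0.0
        for c in candidates:
            if c == target:
                continue
            r = self.r(target, c)
            if np.isfinite(r) and r * r >= r2_min and r * r > best_r * best_r:
                best, best_r = c, r
        return (best, best_r) if best is not None else None


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effect pairs for one protein's cis-pQTLs."""

    protein_id: str
    dataset_label: str
    snps: pd.DataFrame  # variant_id, beta_exp, se_exp, beta_out, se_out, eaf, proxy_used
    accounting: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf", "proxy_used"]
        missing = [c for c in required if c not in self.snps.columns]
        if missing:
            raise ValueError(f"instrument table missing columns: {missing}")
        if self.snps["variant_id"].duplicated().any():
            raise ValueError("duplicate variants in instrument set")
        if len(self.snps) and ((self.snps["se_exp"] <= 0) | (self.snps["se_out"] <= 0)).any():
            raise ValueError("all standard errors must be > 0")

    @property
    def n_snp(self) -> int:
        return len(self.snps)


def select_cis_pqtls(
    exposure: SummaryStats,
    gene: dict | pd.Series,
    maf_min: float = 0.01,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Candidate cis variants: |pos − TSS| ≤ window (inclusive), MAF > maf_min.

    Returns the matching exposure records (possibly empty, in which case the
    protein is skipped by callers).
    """
    rec = exposure.records
    tss = int(gene["tss"])
    chrom = str(gene["chrom"])
    maf = np.minimum(rec["eaf"], 1.0 - rec["eaf"])
    sel = (
        (rec["chrom"].astype(str) == chrom)
        & (np.abs(rec["pos"] - tss) <= window_bp)
        & (maf > maf_min)
    )
    return rec[sel].reset_index(drop=True)


def clump(
    records: pd.DataFrame,
    ld: LDReference,
    r2_max: float = 0.1,
    p_col: str = "pvalue",
) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping: keep a variant only if its r² with
    every already-kept variant is below ``r2_max``. Unknown LD counts as
    linked (conservative)."""
    order = records.dropna(subset=[p_col]).sort_values(p_col, kind="stable")
    kept: list[int] = []
    kept_ids: list[str] = []
    for idx, row in order.iterrows():
        vid = row["variant_id"]
        ok = True
        for kid in kept_ids:
            r2 = ld.r2(vid, kid)
            if not np.isfinite(r2) or r2 >= r2_max:
                ok = False
                break
        if ok:
            kept.append(idx)
            kept_ids.append(vid)
    return records.loc[kept].reset_index(drop=True)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: Optional[LDReference] = None,
    r2_min: float = 0.9,
    maf_tol: float = 0.02,
    palindrome_eaf_margin: float = 0.08,
    protein_id: str = "protein",
    dataset_label: str = "dataset",
) -> InstrumentSet:
    """Align outcome records to the exposure's effect alleles.

    Per exposure variant (matched on chrom:pos):

    * same allele orientation → keep as is;
    * swapped effect/other alleles → negate the outcome beta (flip);
    * palindromic (A/T, C/G) variants → resolved by allele frequency when
      both sides are away from 0.5 (margin ``palindrome_eaf_margin``),
      otherwise dropped;
    * absent from the outcome → substitute the best LD proxy with
      r² ≥ ``r2_min`` and |MAF difference| ≤ ``maf_tol`` (sign-aligned via
      the LD correlation), flagged ``proxy_used``;
    * anything else → dropped.

    The accounting dict satisfies
    ``n_input == retained + flipped + proxied + dropped`` exactly, and the
    operation is idempotent: harmonizing its own output changes nothing.
    """
    out_by_pos: dict[tuple, pd.Series] = {}
    for _, row in outcome.iterrows():
        out_by_pos[(str(row["chrom"]), int(row["pos"]))] = row
    outcome_ids = list(outcome["variant_id"])
    out_by_id = {row["variant_id"]: row for _, row in outcome.iterrows()}

    rows = []
    acct = {"n_input": len(exposure), "retained": 0, "flipped": 0, "proxied": 0, "dropped": 0}
    for _, ex in exposure.iterrows():
        key = (str(ex["chrom"]), int(ex["pos"]))
        ea, oa = str(ex["effect_allele"]), str(ex["other_allele"])
        ov = out_by_pos.get(key)
        if ov is None:
            # proxy substitution
            if ld is not None:
                found = ld.best_proxy(ex["variant_id"], outcome_ids, r2_min)
                if found is not None:
                    pid_, r = found
                    pv = out_by_id[pid_]
                    maf_e = min(ex["eaf"], 1 - ex["eaf"])
                    maf_p = min(pv["eaf"], 1 - pv["eaf"])
                    if abs(maf_e - maf_p) <= maf_tol and np.isfinite(pv["beta"]):
                        sign = 1.0 if r >= 0 else -1.0
                        rows.append((ex["variant_id"], ex["beta"], ex["se"],
                                     sign * pv["beta"], pv["se"], ex["eaf"], True))
                        acct["proxied"] += 1
                        continue
            acct["dropped"] += 1
            continue
        o_ea, o_oa = str(ov["effect_allele"]), str(ov["other_allele"])
        if not np.isfinite(ov["beta"]) or not np.isfinite(ov["se"]):
            acct["dropped"] += 1
            continue
        if _is_palindromic(ea, oa):
            if {o_ea, o_oa} != {ea, oa}:
                acct["dropped"] += 1
                continue
            f_e, f_o = float(ex["eaf"]), float(ov["eaf"])
            if abs(f_e - 0.5) <= palindrome_eaf_margin or abs(f_o - 0.5) <= palindrome_eaf_margin:
                acct["dropped"] += 1  # ambiguous strand
                continue
            # align by frequency: if the outcome's effect-allele frequency is on
            # the other side of 0.5, its labelled effect allele is the exposure's
            # other allele (possibly on the opposite strand)
            same_side = (f_e - 0.5) * ((f_o if o_ea == ea or o_ea == _COMPLEMENT[ea] else 1 - f_o) - 0.5) > 0
            beta_o = ov["beta"] if same_side else -ov["beta"]
            rows.append((ex["variant_id"], ex["beta"], ex["se"], beta_o, ov["se"], ex["eaf"], False))
            acct["retained" if same_side else "flipped"] += 1
            continue
        if (o_ea, o_oa) == (ea, oa):
            rows.append((ex["variant_id"], ex["beta"], ex["se"], ov["beta"], ov["se"], ex["eaf"], False))
            acct["retained"] += 1
        elif (o_ea, o_oa) == (oa, ea):
            rows.append((ex["variant_id"], ex["beta"], ex["se"], -ov["beta"], ov["se"], ex["eaf"], False))
            acct["flipped"] += 1
        elif (_COMPLEMENT.get(o_ea), _COMPLEMENT.get(o_oa)) == (ea, oa):
            rows.append((ex["variant_id"], ex["beta"], ex["se"], ov["beta"], ov["se"], ex["eaf"], False))
            acct["retained"] += 1
        elif (_COMPLEMENT.get(o_ea), _COMPLEMENT.get(o_oa)) == (oa, ea):
            rows.append((ex["variant_id"], ex["beta"], ex["se"], -ov["beta"], ov["se"], ex["eaf"], False))
            acct["flipped"] += 1
        else:
            acct["dropped"] += 1

    snps = pd.DataFrame(
        rows, columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf", "proxy_used"],
    )
    return InstrumentSet(protein_id=protein_id, dataset_label=dataset_label,
                         snps=snps, accounting=acct)
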