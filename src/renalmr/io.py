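"""Summary-statistics container and delimited-text I/O.

All tables are tab-delimited text with a header row; readers match columns
by name so column order is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: canonical per-variant record columns
SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue",
]


@dataclass
class SummaryStats:
    """One trait's per-variant association results.

    Attributes
    ----------
    trait_name : str
    trait_type : {"quantitative", "binary"}
    n : int
        Analyzed sample size.
    n_case, n_control : int or None
        Only for binary traits.
    records : pandas.DataFrame
        One row per variant with columns ``SUMSTAT_COLUMNS``; positions are
        1-based, ``eaf`` is the effect-allele frequency in (0, 1), ``se`` > 0
        and ``pvalue`` in (0, 1].
    """

    trait_name: str
    trait_type: str
    n: int
    records: pd.DataFrame
    n_case: Optional[int] = None
    n_control: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"trait_type must be quantitative|binary, got {self.trait_type}")
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        self.records = self.records.loc[:, SUMSTAT_COLUMNS].reset_index(drop=True)

    def validate(self) -> None:
        r = self.records.dropna(subset=["beta", "se", "pvalue"])
        if (r["se"] <= 0).any():
            raise ValueError("all standard errors must be > 0")
        if ((r["pvalue"] <= 0) | (r["pvalue"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if ((self.records["eaf"] <= 0) | (self.records["eaf"] >= 1)).any():
            raise ValueError("allele frequencies must lie in (0, 1)")
        if self.records["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids")

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"#trait_name={self.trait_name}\n")
            fh.write(f"#trait_type={self.trait_type}\n")
            fh.write(f"#n={self.n}\n")
            if self.trait_type == "binary":
                fh.write(f"#n_case={self.n_case}\n#n_control={self.n_control}\n")
            self.records.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SummaryStats":
        meta = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key] = val
                skip += 1
        records = pd.read_csv(path, sep="\t", skiprows=skip)
        return cls(
            trait_name=meta.get("trait_name", Path(path).stem),
            trait_type=meta.get("trait_type", "quantitative"),
            n=int(meta.get("n", 0)),
            n_case=int(meta["n_case"]) if "n_case" in meta and meta["n_case"] != "None" else None,
            n_control=int(meta["n_control"]) if "n_control" in meta and meta["n_control"] != "None" else None,
            records=records,
        )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def normal_p_from_z(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal p-value from a z statistic, floored away from 0."""
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.nextafter(0, 1), 1.0)
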