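"""Configuration objects for simulation and pipeline runs.

Every threshold used anywhere in the pipeline lives here with its default,
so a run is fully described by (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its documented domain."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The generator produces a cis region of correlated variants, a circulating
    protein under cis genetic control, kidney outcomes downstream of the
    protein (or of a distinct variant when ``shared_causal`` is False), and
    longitudinal creatinine trajectories.

    Parameters
    ----------
    n_individuals : int
        Cohort size (>= 2).
    n_variants_region : int
        Number of variants in the simulated cis region.
    maf_range : (float, float)
        Minor allele frequencies drawn uniformly from this open interval.
    ld_decay : float
        AR(1) haplotype-correlation decay rate per kilobase; adjacent-variant
        latent correlation is ``exp(-ld_decay * distance_kb)``. 0 gives
        independent variants.
    causal_protein_effect : float
        Per-allele effect of the causal cis variant on protein level
        (protein is on an SD scale with unit-variance noise).
    protein_outcome_effect : float
        Effect per protein SD on the latent kidney-burden scale.
    shared_causal : bool
        If True the outcome signal in the region flows through the protein's
        causal variant (colocalizing architecture); if False the outcome gets
        a direct effect from a *different* variant and none through protein.
    confounder_effect : float
        Effect of a standard-normal confounder on the outcome; the same
        confounder also loads on the protein, violating naive observational
        estimates while leaving the genetic instruments valid.
    slope_mean, slope_sd : float
        Mean and SD of the per-person annualized relative eGFR slope, %/year.
    seed : int
        Seed for all randomness; a fixed seed reproduces the cohort exactly.
    """

    n_individuals: int = 4000
    n_variants_region: int = 60
    maf_range: Tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.05
    causal_protein_effect: float = 0.5
    protein_outcome_effect: float = 0.6
    shared_causal: bool = True
    confounder_effect: float = 0.3
    slope_mean: float = -2.0
    slope_sd: float = 2.0
    seed: int = 0

    # region geometry
    region_start: int = 1_000_000
    variant_spacing_bp: int = 5_000
    # protein/outcome nuisance parameters
    confounder_protein_effect: float = 0.3
    noise_sd: float = 1.0
    direct_variant_effect: Optional[float] = None  # default: product of the two effects
    binary_baseline_logit: float = -2.2
    # longitudinal trajectory parameters
    baseline_egfr_geo_mean: float = 85.0
    baseline_egfr_log_sd: float = 0.25
    burden_egfr_effect: float = 0.2    # log-eGFR drop per burden SD
    burden_slope_effect: float = 1.2   # extra %/yr decline per burden SD
    creatinine_cv: float = 0.05        # multiplicative measurement noise on serum creatinine
    # rapid-progression mixture (drives ESKD events); None disables it
    rapid_fraction_logit: Optional[float] = None
    rapid_burden_effect: float = 1.0
    rapid_slope: float = -45.0         # %/year for rapid progressors
    n_visits: int = 6
    followup_years: float = 5.0
    female_fraction: float = 0.074     # predominantly male veteran cohort
    n_pcs: int = 10

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("n_individuals must be >= 2")
        if self.n_variants_region < 1:
            raise ConfigurationError("n_variants_region must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("maf_range must lie in the open interval (0, 1)")
        if self.ld_decay < 0:
            raise ConfigurationError("ld_decay must be >= 0")
        if self.slope_sd < 0:
            raise ConfigurationError("slope_sd must be >= 0")
        if self.creatinine_cv < 0:
            raise ConfigurationError("creatinine_cv must be >= 0")
        if self.n_visits < 1:
            raise ConfigurationError("n_visits must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class RunConfig:
    """Thresholds and knobs for a full pipeline run.

    Defaults follow the analysis conventions of the screening framework:
    cis window ±500 kb inclusive, MAF > 1%, proxy r² ≥ 0.9 with MAF
    difference ≤ 0.02, per-dataset Bonferroni at alpha 0.05, per-endpoint
    consistency threshold 0.0125, colocalization pass at PP4 > 0.8, and a
    PPI confidence floor of 0.9 for secondary druggability.
    """

    scenario: str = "causal"
    seed: int = 0
    output_dir: str = "renalmr_out"

    window_bp: int = 500_000
    maf_min: float = 0.01
    r2_min: float = 0.9
    maf_tol: float = 0.02
    clump_r2: float = 0.1
    alpha: float = 0.05
    endpoint_alpha: float = 0.0125
    pp4_min: float = 0.8
    score_min: float = 0.9
    phewas_pc_count: int = 5
    gwas_pc_count: int = 10
    phewas_min_count: int = 200

    n_proteins: int = 5
    # pipeline study conditions include the rapid-progression mixture so the
    # cohort actually produces ESKD events
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(rapid_fraction_logit=-3.5)
    )

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("maf_min", 0.0, 0.5), ("r2_min", 0.0, 1.0), ("maf_tol", 0.0, 0.5),
            ("clump_r2", 0.0, 1.0), ("alpha", 0.0, 1.0), ("endpoint_alpha", 0.0, 1.0),
            ("pp4_min", 0.0, 1.0), ("score_min", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.window_bp < 0:
            raise ConfigurationError("window_bp must be >= 0")
        if self.scenario not in {"null", "causal", "coloc-shared", "coloc-distinct"}:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
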