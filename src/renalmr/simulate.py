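"""Synthetic cohorts and region-level summary statistics with known truth.

The generator emulates the data a proteome-to-phenome kidney screen
consumes: a cis region of correlated variants, a circulating protein under
cis genetic control, kidney outcomes downstream of the protein (or of a
distinct variant, for colocalization scenarios), longitudinal serum
creatinine with person-level decline, phecode event tables, and fixture
gene-annotation / PPI / drug-target tables.

LD model: haplotypes are thresholded latent Gaussian AR(1) processes with
correlation ``exp(-ld_decay * distance_kb)`` between neighbours; two
independent haplotypes per person give Hardy-Weinberg dosages in [0, 2].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, SimulationConfig
from .io import SummaryStats
from .phenotyping import creatinine_from_egfr

__all__ = [
    "simulate_genotypes", "simulate_protein_and_outcome",
    "simulate_longitudinal_egfr", "simulate_persons", "simulate_cohort",
    "simulate_region_summary_stats", "simulate_phecode_events",
    "make_gene_annotation", "make_drug_target_tables", "Cohort",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def _region_layout(config: SimulationConfig, rng: np.random.Generator,
                   chrom: str = "1") -> pd.DataFrame:
    m = config.n_variants_region
    pos = config.region_start + config.variant_spacing_bp * np.arange(m)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    return pd.DataFrame({
        "variant_id": [f"{chrom}:{p}:{a}:{b}" for p, a, b in zip(pos, ea, oa)],
        "chrom": chrom,
        "pos": pos.astype(np.int64),
        "effect_allele": ea,
        "other_allele": oa,
        "maf_target": maf,
    })


def _sample_haplotypes(n_hap: int, maf: np.ndarray, pos: np.ndarray,
                       ld_decay: float, rng: np.random.Generator) -> np.ndarray:
    """Thresholded latent AR(1) Gaussians: one row per haplotype."""
    m = maf.shape[0]
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        dist_kb = np.diff(pos) / 1000.0
        # ld_decay == 0 disables LD entirely (independent variants); positive
        # values give exp(-ld_decay * distance_kb) neighbour correlation
        rho = np.zeros_like(dist_kb) if ld_decay == 0 else np.exp(-ld_decay * dist_kb)
        eps = rng.standard_normal((n_hap, m - 1))
        for j in range(1, m):
            r = rho[j - 1]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j - 1]
    thresh = stats.norm.ppf(maf)
    return (z < thresh).astype(np.int8)


def simulate_genotypes(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    region: Optional[pd.DataFrame] = None,
    chrom: str = "1",
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Draw a dosage matrix (n_individuals × n_variants) and variant metadata.

    Passing a pre-built ``region`` layout (from a previous call) re-uses the
    same variants, positions, alleles and target MAFs, so that independent
    cohorts can be genotyped on one shared region — the two-sample setting.
    Realized effect-allele frequencies are recorded per cohort.
    """
    if config.n_individuals < 2:
        raise ConfigurationError("n_individuals must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if region is None:
        region = _region_layout(config, rng, chrom=chrom)
    maf = region["maf_target"].to_numpy()
    pos = region["pos"].to_numpy()
    h1 = _sample_haplotypes(config.n_individuals, maf, pos, config.ld_decay, rng)
    h2 = _sample_haplotypes(config.n_individuals, maf, pos, config.ld_decay, rng)
    dosages = (h1 + h2).astype(np.float64)
    variants = region.copy()
    variants["eaf"] = dosages.mean(axis=0) / 2.0
    return dosages, variants


@dataclass
class ProteinOutcome:
    """Ground truth from one protein/outcome draw."""

    protein: np.ndarray
    quantitative: np.ndarray     # latent kidney burden, continuous outcome
    binary: np.ndarray
    confounder: np.ndarray
    causal_index: int            # variant driving the protein
    direct_index: Optional[int]  # variant with a direct outcome effect (distinct scenario)


def simulate_protein_and_outcome(
    dosages: np.ndarray,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    causal_index: Optional[int] = None,
) -> ProteinOutcome:
    """Protein and outcomes with the configured causal architecture.

    protein = causal_effect·G_causal + confounder loading + noise;
    quantitative outcome = protein_outcome_effect·protein +
    confounder_effect·confounder + noise. With ``shared_causal=False`` the
    outcome instead receives a direct per-allele effect from a different
    variant and nothing flows through the protein (the distinct-causal
    colocalization scenario). The binary outcome applies a logistic link to
    the same linear predictor.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, m = dosages.shape
    if causal_index is None:
        causal_index = m // 2
    conf = rng.standard_normal(n)
    g_c = dosages[:, causal_index] - dosages[:, causal_index].mean()
    protein = (
        config.causal_protein_effect * g_c
        + config.confounder_protein_effect * conf
        + config.noise_sd * rng.standard_normal(n)
    )
    if config.shared_causal:
        lin = config.protein_outcome_effect * protein
        direct_index = None
    else:
        direct_index = (causal_index + max(1, m // 3)) % m
        if direct_index == causal_index:
            direct_index = (causal_index + 1) % m
        eff = config.direct_variant_effect
        if eff is None:
            eff = config.causal_protein_effect * config.protein_outcome_effect
        g_d = dosages[:, direct_index] - dosages[:, direct_index].mean()
        lin = eff * g_d
    quantitative = lin + config.confounder_effect * conf + config.noise_sd * rng.standard_normal(n)
    prob = 1.0 / (1.0 + np.exp(-(config.binary_baseline_logit + lin + config.confounder_effect * conf)))
    binary = (rng.uniform(size=n) < prob).astype(np.int8)
    return ProteinOutcome(protein, quantitative, binary, conf, causal_index, direct_index)


def simulate_persons(config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Demographics, ancestry PCs, and encounter counts for a cohort."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = config.n_individuals
    persons = pd.DataFrame({
        "person_id": np.arange(n),
        "age": np.clip(rng.normal(64.3, 13.8, size=n), 20, 95).round(1),
        "sex": np.where(rng.uniform(size=n) < config.female_fraction, "female", "male"),
        "n_encounters": 2 + rng.poisson(6, size=n),
    })
    few = rng.uniform(size=n) < 0.03
    persons.loc[few, "n_encounters"] = 1
    for k in range(config.n_pcs):
        persons[f"pc{k + 1}"] = rng.standard_normal(n)
    return persons


def simulate_longitudinal_egfr(
    config: SimulationConfig,
    persons: pd.DataFrame,
    burden: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    one_visit_fraction: float = 0.0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Serum-creatinine series per person plus the true simulated slopes.

    Each person's eGFR declines log-linearly at a true relative slope drawn
    from Normal(slope_mean, slope_sd) %/year, shifted by the standardized
    kidney burden; trajectories are inverted through the CKD-EPI equation
    into creatinine and multiplied by lognormal measurement noise with the
    configured CV. Persons assigned a single visit are returned with one
    row (downstream slope fitting excludes and flags them).
    """
    if config.slope_sd < 0:
        raise ConfigurationError("slope_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    n = len(persons)
    if burden is None:
        b_z = np.zeros(n)
    else:
        sd = burden.std()
        b_z = (burden - burden.mean()) / (sd if sd > 0 else 1.0)

    slopes = (
        config.slope_mean
        + config.slope_sd * rng.standard_normal(n)
        - config.burden_slope_effect * b_z
    )
    if config.rapid_fraction_logit is not None:
        # stylized rapid-progression mixture: a small, burden-enriched
        # fraction declines fast enough to reach ESKD within follow-up
        p_rapid = 1.0 / (1.0 + np.exp(-(config.rapid_fraction_logit
                                        + config.rapid_burden_effect * b_z)))
        rapid = rng.uniform(size=n) < p_rapid
        slopes[rapid] = config.rapid_slope
    log_e0 = (
        np.log(config.baseline_egfr_geo_mean)
        + config.baseline_egfr_log_sd * rng.standard_normal(n)
        - config.burden_egfr_effect * b_z
    )

    k = config.n_visits
    if k > 1:
        base_days = np.linspace(0, config.followup_years * 365.25, k)
        jitter = rng.uniform(-0.4, 0.4, size=(n, k)) * (base_days[1] - base_days[0])
        jitter[:, 0] = np.abs(jitter[:, 0])
        days = np.sort(np.round(base_days[None, :] + jitter).astype(int), axis=1)
    else:
        days = np.zeros((n, 1), dtype=int)
    days = np.clip(days, 0, None)

    one_visit = rng.uniform(size=n) < one_visit_fraction
    sigma = np.sqrt(np.log1p(config.creatinine_cv**2))

    rows = []
    ages = persons["age"].to_numpy(dtype=float)
    sexes = persons["sex"].to_numpy()
    ids = persons["person_id"].to_numpy()
    for i in range(n):
        d = days[i, :1] if one_visit[i] else days[i]
        t = d / 365.25
        egfr_true = np.exp(log_e0[i] + (slopes[i] / 100.0) * t)
        scr_true = creatinine_from_egfr(egfr_true, ages[i] + t, [sexes[i]] * len(t))
        scr = np.atleast_1d(scr_true) * np.exp(sigma * rng.standard_normal(len(t)) - sigma**2 / 2)
        for dd, s in zip(d, np.atleast_1d(scr)):
            rows.append((ids[i], int(dd), float(s)))
    labs = pd.DataFrame(rows, columns=["person_id", "day", "scr"])
    true_slopes = pd.Series(slopes, index=pd.Index(ids, name="person_id"), name="true_slope")
    true_slopes[one_visit] = np.nan  # insufficient data, excluded from slope truth
    return labs, true_slopes


def simulate_phecode_events(
    persons: pd.DataFrame,
    catalog: pd.DataFrame,
    burden: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    kidney_effect: float = 0.0,
    n_active: int = 15,
    base_prevalence: float = 0.15,
    single_code_fraction: float = 0.02,
) -> pd.DataFrame:
    """Phecode event rows (person_id, day, phecode) under a liability model.

    The first ``n_active`` catalog phecodes (kidney-domain ones first) get
    non-trivial prevalence; kidney-domain liabilities load on the
    standardized burden with ``kidney_effect``. Cases receive two events on
    different days; a small fraction of non-cases receive exactly one code
    to exercise the single-code exclusion.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(persons)
    if burden is None:
        b_z = np.zeros(n)
    else:
        sd = burden.std()
        b_z = (burden - burden.mean()) / (sd if sd > 0 else 1.0)
    cat = pd.concat([
        catalog[catalog["domain"] == "kidney"],
        catalog[catalog["domain"] != "kidney"],
    ]).head(n_active)
    base_logit = np.log(base_prevalence / (1 - base_prevalence))
    ids = persons["person_id"].to_numpy()
    rows = []
    for _, row in cat.iterrows():
        eff = kidney_effect if row["domain"] == "kidney" else 0.0
        p = 1.0 / (1.0 + np.exp(-(base_logit + eff * b_z)))
        case = rng.uniform(size=n) < p
        lone = (~case) & (rng.uniform(size=n) < single_code_fraction)
        for pid in ids[case]:
            d1, d2 = sorted(rng.integers(0, 1800, size=2))
            rows.append((pid, int(d1), row["phecode"]))
            rows.append((pid, int(d2) + 1, row["phecode"]))
        for pid in ids[lone]:
            rows.append((pid, int(rng.integers(0, 1800)), row["phecode"]))
    return pd.DataFrame(rows, columns=["person_id", "day", "phecode"])


def make_gene_annotation(genes: Sequence[str], chroms: Sequence[str],
                         tss: Sequence[int]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene": list(genes), "chrom": list(chroms),
        "tss": np.asarray(tss, dtype=np.int64), "strand": "+",
    })


def make_drug_target_tables(
    proteins: Sequence[str],
    rng: Optional[np.random.Generator] = None,
    direct_fraction: float = 0.3,
    interactor_fraction: float = 0.4,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fixture drug–target and PPI tables shaped like ChEMBL/STRING extracts."""
    if rng is None:
        rng = np.random.default_rng(0)
    drug_rows, ppi_rows = [], []
    for i, prot in enumerate(proteins):
        if rng.uniform() < direct_fraction:
            drug_rows.append((f"DRUG_{i}_a", prot, "approved"))
        partner = f"{prot}_IX"
        score = float(rng.uniform(0.75, 0.99))
        ppi_rows.append((prot, partner, round(score, 3)))
        if rng.uniform() < interactor_fraction:
            drug_rows.append((f"DRUG_{i}_b", partner, "investigational"))
    drugs = pd.DataFrame(drug_rows, columns=["drug", "target", "phase"])
    ppi = pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "score"])
    return drugs, ppi


@dataclass
class Cohort:
    """One simulated cohort bundle with its ground truth."""

    config: SimulationConfig
    persons: pd.DataFrame
    dosages: np.ndarray
    variants: pd.DataFrame
    truth: ProteinOutcome
    labs: pd.DataFrame
    true_slopes: pd.Series
    procedures: pd.DataFrame
    covariate_columns: list = field(default_factory=list)

    def covariates(self, n_pcs: int = 10) -> np.ndarray:
        cols = ["age"] + [f"pc{k + 1}" for k in range(n_pcs)]
        X = self.persons[cols].to_numpy(dtype=float)
        sex = (self.persons["sex"].to_numpy() == "female").astype(float)
        return np.column_stack([X[:, :1], sex, X[:, 1:]])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.dosages.tobytes())
        for df in (self.persons, self.variants, self.labs):
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def simulate_cohort(
    config: SimulationConfig,
    region: Optional[pd.DataFrame] = None,
    causal_index: Optional[int] = None,
    one_visit_fraction: float = 0.02,
) -> Cohort:
    """Full individual-level cohort: genotypes, protein, outcomes, labs.

    Deterministic given (config, region): all randomness flows from
    ``config.seed`` through a spawned generator sequence.
    """
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(5)]
    dosages, variants = simulate_genotypes(config, rng=rngs[0], region=region)
    truth = simulate_protein_and_outcome(dosages, config, rng=rngs[1], causal_index=causal_index)
    persons = simulate_persons(config, rng=rngs[2])
    labs, true_slopes = simulate_longitudinal_egfr(
        config, persons, burden=truth.quantitative, rng=rngs[3],
        one_visit_fraction=one_visit_fraction,
    )
    # dialysis/transplant events for persons with very low late eGFR
    merged = labs.merge(persons[["person_id", "age", "sex"]], on="person_id")
    from .phenotyping import ckdepi_egfr

    merged["egfr"] = ckdepi_egfr(
        merged["scr"].to_numpy(), merged["age"].to_numpy() + merged["day"].to_numpy() / 365.25,
        merged["sex"].to_numpy(),
    )
    last = merged.sort_values("day").groupby("person_id").tail(1)
    low = last[last["egfr"] < 15.0]
    proc_rng = rngs[4]
    chosen = low[proc_rng.uniform(size=len(low)) < 0.5]
    procedures = pd.DataFrame({
        "person_id": chosen["person_id"].to_numpy(),
        "day": chosen["day"].to_numpy(),
        "event": "dialysis",
    })
    return Cohort(
        config=config, persons=persons, dosages=dosages, variants=variants,
        truth=truth, labs=labs, true_slopes=true_slopes, procedures=procedures,
    )


def simulate_region_summary_stats(
    n_snps: int,
    n_samples: int,
    causal_index: int,
    causal_z: float,
    ld_decay: float = 0.05,
    spacing_kb: float = 5.0,
    maf: float = 0.3,
    rng: Optional[np.random.Generator] = None,
    trait_name: str = "trait",
    trait_type: str = "quantitative",
    chrom: str = "1",
    region_start: int = 1_000_000,
) -> SummaryStats:
    """Region summary statistics under the multivariate-normal z model.

    Marginal z-scores follow ``z ~ MVN(R @ lam, R)`` where R is the AR(1)
    LD matrix and ``lam`` carries the causal SNP's non-centrality
    ``causal_z``. Betas are reported on a per-SD scale with
    ``se = 1/sqrt(n)``. Fast enough for hundreds of replicate regions, as
    used by the colocalization scenario suites.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    idx = np.arange(n_snps)
    R = np.exp(-ld_decay * spacing_kb * np.abs(idx[:, None] - idx[None, :]))
    lam = np.zeros(n_snps)
    lam[causal_index] = causal_z
    L = np.linalg.cholesky(R + 1e-10 * np.eye(n_snps))
    z = R @ lam + L @ rng.standard_normal(n_snps)
    se = np.full(n_snps, 1.0 / np.sqrt(n_samples))
    beta = z * se
    pos = region_start + (spacing_kb * 1000 * idx).astype(np.int64)
    rec = pd.DataFrame({
        "variant_id": [f"{chrom}:{p}:A:G" for p in pos],
        "chrom": chrom, "pos": pos,
        "effect_allele": "A", "other_allele": "G",
        "eaf": maf, "beta": beta, "se": se,
        "pvalue": 2 * stats.norm.sf(np.abs(z)),
    })
    kwargs = {}
    if trait_type == "binary":
        kwargs = {"n_case": n_samples // 5, "n_control": n_samples - n_samples // 5}
    return SummaryStats(trait_name=trait_name, trait_type=trait_type,
                        n=n_samples, records=rec, **kwargs)
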