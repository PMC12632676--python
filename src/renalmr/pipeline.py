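"""End-to-end orchestration: simulate → phenotype → scan → MR → gates →
coloc → PheWAS → network.

A run simulates three independent cohorts genotyped on shared cis regions
(one region per protein): an exposure cohort for the protein GWAS, an
outcome cohort whose longitudinal records yield the four kidney endpoints
(baseline eGFR, annualized eGFR slope, incident CKD, ESKD), and a
replication cohort providing external endpoint analogs (eGFR, CKD,
Rapid3-style rapid decline, CKDi25-style incident drop). Two-sample MR per
endpoint is ACAT-combined per protein, gated on per-dataset Bonferroni
significance, directional consistency, colocalization (PP4 > 0.8) and
external replication, then PheWAS pleiotropy tiers and the drug-target
evidence network are assembled for the surviving proteins.

Every stage is a pure function of (config, seed); rerunning a config+seed
reproduces all tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import ProteinVerdict, acat, bonferroni_threshold, classify_direction, replicate
from .assoc import scan_binary, scan_quantitative
from .coloc import ColocResult, colocalize
from .config import RunConfig, SimulationConfig
from .instruments import InstrumentSet, LDReference, clump, harmonize, select_cis_pqtls
from .io import SummaryStats, write_table
from .mr import run_mr
from .network import build_network, export_network, network_summary
from .phenotyping import derive_endpoints
from .phewas import classify_pleiotropy, run_phewas, synthetic_phecode_catalog
from .simulate import (
    _region_layout, make_drug_target_tables, make_gene_annotation,
    simulate_genotypes, simulate_longitudinal_egfr, simulate_persons,
    simulate_phecode_events,
)

ENDPOINTS = ["egfr", "slope", "ckd", "eskd"]
REPLICATION_ENDPOINTS = ["egfr", "ckd", "rapid3", "ckdi25"]

#: exposure-side p-value ceiling for instrument candidacy
PQTL_P_MAX = 5e-6


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage


@dataclass
class StudyCohort:
    """One simulated cohort genotyped on the shared protein regions."""

    persons: pd.DataFrame
    regions: List[pd.DataFrame]
    dosages: List[np.ndarray]
    proteins: np.ndarray                 # n × K
    burden: Optional[np.ndarray] = None
    labs: Optional[pd.DataFrame] = None
    procedures: Optional[pd.DataFrame] = None
    endpoints: Optional[pd.DataFrame] = None
    phecode_events: Optional[pd.DataFrame] = None

    def covariates(self, n_pcs: int) -> np.ndarray:
        sex = (self.persons["sex"].to_numpy() == "female").astype(float)
        pcs = self.persons[[f"pc{k + 1}" for k in range(n_pcs)]].to_numpy(dtype=float)
        return np.column_stack([self.persons["age"].to_numpy(dtype=float), sex, pcs])


@dataclass
class PipelineResult:
    config: RunConfig
    verdicts: List[ProteinVerdict]
    verdict_table: pd.DataFrame
    mr_table: pd.DataFrame
    coloc_results: Dict[str, ColocResult]
    profiles: Dict[str, object]
    network: object
    report: dict
    output_dir: Optional[Path] = None


def _protein_ids(k: int) -> List[str]:
    return [f"PROT{i + 1}" for i in range(k)]


def _causal_flags(run: RunConfig) -> List[bool]:
    if run.scenario == "null":
        return [False] * run.n_proteins
    flags = [False] * run.n_proteins
    flags[0] = True
    return flags


def build_cohort(
    run: RunConfig,
    regions: List[pd.DataFrame],
    seed: int,
    n: int,
    with_records: bool = False,
    catalog: Optional[pd.DataFrame] = None,
) -> StudyCohort:
    """Genotype a fresh cohort on the shared regions and simulate phenotypes.

    With ``with_records`` the cohort also gets longitudinal creatinine,
    dialysis procedures, derived endpoints and phecode events — the
    outcome-side data. Without, it is an exposure-side cohort (proteins
    only).
    """
    sim = run.simulation
    K = len(regions)
    flags = _causal_flags(run)
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(K + 4)
    cfg = dataclasses.replace(sim, n_individuals=n)

    persons = simulate_persons(cfg, rng=np.random.default_rng(seeds[K]))
    conf_rng = np.random.default_rng(seeds[K + 1])
    confounder = conf_rng.standard_normal(n)

    dosages, proteins = [], []
    for k in range(K):
        rng_k = np.random.default_rng(seeds[k])
        G, _ = simulate_genotypes(cfg, rng=rng_k, region=regions[k])
        g_c = G[:, G.shape[1] // 2]
        prot = (
            sim.causal_protein_effect * (g_c - g_c.mean())
            + sim.confounder_protein_effect * confounder
            + sim.noise_sd * rng_k.standard_normal(n)
        )
        dosages.append(G)
        proteins.append(prot)
    proteins = np.column_stack(proteins)

    lin = np.zeros(n)
    distinct = run.scenario == "coloc-distinct"
    for k in range(K):
        if not flags[k]:
            continue
        if distinct:
            G = dosages[k]
            m = G.shape[1]
            j = (m // 2 + max(1, m // 3)) % m
            eff = sim.direct_variant_effect
            if eff is None:
                eff = sim.causal_protein_effect * sim.protein_outcome_effect
            lin = lin + eff * (G[:, j] - G[:, j].mean())
        else:
            lin = lin + sim.protein_outcome_effect * proteins[:, k]
    burden_rng = np.random.default_rng(seeds[K + 2])
    burden = lin + sim.confounder_effect * confounder + sim.noise_sd * burden_rng.standard_normal(n)
    b_z = (burden - burden.mean()) / burden.std()
    persons["diabetes"] = burden_rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-(-1.1 + 0.3 * b_z)))

    cohort = StudyCohort(persons=persons, regions=regions, dosages=dosages,
                         proteins=proteins, burden=burden)
    if not with_records:
        return cohort

    lab_rng = np.random.default_rng(seeds[K + 3])
    labs, _ = simulate_longitudinal_egfr(cfg, persons, burden=burden, rng=lab_rng,
                                         one_visit_fraction=0.02)
    cohort.labs = labs

    # dialysis events for persons whose measured eGFR ends below 15
    from .phenotyping import ckdepi_egfr

    merged = labs.merge(persons[["person_id", "age", "sex"]], on="person_id")
    merged["egfr"] = ckdepi_egfr(
        merged["scr"].to_numpy(),
        merged["age"].to_numpy() + merged["day"].to_numpy() / 365.25,
        merged["sex"].to_numpy(),
    )
    last = merged.sort_values("day").groupby("person_id").tail(1)
    low = last[last["egfr"] < 15.0]
    chosen = low[lab_rng.uniform(size=len(low)) < 0.5]
    cohort.procedures = pd.DataFrame({
        "person_id": chosen["person_id"].to_numpy(),
        "day": chosen["day"].to_numpy(), "event": "dialysis",
    })
    cohort.endpoints = derive_endpoints(persons, labs, cohort.procedures)
    if catalog is not None:
        cohort.phecode_events = simulate_phecode_events(
            persons, catalog, burden=burden, rng=lab_rng, kidney_effect=0.8,
        )
    return cohort


def _endpoint_traits(cohort: StudyCohort) -> Dict[str, tuple[np.ndarray, bool]]:
    """Map endpoint name → (per-person trait vector, is_binary).

    Quantitative endpoints are standardized so downstream effects are on an
    SD scale; indeterminate case/control statuses become NaN (complete-case
    in the scans).
    """
    ep = cohort.endpoints.reindex(cohort.persons["person_id"])
    out = {}
    for name, col in (("egfr", "baseline_egfr"), ("slope", "egfr_slope")):
        v = ep[col].to_numpy(dtype=float)
        sd = np.nanstd(v)
        out[name] = ((v - np.nanmean(v)) / (sd if sd > 0 else 1.0), False)
    for name, col in (("ckd", "ckd_status"), ("eskd", "eskd_status")):
        s = ep[col].astype(str)
        v = np.where(s == "case", 1.0, np.where(s == "control", 0.0, np.nan))
        out[name] = (v, True)
    return out


def _scan_endpoints(cohort: StudyCohort, run: RunConfig,
                    labels: List[str]) -> Dict[str, List[SummaryStats]]:
    """GWAS of every endpoint over every protein's region.

    Returns endpoint → list of per-protein SummaryStats. Endpoints whose
    scan is infeasible (e.g. a class missing) are omitted.
    """
    cov = cohort.covariates(run.gwas_pc_count)
    traits = _endpoint_traits(cohort)
    out: Dict[str, List[SummaryStats]] = {}
    for name in labels:
        if name not in traits:
            continue
        v, is_binary = traits[name]
        stats_k = []
        try:
            for k, (G, region) in enumerate(zip(cohort.dosages, cohort.regions)):
                scan = scan_binary if is_binary else scan_quantitative
                stats_k.append(scan(v, G, cov, region, trait_name=name))
        except ValueError:
            continue
        out[name] = stats_k
    return out


def _replication_traits(cohort: StudyCohort) -> Dict[str, tuple[np.ndarray, bool]]:
    """External-analog endpoints: eGFR, CKD, Rapid3 (slope < −3 %/yr),
    CKDi25 (≥25% eGFR drop to below 60)."""
    base = _endpoint_traits(cohort)
    ep = cohort.endpoints.reindex(cohort.persons["person_id"])
    slope = ep["egfr_slope"].to_numpy(dtype=float)
    rapid3 = np.where(np.isfinite(slope), (slope < -3.0).astype(float), np.nan)

    labs = cohort.labs.merge(cohort.persons[["person_id", "age", "sex"]], on="person_id")
    from .phenotyping import ckdepi_egfr

    labs = labs.sort_values("day")
    labs["egfr"] = ckdepi_egfr(
        labs["scr"].to_numpy(), labs["age"].to_numpy() + labs["day"].to_numpy() / 365.25,
        labs["sex"].to_numpy(),
    )
    first = labs.groupby("person_id")["egfr"].first()
    last = labs.groupby("person_id")["egfr"].last()
    drop = ((last <= 0.75 * first) & (last < 60.0)).astype(float)
    ckdi25 = drop.reindex(ep.index).to_numpy()
    return {
        "egfr": base["egfr"],
        "ckd": base["ckd"],
        "rapid3": (rapid3, True),
        "ckdi25": (ckdi25, True),
    }


def _scan_replication(cohort: StudyCohort, run: RunConfig) -> Dict[str, List[SummaryStats]]:
    cov = cohort.covariates(run.gwas_pc_count)
    traits = _replication_traits(cohort)
    out: Dict[str, List[SummaryStats]] = {}
    for name, (v, is_binary) in traits.items():
        try:
            stats_k = []
            for G, region in zip(cohort.dosages, cohort.regions):
                scan = scan_binary if is_binary else scan_quantitative
                stats_k.append(scan(v, G, cov, region, trait_name=f"rep_{name}"))
            out[name] = stats_k
        except ValueError:
            continue
    return out


def run_pipeline(run: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full proteome-to-phenome screen for one configuration."""
    sim = run.simulation
    K = run.n_proteins
    pids = _protein_ids(K)
    root = np.random.SeedSequence(run.seed)
    s_regions, s_exp, s_out, s_rep = root.spawn(4)

    stage = "simulate"
    try:
        layout_rng = np.random.default_rng(s_regions)
        regions = [
            _region_layout(sim, layout_rng, chrom=str(k + 1)) for k in range(K)
        ]
        catalog = synthetic_phecode_catalog()
        seed_of = lambda ss: int(ss.generate_state(1)[0] % (2**31))  # noqa: E731
        exposure = build_cohort(run, regions, seed=seed_of(s_exp),
                                n=2 * sim.n_individuals, with_records=False)
        outcome = build_cohort(run, regions, seed=seed_of(s_out),
                               n=sim.n_individuals, with_records=True, catalog=catalog)
        replication = build_cohort(run, regions, seed=seed_of(s_rep),
                                   n=sim.n_individuals, with_records=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc)

    stage = "scans"
    try:
        cov_exp = exposure.covariates(run.gwas_pc_count)
        exposure_stats = [
            scan_quantitative(exposure.proteins[:, k], exposure.dosages[k],
                              cov_exp, regions[k], trait_name=pids[k])
            for k in range(K)
        ]
        endpoint_stats = _scan_endpoints(outcome, run, ENDPOINTS)
        replication_stats = _scan_replication(replication, run)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc)

    genes = make_gene_annotation(
        pids, [str(k + 1) for k in range(K)],
        [int(r["pos"].iloc[len(r) // 2]) for r in regions],
    )

    stage = "instruments+mr"
    verdicts: List[ProteinVerdict] = []
    mr_rows = []
    instruments: Dict[str, pd.DataFrame] = {}
    lds: Dict[str, LDReference] = {}
    accounting = {"n_input": 0, "retained": 0, "flipped": 0, "proxied": 0, "dropped": 0}
    try:
        for k, pid in enumerate(pids):
            gene = genes.iloc[k]
            cand = select_cis_pqtls(exposure_stats[k], gene, run.maf_min, run.window_bp)
            cand = cand[cand["pvalue"] < PQTL_P_MAX]
            ld = LDReference(exposure.dosages[k], regions[k]["variant_id"])
            lds[pid] = ld
            clumped = clump(cand, ld, r2_max=run.clump_r2)
            if clumped.empty:
                verdicts.append(ProteinVerdict(pid, "synthetic"))
                continue
            instruments[pid] = clumped
            v = ProteinVerdict(pid, "synthetic")
            for name, stats_list in endpoint_stats.items():
                inst = harmonize(
                    clumped, stats_list[k].records, ld, r2_min=run.r2_min,
                    maf_tol=run.maf_tol, protein_id=pid, dataset_label="synthetic",
                )
                for key in accounting:
                    accounting[key] += inst.accounting[key]
                if inst.n_snp == 0:
                    continue
                try:
                    res = run_mr(inst, outcome_name=name)
                except (ValueError, ZeroDivisionError):
                    continue
                v.endpoint_results[name] = res
                mr_rows.append({
                    "protein_id": pid, "outcome": name, "method": res.method,
                    "beta": res.beta, "se": res.se, "pvalue": res.pvalue,
                    "n_snp": res.n_snp, "cochran_Q": res.cochran_Q,
                    "Q_pvalue": res.Q_pvalue,
                    "egger_intercept": res.egger_intercept,
                    "egger_intercept_p": res.egger_intercept_p,
                })
            if v.endpoint_results:
                v.acat_p = acat([r.pvalue for r in v.endpoint_results.values()])
                v.q_flag = any(r.q_flag for r in v.endpoint_results.values())
                v.egger_flag = any(r.egger_flag for r in v.endpoint_results.values())
            verdicts.append(v)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc)

    stage = "gates"
    try:
        cutoff = bonferroni_threshold(run.alpha, K)
        for v in verdicts:
            v.significant = bool(np.isfinite(v.acat_p) and v.acat_p < cutoff)
            v.direction = classify_direction(v.endpoint_results, run.endpoint_alpha)
        significant = [v for v in verdicts if v.significant]
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc)

    stage = "coloc"
    coloc_results: Dict[str, ColocResult] = {}
    try:
        for v in significant:
            k = pids.index(v.protein_id)
            if "egfr" not in endpoint_stats:
                continue
            res = colocalize(exposure_stats[k], endpoint_stats["egfr"][k],
                             protein_id=v.protein_id, outcome_name="egfr")
            coloc_results[v.protein_id] = res
            v.coloc_pp4 = res.pp4
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc)

    stage = "replication"
    try:
        n_attempted = max(len(significant), 1)
        for v in significant:
            k = pids.index(v.protein_id)
            clumped = instruments.get(v.protein_id)
            if clumped is None:
                continue
            sets = {}
            for name, stats_list in replication_stats.items():
                sets[name] = harmonize(
                    clumped, stats_list[k].records, lds[v.protein_id],
                    r2_min=run.r2_min, maf_tol=run.maf_tol,
                    protein_id=v.protein_id, dataset_label="replication",
                )
            p, ok, _ = replicate(sets, n_proteins_attempted=n_attempted, alpha=run.alpha)
            v.replication_acat_p = p
            v.replicated = ok
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc)

    stage = "phewas"
    profiles: Dict[str, object] = {}
    phewas_tables = []
    try:
        cov_ph = outcome.covariates(run.phewas_pc_count)
        id_to_col = {
            vid: (k, j)
            for k in range(K)
            for j, vid in enumerate(regions[k]["variant_id"])
        }
        for v in significant:
            clumped = instruments.get(v.protein_id)
            tables = []
            if clumped is not None and outcome.phecode_events is not None:
                for vid in clumped["variant_id"]:
                    k, j = id_to_col[vid]
                    tab = run_phewas(
                        outcome.dosages[k][:, j], catalog, outcome.phecode_events,
                        outcome.persons, covariates=cov_ph, variant_label=vid,
                        min_count=run.phewas_min_count, alpha=run.alpha,
                    )
                    tab["protein_id"] = v.protein_id
                    tables.append(tab)
            profiles[v.protein_id] = classify_pleiotropy(v.protein_id, tables)
            phewas_tables.extend(tables)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc)

    stage = "network"
    try:
        drugs, ppi = make_drug_target_tables(pids, rng=np.random.default_rng(run.seed + 99))
        net = build_network(significant, profiles, drugs, ppi, score_min=run.score_min)
        net_summary = network_summary(net)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc)

    verdict_table = pd.DataFrame([v.to_row() for v in verdicts])
    mr_table = pd.DataFrame(mr_rows)
    report = {
        "scenario": run.scenario,
        "seed": run.seed,
        "n_proteins": K,
        "bonferroni_cutoff": cutoff,
        "n_instrumented": len(instruments),
        "n_significant": len(significant),
        "n_consistent": sum(v.direction in ("protective", "detrimental") for v in significant),
        "n_coloc_pass": sum(1 for r in coloc_results.values() if r.passed),
        "n_replicated": sum(v.replicated for v in significant),
        "n_pass_all": sum(v.passes_all for v in verdicts),
        "harmonization": accounting,
        "network": net_summary,
    }

    out_dir = None
    if write:
        out_dir = Path(run.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(verdict_table, out_dir / "verdicts.tsv")
        if len(mr_table):
            write_table(mr_table, out_dir / "mr_results.tsv")
        write_table(outcome.endpoints.reset_index(), out_dir / "endpoints.tsv")
        write_table(outcome.persons, out_dir / "persons.tsv")
        write_table(outcome.labs, out_dir / "labs.tsv")
        write_table(genes, out_dir / "genes.tsv")
        for k, ss in enumerate(exposure_stats):
            ss.to_tsv(out_dir / f"sumstats_exposure_{pids[k]}.tsv")
        for name, stats_list in endpoint_stats.items():
            for k, ss in enumerate(stats_list):
                ss.to_tsv(out_dir / f"sumstats_{name}_{pids[k]}.tsv")
        if phewas_tables:
            write_table(pd.concat(phewas_tables, ignore_index=True),
                        out_dir / "phewas.tsv")
        export_network(net, out_dir)
        cfg_yaml = yaml.safe_dump(run.to_dict(), sort_keys=True)
        manifest = {
            "seed": run.seed,
            "config_hash": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "version": __version__,
            "config": run.to_dict(),
        }
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)

    return PipelineResult(
        config=run, verdicts=verdicts, verdict_table=verdict_table,
        mr_table=mr_table, coloc_results=coloc_results, profiles=profiles,
        network=net, report=report, output_dir=out_dir,
    )
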