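# renalmr

Proteome-to-phenome Mendelian randomization screening for kidney disease,
implemented end to end on synthetic cohorts with known causal structure.

## The problem

Circulating proteins are attractive drug targets for chronic kidney disease
(CKD), but observational protein–outcome associations are confounded and
reverse-causal. Two-sample Mendelian randomization (MR) instruments each
protein with its *cis*-pQTLs — variants near the gene's transcription start
site that shift circulating protein levels — and estimates the causal effect
of the protein on kidney outcomes from GWAS summary statistics. A credible
screen needs more than a p-value per protein: longitudinal EHR-derived
endpoints that capture onset *and* progression, aggregation of correlated
endpoint evidence, colocalization to rule out LD confounding, external
replication, phenome-wide context to separate kidney-proximal biology from
systemic pleiotropy, and a map onto known drug targets.

`renalmr` implements that full cascade as a tested, reusable pipeline, with
a synthetic-data generator that produces every input (genotypes with LD,
cis-regulated proteins, longitudinal creatinine, phecode events, drug-target
tables) under configurable ground truth, so every stage can be validated
against known answers.

## The statistics

For protein *j* with harmonized instrument effects (β̂ₓᵢ, β̂ᵧᵢ) the causal
effect on each endpoint is estimated by the Wald ratio β̂ᵧ/β̂ₓ (one SNP) or
multiplicative random-effects IVW (≥2 SNPs): weighted least squares of β̂ᵧ
on β̂ₓ through the origin with weights 1/se(β̂ᵧ)², the SE inflated by
√max(1, Q/(k−1)) where Q is Cochran's heterogeneity statistic. The MR-Egger
intercept tests directional pleiotropy. Endpoint p-values (baseline eGFR,
annualized eGFR slope, incident CKD, ESKD) are combined with the Aggregated
Cauchy Association Test,

T = Σᵢ wᵢ·tan((½ − pᵢ)π),  p = ½ − arctan(T)/π,

valid under arbitrary endpoint dependence. Survivors of the per-dataset
Bonferroni gate are checked for directional consistency on a common
kidney-benefit axis (p < 0.0125 per endpoint), colocalization by Wakefield
approximate Bayes factors (shared-variant posterior PP4 > 0.8, priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵), and external replication (ACAT across four
replication endpoints, p < 0.05/n attempted). Kidney endpoints come from the
2021 race-free CKD-EPI creatinine equation, persistence rules (two eGFR < 60
— or < 15 for ESKD — at least 90 days apart, or dialysis/transplant codes),
and a random-intercept/random-slope linear mixed model of log eGFR on time.
Phenome-wide logistic scans over a 12-domain phecode catalog tier each
protein from kidney-specific to highly pleiotropic, and a networkx overlay
on drug-target and PPI tables classifies druggability.

## Worked example

```python
from renalmr.config import RunConfig, SimulationConfig
from renalmr.pipeline import run_pipeline

sim = SimulationConfig(n_individuals=4000, n_variants_region=40,
                       rapid_fraction_logit=-3.5, seed=3)
run = RunConfig(scenario="causal", seed=3, n_proteins=5, simulation=sim)
res = run_pipeline(run, write=False)
print(res.verdict_table[["protein_id", "acat_p", "significant", "direction",
                         "coloc_pp4", "replicated", "passes_all"]])
```

prints (PROT1 is the planted causal protein; PROT2–5 are null):

```
  protein_id        acat_p  significant      direction  coloc_pp4  replicated  passes_all
0      PROT1  4.751839e-07         True    detrimental   0.999783        True        True
1      PROT2  5.177897e-01        False  indeterminate        NaN       False       False
2      PROT3  4.030081e-01        False  indeterminate        NaN       False       False
3      PROT4  7.763662e-01        False  indeterminate        NaN       False       False
4      PROT5  2.173547e-02        False    detrimental        NaN       False       False
```

The planted protein clears every gate — ACAT significance under the
per-dataset Bonferroni cutoff (0.05/5 = 0.01), uniform directional
consistency across the four endpoints ("detrimental": lower eGFR, faster
decline, higher CKD/ESKD risk), a shared-causal-variant posterior
PP4 ≈ 1.0, and external replication — while no null protein does. The same
run from the shell:

```bash
renalmr all --scenario causal --seed 3 --out results/causal_run
```

writes per-stage tables (verdicts, MR results, endpoints, summary
statistics, PheWAS, the GraphML evidence network) plus a manifest with the
seed and config hash.

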