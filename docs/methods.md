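# Methods

`renalmr` implements a proteome-to-phenome causal screen for kidney disease
on synthetic data. This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic validation
does and does not establish.

## Synthetic cohort model

**Genotypes.** Each protein has a cis region of `n_variants_region`
variants spaced `variant_spacing_bp` apart (defaults: 60 variants, 5 kb —
a 300 kb region sitting inside the ±500 kb cis window). Haplotypes are
latent Gaussian AR(1) processes thresholded at Φ⁻¹(MAF): neighbour latent
correlation is `exp(-ld_decay·Δkb)` and two independent haplotypes per
person give Hardy–Weinberg dosages in [0, 2]. `ld_decay = 0` is a special
case meaning *no LD at all* (independent variants); positive values give
the AR(1) decay. Thresholding attenuates the genotype correlation relative
to the latent one, which is acceptable because the LD model is a control
knob, not a fit to human data — realistic human LD maps are out of scope.
MAFs are uniform on `maf_range` (default 0.05–0.5, comfortably above the
1% analysis floor).

**Protein and outcome.** One mid-region variant is causal for the protein:
`protein = β_G·G + λ_P·C + ε`, with per-allele effect `β_G = 0.5` SD, a
standard-normal confounder `C` loading on both protein (λ_P = 0.3) and
outcome (λ_Y = 0.3), and unit-variance noise. The latent *kidney burden*
is `θ·protein + λ_Y·C + ε` with `θ = protein_outcome_effect` (default
0.6 per protein SD). With `shared_causal=False` the burden instead takes a
direct per-allele effect from a *different* region variant and nothing
flows through the protein — the distinct-causal colocalization scenario.
The confounder makes the naive observational protein–outcome slope biased
while leaving cis instruments valid (verified by simulation in the test
suite). Binary outcomes use a logistic link on the same linear predictor.

**Longitudinal eGFR.** Each person gets a baseline eGFR that is lognormal
(geometric mean 85 mL/min/1.73 m², log-SD 0.25 — a mostly-normal-function
cohort with a low-eGFR tail) shifted down by `burden_egfr_effect` (0.2 log
units per burden SD), and a true relative slope drawn from
Normal(`slope_mean`, `slope_sd`) %/year (defaults −2 ± 2, a typical
at-risk-cohort decline) shifted by `burden_slope_effect` (1.2 %/yr per
burden SD). An optional *rapid-progression mixture* (off by default in the
bare generator, on in pipeline runs) assigns a small, burden-enriched
fraction (logit −3.5 + 1.0·burden) a −45 %/yr decline; this is a stylized
device whose sole purpose is to make ESKD — a rare event — actually occur
in desk-scale cohorts. Trajectories are generated on the log-eGFR scale,
inverted through the CKD-EPI equation (closed-form piecewise inverse) to
serum creatinine, and multiplied by lognormal measurement noise with CV
`creatinine_cv` (default 0.05; assay noise magnitude is a free parameter
of the generator, not a claim about any particular laboratory). Visits:
6 over 5 years with ±40% jitter.

**Phecode events.** A synthetic 1,020-phecode catalog spans 12 clinical
domains (11 plus a curated kidney domain). A subset of phecodes receives
events from a liability model; kidney-domain liabilities load on the
standardized burden. Cases get two codes on different days; a small
fraction of non-cases gets exactly one code to exercise the single-code
exclusion. Drug-target and PPI tables are fixture tables shaped like
ChEMBL/STRING extracts, generated per run.

## Phenotyping

* **eGFR**: 2021 race-free CKD-EPI creatinine equation;
  142·min(scr/κ,1)^α·max(scr/κ,1)^(−1.200)·0.9938^age·(1.012 if female),
  κ = 0.7/0.9, α = −0.241/−0.302 (female/male). Continuous at the knot
  scr = κ; strictly decreasing in creatinine.
* **CKD**: two eGFR < 60 at least 90 days apart (boundary inclusive).
  **ESKD**: dialysis/transplant code, or two eGFR < 15 ≥ 90 days apart.
  Controls need ≥ 2 encounters and no qualifying event; persons who are
  neither case nor eligible control are *indeterminate* and excluded from
  that endpoint rather than forced to control.
* **Slope**: random-intercept/random-slope linear mixed model of
  log(eGFR) on years; the per-person slope is (fixed + BLUP)·100 in
  %/year. The relative ("%/year") definition is the slope of log eGFR —
  the standard relative-decline measure. Persons with one measurement are
  excluded and listed. Default engine is the package's batched
  maximum-likelihood implementation (`renalmr._lmm`), which factorises the
  marginal likelihood over persons and batches same-visit-count persons
  through stacked Cholesky solves; it matches statsmodels `MixedLM` on
  shared fixtures (slope correlation > 0.999 in the tests) and is fast
  enough for the repeated-cohort suites. Exactly linear noise-free data
  short-circuits to per-person OLS (the mixed model is degenerate there);
  a singular fit falls back to per-person OLS with a warning and a flag.
* **Diabetes**: (one diabetes code at a PCP visit, or codes on two
  different days) AND a diabetes drug prescription. The "face-to-face PCP
  outpatient visit" concept is modelled as a per-event boolean flag.

## Association scans

Quantitative traits: OLS per variant with age, sex and ancestry PCs,
computed by residualizing trait and dosages on the covariates once
(Frisch–Waugh–Lovell) — exact, and cross-checked against statsmodels OLS.
Binary traits: per-variant logistic regression by Newton–Raphson,
warm-started at the covariate-only fit; separation or non-convergence
yields a flagged missing record excluded downstream. All p-values are
two-sided normal on beta/se, so p is always reproducible from the stored
effect and SE (this is also why the Wald p, not the t p, is used — at the
simulated sample sizes the difference is negligible). Ten PCs are used for
endpoint GWAS and five for PheWAS, both configurable. Quantitative
endpoint traits are standardized before scanning so effects are on an SD
scale — which also puts them on the scale the colocalization priors
assume.

## Instruments and harmonization

Candidates lie within an inclusive ±500 kb window of the TSS with
MAF > 1% and exposure p < 5×10⁻⁶ (an instrument-relevance floor), then
greedy p-value-ordered LD clumping at r² < 0.1 approximates conditional
independence. Harmonization aligns outcome records to exposure effect
alleles: direct match, swap (negate), or strand complement; palindromic
(A/T, C/G) variants are resolved by allele frequency only when both sides
are > 0.08 from 0.5, otherwise dropped; variants missing from the outcome
are replaced by the best LD proxy with r² ≥ 0.9 and |ΔMAF| ≤ 0.02,
sign-aligned by the LD correlation and flagged. The accounting identity
`input = retained + flipped + proxied + dropped` holds exactly and
harmonization is idempotent.

## MR, aggregation and gates

Wald ratio (one SNP; delta-method SE = se_out/|β_exp|) or multiplicative
random-effects IVW (≥ 2 SNPs; WLS through the origin, weights 1/se_out²,
SE scaled by √max(1, Q/(k−1)) — floored at 1 so the SE never drops below
the fixed-effect SE). Cochran's Q uses first-order ratio weights; MR-Egger
(≥ 3 SNPs) regresses with an intercept after orienting exposure effects
positive, with the same multiplicative overdispersion floor. Q and Egger
failures *flag* a protein; they never remove it. Stratum differences use
z = (β₁−β₂)/√(se₁²+se₂²).

ACAT combines the four endpoint p-values with equal weights (none are
specified by the screening design), inputs clipped to [10⁻¹⁵, 1−10⁻¹⁵]
to keep the tangent finite. Significance is per-dataset Bonferroni
(α/n proteins tested). Direction orients each endpoint's beta onto a
kidney-benefit axis (eGFR +, slope +, CKD −, ESKD −); among endpoints with
p < 0.0125, all-positive = protective, all-negative = detrimental, mixed =
inconsistent, none = indeterminate. Colocalization uses Wakefield log-ABFs
(prior effect SD 0.15 quantitative / 0.2 binary — the canonical defaults,
configurable) with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, all sums by
log-sum-exp; PP3's i≠j cross-term is computed as the log-difference of the
full cross product and the diagonal, clamped at 1−10⁻¹⁶ to absorb
roundoff, and a single-SNP region has PP3 exactly 0. Replication runs MR
against four external endpoint analogs in an independent cohort — baseline
eGFR, CKD, "Rapid3" (fitted slope < −3 %/yr) and "CKDi25" (≥ 25% eGFR drop
to below 60) — ACAT-combines them, and declares replication at
p < 0.05/n proteins attempted.

## PheWAS and networks

Per phecode: ≥ 2 mapped codes = case, 0 = control, exactly 1 = excluded;
phecodes with < 200 cases or < 200 controls are skipped with a recorded
reason; the Bonferroni cutoff is α divided by the *loaded* catalog size
(default 1,020). A protein's pleiotropy tier is the union of significant
hits over its clumped instruments: kidney_only, kidney_plus_k,
extra_renal_only, or no_hits — the last kept distinct from kidney
specificity because absent hits may only reflect small variant effects.
Druggability: direct if any drug targets the protein, secondary if a
first-shell interactor with confidence ≥ 0.9 (configurable; 0.8 is the
documented alternative) is a target, else none. The evidence network links
drugs, proteins, the kidney outcome (signed MR edge) and significant
phecodes; exported as GraphML plus node/edge tables.

## Pipeline study conditions

A pipeline run simulates three independent cohorts on shared regions: an
exposure cohort (2n) for protein GWAS, an outcome cohort (n) with
longitudinal records, and a replication cohort (n). Defaults: n = 4,000,
5 proteins, 40–60 variants per region. In the *causal* scenario one
planted protein drives the burden; *null* has none; *coloc-distinct*
routes the regional outcome signal around the protein. These sizes and the
effect defaults above were chosen once so that the planted protein's
outcome-side signal reaches z ≈ 6–8 (the regime where an ABF
colocalization can exceed PP4 = 0.8) while null proteins stay controlled;
with them the positive control clears every gate in 10/10 independent
seeds and 20 null replicates pass nothing.

## What the synthetic validation shows — and does not

Passing tests establish that each statistical component is implemented
correctly (exact oracles), is calibrated under its own null (Monte Carlo),
and that the assembled cascade controls family-wise error while recovering
a planted effect under the generator's assumptions: a single causal
variant per region, AR(1) LD, Gaussian confounding, log-linear individual
decline, and missingness-free labs. Real cohorts violate all of these —
allelic heterogeneity, population structure, assay batch effects,
informative visit timing, ICD coding noise — so green tests here do not
certify performance on real biobank data; they certify the machinery.

## Known limitations

* Single-causal-variant colocalization only (no SuSiE-style multi-signal
  decomposition or conditional analysis).
* The rapid-progression mixture is a device for generating ESKD events,
  not a clinical model of progression.
* Plain covariate-adjusted regression replaces mixed-model GWAS; synthetic
  cohorts contain no relatedness, so nothing is lost here by construction.
* Weighted-median/mode and MR-PRESSO estimators are not implemented.
* Palindromic-variant resolution by frequency fails near MAF 0.5 by
  design (such variants are dropped, counted).
* ML (not REML) in the fast LMM engine; at ≥ 500 persons the variance
  bias is negligible relative to the suite's tolerances, and the
  statsmodels REML engine remains available.
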