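# Methods

## Model and pipeline

The working object is a per-individual cohort table (id, cohort, sex, age,
BMI, menopause status, serum urate in mmol/L, effect-allele dosage in
[0, 2], two genetic principal components, exclusion flags).

**Variance phenotype.** Urate is residualized by OLS on age, BMI, PC1 and
PC2 *within each sex × cohort stratum* (sex and cohort therefore never
appear as covariates). The ranked inverse-normal transform (INT) of the
absolute residuals uses z = Φ⁻¹((r − c)/(n − 2c + 1)) with ascending ranks,
mean rank for ties, and Blom offset c = 3/8 (c = 0 and c = 0.5 are
supported). The INT is applied within the same strata, so z has mean ≈ 0
and SD ≈ 1 per stratum by construction; z² is the variance variable. The
INT deliberately discards the scale of the absolute residuals, which makes
the variance test conservative but robust to mean–variance coupling in the
raw trait.

**Mean adjustment.** The adjusted variance phenotype subtracts the
genotype-class mean urate (classes 0/1/2 from rounding dosage, means
computed within stratum) *before* covariate residualization, then rebuilds
z². The alternative order — residualize first, then remove genotype-class
means of the residuals — is available via `residualize_first=True`; on
simulated data the two orders give nearly identical tests, and the
subtract-first order is the default. A genotype class with fewer than two
members in a stratum is merged into the nearest occupied class with a
warning.

**Tests.** The mean-effect test is OLS of urate on dosage + age + BMI +
sex + PC1 + PC2 within a cohort (one pooled model per cohort; sex-specific
allele effects belong to the strata module). The variance test is simple
OLS of z² on dosage. p-values use the t distribution with residual degrees
of freedom; the dosage term's contribution is reported as partial r²
(incremental sum of squares) for the mean model and plain model r² for the
simple variance regression.

**Meta-analysis.** Inverse-variance weights w = 1/SE²; Cochran's
Q = Σw(β − β_fixed)² on k − 1 df; fixed effects unless P_Het < 0.05, in
which case DerSimonian–Laird random effects
(τ² = max(0, (Q − df)/(Σw − Σw²/Σw))) re-weights by 1/(SE² + τ²). Pooled
p-values are two-sided Wald. The gate and the estimator can be overridden
(`force_model=`). On the published per-cohort *adjusted* variance
estimates, Q computed from the rounded, printed inputs gives P_Het ≈ 0.049
— essentially on the gate — while the published combined value corresponds
to fixed-effect arithmetic; the package keeps the automatic rule and
reports the fixed-model value where that row is reproduced.

**Strata and interactions.** Groups are men, pre-menopausal and
post-menopausal women, formed after the menopause-analysis exclusions
(pregnancy, breastfeeding, hormone-replacement therapy, missing status,
and post-menopausal reports contradicted by menstruation within 12
months). The group-wise variance test subsets the cohort-level adjusted z²
(built on the full post-exclusion cohort so the genotype-mean adjustment
is shared) and pools across cohorts per group; a group under the minimum
size (default 30) yields a missing-estimate row, which tolerates cohorts
with no pre-menopausal women. Interaction models pool cohorts with cohort
indicator covariates rather than meta-analysing per-cohort interactions
(a per-cohort route is available through the library): mean model
urate ~ age + BMI + allele + group + allele:group on the men + comparison
subset with additive allele coding, variance model z² ~ allele + group +
allele:group on the adjusted phenotype. The saturated group × genotype
cell-means model (men/zero-copies reference, age and BMI adjusted)
provides per-cell betas and TT − GG contrasts. Plain (unadjusted) model r²
is reported with and without the interaction term.

## Synthetic cohorts

The generator draws hard Hardy–Weinberg genotypes at the configured
effect-allele frequency (an optional truncated-Normal dosage noise switch
emulates imputation uncertainty; hard calls are the default since the
original dosage distribution is unknown). Age and BMI are Normal,
truncated at 18 years and 15 kg/m²; PCs are standard Normal with no
phenotype loading; menopause status is Bernoulli within women. Urate is

    urate = intercept + (β_allele + β_interaction[group])·dosage
            + β_age·age + β_BMI·BMI + β_female + β_postmeno + ε,
    ε ~ N(0, σ²(dosage, group)),   log σ = log σ₀ + d_group·dosage,

so all dispersion slopes d = 0 is the homoscedastic null. Exclusion flags
(medication, gout, kidney disease, and the female-only menopause-analysis
flags) are independent Bernoulli draws at configurable rates.

Defaults were chosen once to match the study's descriptive statistics:
σ₀ = 0.07 mmol/L, β_BMI = 0.006 mmol/L per kg/m² and β_female = −0.09
mmol/L reproduce a total urate SD near 0.08–0.09 mmol/L with BMI and sex
explaining roughly 10–25% of variance and the dosage term ≈ 3% — the
observed magnitudes. The five-cohort preset fixes each cohort's size, age,
sex, BMI and menopause composition to the published cohort summaries,
solves the intercept so the expected urate mean matches the published
cohort mean, and applies each cohort's exclusion policy (only ARIC and FHS
drop antihypertensive users). CHS women are all post-menopausal, so its
pre-menopausal partition is empty, as in the study.

The stratified-scenario dispersion slopes (men 0, post 0.14, pre 0.22 on
the log-SD scale) were calibrated once so that the pooled mean-adjusted
variance effects land on the published group pattern (≈ 0.19 / 0.09 / ≈ 0
z² units per allele) at study scale; they are the scenario definition, not
free parameters.

What the generator does *not* emulate: skewed or heavy-tailed urate
residuals, age-linked menopause by default (a logistic link can be added),
linkage to other causal variants, relatedness, or correlated exclusion
flags. Consequently the mean-induced *unadjusted* variance artifact under
Gaussian residuals (≈ −0.02 to −0.04 at the preset's signal-to-noise) is
smaller in magnitude than the −0.152 observed in the real data, where
residual skewness amplifies the effect; the package's checks therefore
assert the direction of the flip and the null behaviour of the adjusted
test, not the artifact's magnitude. Passing tests demonstrate internal
statistical correctness and qualitative reproduction, not distributional
realism of real serum urate.

## Numerical choices and problem sizes

Region simulation uses Markov haplotype copying (each haplotype allele
copies its left neighbour with probability `ld_decay`), which yields an
exact AR(1) dosage correlation `ld_decay**distance` with a shared allele
frequency across sites. Ranking ties get mean rank. Monomorphic variants
are rejected by the single-variant tests and skipped (with a warning
recorded in the output) by the region scan. TSV output uses one dialect:
tab-separated, UTF-8, '.' decimal, 'NA' missing; urate is stored in
mmol/L, with an mg/dL unit declaration converted at 0.05948 mmol/L per
mg/dL. All simulation entry points take integer seeds; identical seeds
give bitwise-identical tables.

The repeated-simulation experiments use problem sizes chosen to keep a
full run on one CPU in tens of seconds while leaving comfortable power:
2,000 null replicates of n = 2,000 for type-I calibration, 100–200
replicates of n = 6,000 for interaction recovery, 50–100 study-scale
(five-cohort, n ≈ 14,000) replicates for the stratified ordering, and
six preset replicates pooled for the sign-pattern run (a single
replicate's pooled unadjusted-variance SE of ≈ 0.02 would leave the sign
assertion under-powered against a ≈ −0.03 expected effect).

## Known limitations

- The Gaussian residual model understates the unadjusted-variance artifact
  (see above); magnitudes of unadjusted effects are not comparable to the
  real-data values, only their signs.
- DerSimonian–Laird is the only random-effects estimator; no
  Hartung–Knapp correction, meta-regression or forest plots.
- The region scan reports raw p-values (plus a convenience Bonferroni
  column); no genomic control, LD-aware correction, or kinship modelling.
- Exclusion flags are independent draws, so simulated exclusion counts are
  binomial rather than matching any cohort's exact attrition.
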