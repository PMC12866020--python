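# Methods

This note documents the statistical procedures implemented in
`liverewas`, the synthetic data they are validated on, the numerical
choices made where the design was genuinely open, and what the passing
tests do and do not establish about real cohort data.

## Phenotype derivation

Liver variables (GGT, ALT, AST and the fatty liver index) are
right-skewed; all association models use a rank-based inverse-normal
transformation Φ⁻¹((r − c)/(n − 2c + 1)) with Blom's offset c = 3/8
(configurable to c = 1/2 or c = 0 for sensitivity). Ties receive
average ranks; missing values propagate. The transform is applied per
analysis set (per cohort, and per stratum in stratified analyses),
matching a design in which each cohort is analysed separately before
pooling.

The fatty liver index uses triglycerides in mg/dl; inputs in mmol/l
are converted with the factor 88.57. The score is a logistic function
of a linear predictor and is strictly increasing in all four
components, bounded in (0, 100).

Alcohol enters models in two codings: a 3-level mediation covariate
(0 g/day; up to one 12 g standard drink/day, boundary inclusive; more
than one) and a weekly-consumption class (none; ≤ 350 g/week for
females / ≤ 420 g/week for males = moderate; above = excess). BMI
strata split at 25 kg/m².

## EWAS

Each CpG is tested with OLS of the transformed outcome on the CpG
beta-value plus covariates: age, sex, BMI, smoking, alcohol (g/day),
five of six cell-type proportions (one dropped — they sum to one),
technical principal components, and batch. Binary steatosis uses the
identical linear contract on the 0/1 indicator (a linear probability
model, so effects live on an interpretable probability scale next to
the crude Δbeta = mean(beta | cases) − mean(beta | controls)); a
logistic link is available by configuration. The implementation
residualizes outcome and methylation on the covariates
(Frisch–Waugh–Lovell), which is algebraically identical to the full
normal-equations fit and lets a whole cohort's scan run as one matrix
operation; CpGs with missing values fall back to per-CpG fits with
row-wise deletion. Constant CpGs are reported with missing statistics
rather than failing the scan. p-values are floored at 1e-320 to keep
downstream FDR machinery defined when t-statistics underflow.

Genomic inflation is λ = median(z²)/median(χ²₁), requiring ≥ 100
tests. When λ exceeds the trigger (default 1.1) and at least 1000
tests are available, an empirical-null correction is applied: a
three-component Gaussian mixture (dominant central null + left/right
tail components) is fitted by EM, initialized at null mean 0, SD 1,
weight 0.9 with three seeded random restarts. The null component's
mean is the bias and its SD the inflation; corrected statistics are
(z − bias)/inflation with two-sided normal p. EM is used instead of a
Gibbs sampler for determinism; to keep the decomposition identifiable
on (near-)pure-Gaussian input the M-step projects onto constraints:
tail means at least 3 null-SDs from the null mean, tail SDs at least
the null SD, null weight at least 0.5. Without these the tail
components absorb the null's shoulders and the null SD is
underestimated. Non-convergence returns raw statistics with a flag and
warning rather than corrected ones.

A note on evaluating the correction in simulations: with a planted 5%
fraction of true associations, the genomic inflation of *all*
corrected statistics has expectation ≈ 1.13 even if the correction is
perfect, because the mixture median sits at the 0.5/0.95 quantile of
the null. Recovery experiments therefore evaluate post-correction λ on
the ground-truth null tests, and report the all-test value alongside.

FDR control is step-up Benjamini–Hochberg with the cumulative-minimum
monotonicity step, applied to the final (corrected if correction ran)
p-vector.

## Meta-analysis and replication

Fixed-effect inverse-variance pooling: weights wᵢ = 1/SEᵢ², pooled
effect Σwᵢbᵢ/Σwᵢ, pooled SE (Σwᵢ)^(−1/2), Z and two-sided normal p,
plus a per-cohort sign ("direction") string in fixed cohort order with
"?" for missing cohorts. CpGs present in fewer than two cohorts are
excluded. Cochran's Q and I² are computed as diagnostics only — they
play no part in selection. FDR for the meta p-vector is computed over
all CpGs pooled in ≥ 2 cohorts. The replication rule keeps CpGs with
FDR q < 0.05 in at least two cohorts; direction consistency is *not*
required by default (an optional flag enforces it), since
heterogeneous-direction replication patterns occur in practice.
Cross-generation summaries order per-generation effects by cohort mean
age and flag CpGs whose |effect| increases strictly with age.

## Genetics

Variant QC: MAF ≥ 0.02 (computed from non-missing dosages), exact
Hardy–Weinberg p ≥ 1e−6, missingness strictly below 5%. The HWE test
is the standard exact conditional test (probabilities of heterozygote
counts given allele totals, summing configurations no more probable
than observed; no mid-p variant, matching the common PLINK default);
monomorphic variants get p = 1 by convention. cis-meQTL scans test
every QC-passed variant within a closed ±1 Mb window by additive
regression of methylation on dosage, without the EWAS covariates by
default (configurable); hits at p < 5e−8 are genome-wide significant
and the lowest-p hit is the top variant, ties broken by |distance|
then variant id. Missing dosages are dropped row-wise in regression.
Conditional models fit the liver variable on CpG + covariates and on
CpG + top variant + covariates over the identical complete-case
sample; near-collinear CpG/SNP pairs are flagged but both models are
still attempted. Coordinates are 1-based inclusive in memory; BED
interchange converts to 0-based half-open at the boundary.

## eQTM and mediation

Transcripts within a closed ±100 kb window of a CpG are tested with
OLS of expression on methylation adjusted for age, sex, BMI, smoking
and alcohol; pairs at nominal p < 0.05 become mediation candidates.

Mediation fits three OLS models on identical complete-case rows
(mismatched rows are a hard error because the in-sample identity
η₁ = γ₁ + β₁γ₂ would silently break):

    outcome  = η₀ + η₁·DNAm + η₂'C            (total effect η₁)
    outcome  = γ₀ + γ₁·DNAm + γ₂·GE + γ₃'C    (direct γ₁, mediator path γ₂)
    GE       = β₀ + β₁·DNAm + β₂'C            (first path β₁)

The mediation covariate set is age, sex, smoking and the 3-level
alcohol category — BMI is deliberately excluded because the BMI
stratification replaces adjustment; the EWAS covariate set is
selectable instead. The indirect effect β₁γ₂ gets a first-order
Delta-method SE √(γ₂²·var β₁ + β₁²·var γ₂) with zero cross-model
covariance (the two coefficients come from separate regressions; a
nonparametric bootstrap utility provides an independent cross-check
and agrees within a few percent at n = 1500). The proportion mediated
indirect/total uses the ratio gradient (1/T, −I/T²) with the same
plug-in zero-covariance convention and is reported as undefined, with
the reason, when |total| is below tolerance (the ratio is unstable
near a null total effect). Mediation is inferred when the indirect
95% CI excludes zero; an inconsistent-sign flag is raised when direct
and indirect effects disagree in sign. Valid causal interpretation
additionally requires the four exchangeability (no-unmeasured-
confounding) conditions, which are assumptions stated in the report
header, not testable properties.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any
particular real population:

- **Methylation**: per-CpG baselines drawn on the logit scale from a
  hypo/mid/hyper mixture, with cell-type (granulocyte-fraction) and
  batch structure on subsets of CpGs, inverse-logit transformed so
  beta-values stay in [0, 1]. Planted CpGs get mid-range baselines so
  effects have dynamic range.
- **Covariates**: age uniform around the cohort mean; BMI ≈
  N(25.5 + 0.09·(age − 40), 4) reflecting adult-cohort means near
  26–27 kg/m² (this also populates both BMI strata); waist tracks
  BMI; alcohol is a 30% zero-mass + gamma mixture (mean ≈ 14 g/day);
  six leukocyte proportions are Dirichlet with a granulocyte-dominated
  mean, summing to one.
- **Phenotypes**: a latent liver score L is linear in covariates and
  planted CpG beta-values, and GGT = exp(3.1 + L), so GGT is strictly
  positive and right-skewed while planted slopes are exact on the
  log-GGT scale (truth-recovery regressions target log GGT; the
  analyses themselves use inverse-normal transforms, which are
  monotone in log GGT). Steatosis is Bernoulli with a logistic link on
  L and BMI. Triglycerides are stored in mmol/l.
- **Age modulation**: planted slopes scale as
  (cohort mean age / 45)^k, default k = 1, reproducing a strictly
  older-stronger generational gradient without asserting a biological
  model.
- **Genetics**: allele frequencies uniform on [0.1, 0.5], genotypes
  HWE by construction, missingness MCAR (default 1%). The
  three-generation design draws each middle-generation (G1) allele
  from a G0 couple and each G2 allele from its G1 parent plus a
  population mate, so all trios are Mendelian-consistent. meQTLs add a
  per-allele beta-value shift (default 0.05), attached preferentially
  to CpGs that also carry phenotype or mediation effects so at least
  one CpG carries the full chain for end-to-end tracing.
- **Mediation path**: expression of a nearby gene = baseline +
  a·(methylation − ½) + noise; the liver score takes both a direct
  methylation term and b·(expression − baseline). Defaults a = −5
  (expression units per beta-unit), b = −0.3, direct = 1.0 — strong
  enough to be detectable at the simulated sample sizes while leaving
  realistic noise.
- **Determinism**: one master seed; per-cohort streams via fixed
  `SeedSequence` spawns; identical (config, seed) reproduces cohorts
  byte-identically (hash-verified).

What the simulator does **not** emulate: probe chemistry and type
I/II array effects, realistic LD (one causal variant per meQTL),
cross-reactive probes, cell-type deconvolution error (proportions are
taken as known inputs), non-MCAR genotype missingness, and technical
PCs that actually track batch (PCs are independent noise; batch is a
separate covariate). Passing tests therefore demonstrate calibration
and correctness of the statistical machinery under the assumed model,
not robustness to array artefacts or population structure.

## Probe/sample QC

Probes are removed when their detection p exceeds the threshold in
more than a configured fraction of samples (default 1%; the
per-sample vs any-sample reading of this rule differs between
pipelines, so the fraction rule is explicit in the removal report);
samples are removed when their call rate falls below 95%. The
detection-p threshold "10e−16" is read literally as 1e-15, with 1e-16
available by configuration. An empty post-QC matrix is a reported
warning, not a crash.

## Problem sizes

Simulation-based validations use: 10 cohorts of 5000 CpGs × 1000
samples for global-null calibration; 10⁴ z-scores for empirical-null
recovery; 200 replicates of n = 1500 for mediation CI coverage with a
1000-replicate bootstrap cross-check; 500 random genotype tables
(n ≤ 200) against exact-rational enumeration; and an end-to-end
pipeline of three cohorts plus three generations at 600 samples × 500
CpGs. These sizes give each check adequate power (e.g. a planted
meQTL of 0.05 beta-units/allele has |t| ≈ 9 at n = 600) while keeping
the whole suite fast.

## Known limitations

- The linear probability model for binary steatosis can predict
  outside [0, 1]; the logistic option avoids this at the cost of a
  different effect scale.
- The Delta-method proportion-mediated CI is unreliable when the total
  effect is small relative to its SE; the implementation reports the
  ratio as undefined below a tolerance and offers the bootstrap.
- The empirical-null constraints assume true associations are well
  separated (≥ 3 null-SDs) from the null; diffuse weak signal will be
  absorbed into the null and look like inflation, which is the
  standard behaviour of empirical-null methods.
- Fixed-effects meta-analysis only; heterogeneity is reported (Q, I²)
  but never modelled.
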