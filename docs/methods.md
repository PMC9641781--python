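# Methods

## The causal model and its assumptions

The pipeline estimates the effect of a genetically predicted exposure
(leukocyte telomere length, in SD units) on quantitative outcomes using
independent SNPs as instrumental variables. The standard MR assumptions
apply: each instrument is (i) associated with the exposure, (ii)
independent of confounders of the exposure–outcome relation, and (iii)
affects the outcome only through the exposure. The design is two-sample:
SNP–exposure effects come from an external GWAS (summary statistics only),
SNP–outcome effects from covariate-adjusted linear regressions in the
analysis cohort. Instruments are assumed mutually independent (no LD);
LD pruning is out of scope because the panel is selected as independent
hits.

## Estimators

* **IVW** — inverse-variance-weighted mean of the per-SNP Wald ratios,
  identical to weighted least squares of β_Y on β_X through the origin with
  weights σ_Y⁻². Two flavors are always available: *fixed-effect*
  (SE = (Σw)^(−1/2)) and *multiplicative random-effects*, which scales the
  SE by max(1, √(Q/(J−1))). The floor means the random-effects SE never
  falls below the fixed-effect SE; under an exact null it is therefore
  mildly conservative (type-I error ≈ 3% rather than 5%), while the
  fixed-effect flavor is analytically calibrated. The random-effects flavor
  is the reporting default (robust to mild heterogeneity); the fixed-effect
  flavor is the reference in calibration checks.
* **Maximum likelihood** — treats (β_X_j, β_Y_j) as independent normals
  around (μ_j, θμ_j). Profiling out μ_j gives the closed-form marginal
  −½Σ(β_Y_j − θβ_X_j)²/(σ_Y_j² + θ²σ_X_j²), maximized by bounded 1-d
  search; the SE is the inverse square root of the observed information
  (central-difference curvature at the optimum). Unlike IVW this propagates
  the SNP–exposure uncertainty (no NOME assumption).
* **Weighted median** — interpolated 50% point of the weight-ordered
  ratios; consistent when valid instruments carry ≥ half the weight. SE by
  parametric bootstrap (resampling β_X, β_Y from normals with the reported
  SEs; default 1,000 draws, seed recorded in the estimate).
* **Weighted mode** — argmax of a weighted Gaussian KDE over the ratios
  with bandwidth φ·0.9·min(sd, iqr/1.34)·J^(−1/5) (φ = 1 by default),
  located on a 2,048-point grid then refined by bounded minimization;
  bootstrap SE as above. Consistent under the plurality-valid assumption.
* **MR-Egger** — weighted LS of β_Y on (1, β_X) after orienting all
  β_X ≥ 0; the intercept estimates average directional pleiotropy, the
  slope the causal effect under InSIDE. SEs carry a multiplicative
  overdispersion factor max(1, √(Q_egger/(J−2))); p-values use t on J−2 df.
  All other estimators use normal (1.96) intervals.

## Sensitivity battery

Cochran's Q (centered on fixed-effect IVW by definition, χ² on J−1 df);
the Egger intercept t-test; MR-PRESSO with leave-one-out fitted values,
parametric null simulation (default 1,000 draws), +1-smoothed empirical
global p, Bonferroni-adjusted per-SNP outlier p-values (α = 0.05), an
outlier-removed corrected IVW, and an informational distortion test; and
leave-one-SNP-out IVW with flags for p-values crossing 0.05.

## Outcome derivation

Cognitive composites average within-cohort z-scores of their components
(mPACC: immediate total paired recall, delayed free recall, coding,
semantic fluency; domain composites: all subtests of a domain).
Individuals with at least half of a composite's components observed get
the mean of the available z-scores, otherwise missing. Thickness
signatures are unweighted means over the named region sets of the
bilateral (L/R-averaged) thickness, in mm (9 AD-signature regions, 8
aging-signature regions; a surface-area-weighted variant was considered
and left to configuration since the region weighting is not standardized).
The CSF amyloid outcome is the Aβ42/40 ratio; other analytes pass through
on their native assay scale. Outcomes are analyzed unstandardized — a
raw-unit biomarker effect is only interpretable on its own scale.

## Strata and multiplicity

ε2/ε4 individuals (phase-ambiguous double heterozygotes under the no-ε1
convention) are excluded from **all** analyses. The whole-sample
regressions adjust for age, sex, education and APOE-ε4; all stratified
regressions (APOE carriers/non-carriers, PRS high/low at the
75th-percentile split, strict inequality, linear-interpolation quantile)
adjust for age, sex and education only — within APOE strata the carrier
covariate is constant, and the stratified models are deliberately uniform
across strata. Benjamini–Hochberg FDR is applied within one endophenotype
family, one stratum, one method (pooling methods into a single block is
available but off by default, since per-method q-values are what a
per-method results table reports). The labels are *fdr_significant*
(q < 0.05), *nominal* (p < 0.05 only), *null*.

## The synthetic cohort generator

The generator emulates the study conditions: ~20 instrument SNPs with
allele frequencies uniform on [0.05, 0.95]; per-allele exposure effects
positive (the effect allele is the longer-exposure allele) and drawn
conditional on genome-wide discoverability — the expected GWAS z-score is
6.5 + half-normal(4), so every simulated instrument would survive the
p < 5×10⁻⁸ selection that defines a hit panel; the implied exposure
heritability of the panel is ~2%. External GWAS summary statistics use the
unit-variance analytic SE 1/√(2p(1−p)n) at n = 78,592 (an exact mode
simulating individuals exists for small n). Cohort genotypes are
binomial(2, p) (HWE by construction); the latent exposure is the genetic
score plus confounder and noise with the noise variance chosen so the
population variance is exactly 1 (a population-level standardization —
empirical rescaling would perturb the per-allele effects relative to the
external GWAS). Outcomes are built on a standardized scale — causal term
θ/sd_f·X, pleiotropic term Σa_j g_j (a_j in outcome-SD per allele),
confounder, covariate effects (age −0.02 SD/yr, sex 0.1 SD, education
0.02 SD/yr), noise — then mapped to native units: a unit-SD cognition
composite, a thickness signature (mean 2.5 mm, SD ≈ 0.1 mm), and a
right-skewed NfL-style biomarker (lognormal noise), so θ is always in
native outcome units per SD of exposure. Covariates are age ~ U(45, 74),
sex ~ Bernoulli(0.5), education ~ N(12, 3.5). APOE genotypes come from
independent (ε2, ε3, ε4) haplotype draws at (0.08, 0.72, 0.20) — an
AD-enriched carrier fraction of 1 − 0.8² = 0.36. The PRS SNP set is
disjoint from the instruments with its own half-normal weights, as a
disease-GWAS hit list is from an exposure-GWAS hit list.

What the generator does **not** emulate: LD between instruments,
imputation uncertainty beyond optional fractional dosages, assay
measurement processes, non-random missingness, or population
stratification. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under its stated assumptions, not
robustness to those real-data complications.

## Numerical choices and degenerate inputs

Harmonization resolves strand flips by Watson–Crick complementing;
strand-ambiguous (A/T, C/G) SNPs are oriented by comparing effect-allele
frequencies and dropped when either frequency lies in [0.42, 0.58] or
frequencies are unavailable. Proxy instruments need r² ≥ 0.9 unless
whitelisted (two published exceptions ship as defaults). The HWE test is
the exact conditional (Levene/Haldane) two-sided test computed in log
space. Per-SNP regressions use complete cases per SNP, guard against
collinearity via the design condition number (limit 10¹⁰), and reject
zero-variance dosages. Weighted-mode bandwidth zero (all ratios equal)
returns that common ratio. Empirical p-values are floored at 1/(n_sim+1).
All stochastic procedures require a seed and record it in their outputs;
study cells derive per-cell seeds deterministically from the master seed.

## Validation problem sizes

The validation studies (`endomr.validation`) use 1,000 replicates for
calibration via the analytic summary-statistic shortcut (drawing β_X, β_Y
directly from their sampling distributions — first-order identical to
simulating a cohort), 200 replicates of the full individual-level pipeline
at n = 1,000 for parameter recovery, and 200 replicates for the
pleiotropy-machinery power studies; these sizes give Monte-Carlo SEs of
~0.7% on rejection rates and ~0.0016 on the recovery bias, small relative
to the effects being checked.

## Known limitations

Ratio SEs are first-order delta approximations (NOME) except in the ML
estimator; no Steiger filtering, winner's-curse correction, SIMEX, radial
MR, or multivariable MR; instruments must be pre-pruned for LD; the
MR-PRESSO distortion test is reported but not acted on. With an outlier
planted on a randomly chosen instrument of a 20-SNP panel at 10× its
outcome SE, outlier removal improves the point estimate in ~85% of
replicates (not more — the improvement probability is Φ(5·b_k/‖b‖) for an
outlier on instrument k, a scale-invariant geometric limit of the panel's
strength distribution).
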