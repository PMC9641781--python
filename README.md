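# endomr

Two-sample Mendelian randomization (MR) of genetically predicted telomere
length on Alzheimer's-disease **endophenotypes** — cognitive composites,
cortical-thickness signatures, and CSF biomarkers — for epidemiologists and
biostatisticians who have individual-level cohort data for the outcomes but
rely on an external GWAS for the exposure.

## The method

For each instrument SNP *j*, the per-allele effect on the exposure
(β<sub>X<sub>j</sub></sub>, in SD of telomere length, with SE σ<sub>X<sub>j</sub></sub>)
comes from external GWAS summary statistics, harmonized so the effect allele
is the longer-telomere allele. The per-allele effect on each outcome
(β<sub>Y<sub>j</sub></sub>, σ<sub>Y<sub>j</sub></sub>) is estimated in-sample by OLS
adjusted for age, sex, years of education, and APOE-ε4 status. The per-SNP
Wald ratio β<sub>Y<sub>j</sub></sub>/β<sub>X<sub>j</sub></sub> estimates the
causal effect; the inverse-variance-weighted (IVW) estimate

&nbsp;&nbsp;β̂<sub>IVW</sub> = Σ w<sub>j</sub> (β<sub>Y<sub>j</sub></sub>/β<sub>X<sub>j</sub></sub>) / Σ w<sub>j</sub>,&nbsp;&nbsp;w<sub>j</sub> = (σ<sub>Y<sub>j</sub></sub>/|β<sub>X<sub>j</sub></sub>|)<sup>−2</sup>

pools them (equivalently, weighted LS of β<sub>Y</sub> on β<sub>X</sub>
through the origin), in outcome units per SD of genetically predicted
exposure. Four robust estimators accompany it — maximum likelihood
(modelling σ<sub>X</sub>), weighted median, weighted mode, and MR-Egger
regression — plus a sensitivity battery: Cochran's Q, the MR-Egger
intercept test for directional pleiotropy, MR-PRESSO global/outlier tests
with an outlier-corrected estimate, and leave-one-SNP-out. Analyses are
stratified (entire sample, APOE-ε4 carriers/non-carriers, high/low
polygenic-risk group; ε2/ε4 individuals excluded) and Benjamini–Hochberg
FDR is applied within each endophenotype family per stratum.

Because the cohort that motivated this design is not publicly deposited,
the package ships a first-class synthetic-cohort generator
(`endomr.synthetic_cohort`) reproducing the statistical structure the
estimators assume — HWE genotypes, a unit-variance latent exposure,
confounding, configurable causal effects, balanced/directional/outlier
pleiotropy, APOE haplotypes and an independent PRS SNP set.

## Worked example

Simulate a cohort of 1,000 with a true causal effect of 0.06 mm of cortical
thickness per SD of exposure, then run the whole pipeline:

```python
from endomr import SimulationConfig, simulate_study, build_strata, run_study

cfg = SimulationConfig(n_cohort=1000, theta=0.06, seed=42)
study = simulate_study(cfg)
strata = build_strata(study.cohort.apoe_genotypes,
                      study.prs_dosages, study.prs_weights)
res = run_study(study.exposure_gwas, study.cohort.dosages,
                study.cohort.covariates, study.cohort.outcomes,
                {"thickness_signature": "imaging"},
                strata, n_boot=1000, n_sim=1000, seed=7)
print(res.grid.loc[res.grid.stratum == "whole",
      ["method", "beta", "se", "pval", "qval"]].round(4))
```

```
         method    beta     se   pval   qval
     ivw_random  0.0357 0.0270 0.1865 0.1865
 max_likelihood  0.0360 0.0272 0.1844 0.1844
weighted_median  0.0379 0.0384 0.3236 0.3236
  weighted_mode  0.0339 0.0676 0.6158 0.6158
    egger_slope  0.1587 0.1094 0.1640 0.1640
egger_intercept -0.0067 0.0058 0.2609    NaN
```

The IVW estimate 0.036 ± 0.027 covers the true effect 0.06 within its 95%
CI (a single replicate at n = 1,000 has limited power; over 200 replicates
the mean bias is below 0.001 — see the acceptance script). The sensitivity
battery for the same cell reports no pleiotropy, as it should here:
`Cochran Q p = 0.635, MR-PRESSO global p = 0.573, Egger intercept p = 0.261`.

The same pipeline runs from files via the CLI:

```sh
endomr simulate --config sim.yaml --out data/
endomr run --config study.yaml --out results/
```

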