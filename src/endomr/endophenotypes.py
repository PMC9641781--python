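"""Outcome derivation and per-SNP covariate-adjusted association models.

Three endophenotype families are supported:

* **cognition** — composites built from z-scored subtests: a modified
  preclinical Alzheimer cognitive composite (mPACC) averaging four specific
  measures, and domain composites (episodic memory, executive function)
  averaging all subtests of a domain;
* **imaging** — cortical-thickness signatures: the unweighted mean over a
  named region set of the bilateral (left/right averaged) thickness, in mm;
* **csf** — cerebrospinal-fluid analytes on their native assay scale, with
  the Abeta42/40 ratio as the amyloid-pathology outcome.

The module's contract with the MR estimators is
:func:`snp_outcome_regression`: ordinary least squares of an outcome on one
SNP's dosage plus covariates, returning the dosage coefficient as the
per-allele SNP–outcome effect beta_Y with its classical standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeSpec",
    "AssociationResult",
    "AD_SIGNATURE_REGIONS",
    "AGING_SIGNATURE_REGIONS",
    "zscore",
    "compute_mpacc",
    "compute_domain_composite",
    "compute_signature",
    "compute_abeta_ratio",
    "snp_outcome_regression",
    "snp_outcome_associations",
]

#: regions preferentially thinned in Alzheimer's disease
AD_SIGNATURE_REGIONS = (
    "medial_temporal", "inferior_temporal", "temporal_pole",
    "superior_parietal", "precuneus", "angular", "supramarginal",
    "superior_frontal", "middle_frontal",
)

#: regions preferentially thinned in normal aging
AGING_SIGNATURE_REGIONS = (
    "calcarine", "caudal_insula", "cuneus", "caudal_fusiform",
    "dorsomedial_frontal", "lateral_occipital", "precentral",
    "inferior_frontal",
)

_FAMILIES = ("cognition", "imaging", "csf")


@dataclass(frozen=True)
class OutcomeSpec:
    """Registry entry mapping raw columns to one derived outcome."""

    name: str
    family: str
    components: tuple
    transform: str = "identity"   # zscore_mean | bilateral_region_mean | ratio | identity

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if not self.components:
            raise ValueError("components must be non-empty")
        object.__setattr__(self, "components", tuple(self.components))


@dataclass(frozen=True)
class AssociationResult:
    rsid: str
    outcome: str
    stratum: str
    beta_y: float
    se_y: float
    pval: float
    n_used: int

    def __post_init__(self):
        if not (self.se_y > 0):
            raise ValueError(f"{self.rsid}/{self.outcome}: non-positive SE")


def zscore(values) -> pd.Series:
    """Standardize to mean 0, SD 1 (n-1 denominator) over non-missing entries.

    Missing values are propagated unchanged; a constant input raises.
    """
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    obs = s.dropna()
    if len(obs) < 2:
        raise ValueError("need at least 2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-score undefined")
    return (s - obs.mean()) / sd


def _mean_of_zscores(df: pd.DataFrame, min_fraction: float = 0.5) -> pd.Series:
    z = pd.concat([zscore(df[c]) for c in df.columns], axis=1)
    n_obs = z.notna().sum(axis=1)
    out = z.mean(axis=1, skipna=True)
    # individuals with fewer than half the components observed get no composite
    out[n_obs < np.ceil(min_fraction * z.shape[1])] = np.nan
    out[n_obs == 0] = np.nan
    return out


def compute_mpacc(
    mbt_total_paired, mbt_delayed_free, coding, semantic_fluency
) -> pd.Series:
    """Modified preclinical Alzheimer cognitive composite.

    The per-individual mean of the z-scores of four measures: immediate
    total paired recall and delayed free recall from the memory binding
    test, the WAIS-IV coding subtest, and semantic fluency.  Individuals
    with at least half of the components observed get the mean of the
    available z-scores; others are missing.
    """
    df = pd.DataFrame({
        "mbt_total_paired": np.asarray(mbt_total_paired, dtype=float),
        "mbt_delayed_free": np.asarray(mbt_delayed_free, dtype=float),
        "coding": np.asarray(coding, dtype=float),
        "semantic_fluency": np.asarray(semantic_fluency, dtype=float),
    })
    return _mean_of_zscores(df)


def compute_domain_composite(subtest_matrix: pd.DataFrame) -> pd.Series:
    """Domain composite: mean of z-scored subtests (any component count).

    Used for episodic memory (memory-binding-test subtests) and executive
    function (WAIS-IV subtests).
    """
    if subtest_matrix.shape[1] < 1:
        raise ValueError("need at least one subtest column")
    return _mean_of_zscores(pd.DataFrame(subtest_matrix))


def compute_signature(
    thickness_left: pd.DataFrame,
    thickness_right: pd.DataFrame,
    region_set: Sequence[str],
) -> pd.Series:
    """Cortical-thickness signature: unweighted mean of bilateral means.

    For each region the left/right hemisphere thicknesses are averaged;
    the signature is the plain mean of those bilateral means over the
    region set (mm; higher = thicker).  Any missing region value makes the
    individual's signature missing.
    """
    region_set = list(region_set)
    missing = [r for r in region_set
               if r not in thickness_left.columns or r not in thickness_right.columns]
    if missing:
        raise KeyError(f"regions absent from thickness tables: {missing}")
    bilateral = (thickness_left[region_set].astype(float)
                 + thickness_right[region_set].astype(float)) / 2.0
    return bilateral.mean(axis=1, skipna=False)


def compute_abeta_ratio(ab42, ab40) -> pd.Series:
    """CSF Abeta42/40 ratio (amyloid-pathology biomarker)."""
    a42 = pd.Series(np.asarray(ab42, dtype=float))
    a40 = pd.Series(np.asarray(ab40, dtype=float))
    if np.any(a40.dropna() <= 0):
        raise ValueError("Abeta40 must be strictly positive")
    return a42 / a40


def snp_outcome_regression(
    dosage,
    outcome,
    covariates: pd.DataFrame,
    rsid: str = "",
    outcome_name: str = "",
    stratum: str = "",
    adjust_apoe: bool = True,
    robust: bool = False,
    max_condition: float = 1e10,
) -> AssociationResult:
    """Per-allele SNP–outcome effect from covariate-adjusted OLS.

    Regresses the outcome on (intercept, dosage, covariates) over complete
    cases and returns the dosage coefficient with its classical standard
    error (sigma^2 (X'X)^-1, n-k denominator) and two-sided t p-value.
    ``adjust_apoe=False`` drops the ``apoe_e4`` covariate column — the rule
    inside strata that are themselves defined by carrier status.
    ``robust=True`` switches to HC3 heteroskedasticity-robust SEs.
    """
    import statsmodels.api as sm

    cov = covariates.copy()
    if not adjust_apoe and "apoe_e4" in cov.columns:
        cov = cov.drop(columns=["apoe_e4"])
    df = pd.DataFrame({"__y": np.asarray(outcome, dtype=float),
                       "__g": np.asarray(dosage, dtype=float)})
    df = pd.concat([df, cov.reset_index(drop=True)], axis=1).dropna()
    k = 2 + cov.shape[1]
    if len(df) < k + 2:
        raise ValueError(
            f"{rsid}/{outcome_name}: only {len(df)} complete cases for {k} regressors")
    if df["__g"].std(ddof=1) == 0:
        raise ValueError(f"{rsid}: zero-variance dosage in analysis set")
    design = sm.add_constant(df.drop(columns="__y"), has_constant="add")
    cond = np.linalg.cond(design.to_numpy())
    if cond > max_condition:
        raise ValueError(f"{rsid}/{outcome_name}: collinear design "
                         f"(condition number {cond:.2e})")
    fit = sm.OLS(df["__y"], design).fit(cov_type="HC3" if robust else "nonrobust")
    return AssociationResult(
        rsid=rsid, outcome=outcome_name, stratum=stratum,
        beta_y=float(fit.params["__g"]), se_y=float(fit.bse["__g"]),
        pval=float(fit.pvalues["__g"]), n_used=int(fit.nobs),
    )


def snp_outcome_associations(
    dosages: pd.DataFrame,
    outcome,
    covariates: pd.DataFrame,
    outcome_name: str = "",
    stratum: str = "",
    adjust_apoe: bool = True,
    robust: bool = False,
) -> pd.DataFrame:
    """Run :func:`snp_outcome_regression` for every SNP column.

    Missing dosages are handled per SNP (complete cases for that SNP only).
    SNPs whose regression is not estimable (zero variance, too few cases)
    are skipped with a note in the ``note`` column of the returned frame.
    """
    rows = []
    for rsid in dosages.columns:
        try:
            res = snp_outcome_regression(
                dosages[rsid], outcome, covariates, rsid=rsid,
                outcome_name=outcome_name, stratum=stratum,
                adjust_apoe=adjust_apoe, robust=robust,
            )
            rows.append({"rsid": rsid, "beta_y": res.beta_y, "se_y": res.se_y,
                         "pval": res.pval, "n_used": res.n_used, "note": ""})
        except ValueError as exc:
            rows.append({"rsid": rsid, "beta_y": np.nan, "se_y": np.nan,
                         "pval": np.nan, "n_used": 0, "note": str(exc)})
    out = pd.DataFrame(rows)
    out.insert(1, "outcome", outcome_name)
    out.insert(2, "stratum", stratum)
    return out
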