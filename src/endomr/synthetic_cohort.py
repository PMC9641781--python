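"""Synthetic exposure GWAS and individual-level cohort generator.

The MR analysis needs two data sources that cannot be redistributed: the
external exposure GWAS (per-SNP effects of ~20 independent variants on
telomere length, meta-analyzed in ~78,592 individuals) and an
individual-level cohort of middle-aged participants with genotypes,
covariates and endophenotype outcomes.  This module generates both with the
statistical structure the estimators assume — and with controlled
violations (confounding, balanced/directional pleiotropy, single outlier
SNPs) so every sensitivity procedure can be exercised against a known
truth.

Generative model
----------------
Instrument genotypes are independent binomial(2, p_j) draws (Hardy–Weinberg
by construction).  The latent exposure is

    X_i = sum_j b_j (g_ij - 2 p_j) + c_X C_i + s_X e_i,

with per-allele effects ``b_j`` drawn conditional on genome-wide
discoverability in the external sample (see :func:`simulate_true_panel`)
and ``s_X`` chosen so X has unit population variance — so ``b_j`` is in
SD-of-exposure units and any causal effect downstream is per SD of
exposure.  Each outcome family is built on a
standardized scale,

    Y*_i = (theta/sd_f) X_i + sum_j a_j g_ij + c_Y C_i + covariate terms + noise,

then mapped to native units ``Y = offset_f + sd_f * Y*`` (unit-SD cognition
composite, mm-scale cortical thickness with mean 2.5 and SD 0.1, NfL-style
right-skewed biomarker), so ``theta`` is always in native outcome units per
SD of exposure.  Pleiotropic effects ``a_j`` are in outcome-SD units per
allele copy.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr_core import MRInput

__all__ = [
    "TruePanel",
    "OutcomeFamilySpec",
    "SimulationConfig",
    "SyntheticCohort",
    "DEFAULT_FAMILIES",
    "simulate_true_panel",
    "simulate_external_gwas",
    "simulate_cohort",
    "simulate_apoe",
    "simulate_prs_panel",
    "simulate_summary_mrinput",
    "simulate_study",
    "export_study",
]

_PLEIOTROPY_MODES = ("none", "balanced", "directional", "single_outlier")
# unambiguous allele pairs only, so harmonization never has to drop a SNP
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass(frozen=True)
class TruePanel:
    """Ground truth for the instrument SNPs."""

    rsid: tuple
    eaf: np.ndarray            # effect-allele frequency, in (0,1)
    beta_x_true: np.ndarray    # SD of exposure per effect-allele copy
    alpha_pleio: np.ndarray    # direct SNP->outcome effect, outcome SDs per allele
    effect_allele: tuple = ()
    other_allele: tuple = ()

    def __post_init__(self):
        for name in ("eaf", "beta_x_true", "alpha_pleio"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.rsid)
        if not (len(self.eaf) == len(self.beta_x_true) == len(self.alpha_pleio) == n):
            raise ValueError("all TruePanel fields must have equal length")
        if np.any((self.eaf <= 0) | (self.eaf >= 1)):
            raise ValueError("allele frequencies must lie strictly inside (0,1)")
        if np.all(self.beta_x_true == 0):
            raise ValueError("beta_x_true must not be all zero")

    @property
    def n_snps(self) -> int:
        return len(self.rsid)


@dataclass(frozen=True)
class OutcomeFamilySpec:
    """Scale and noise shape of one synthetic endophenotype."""

    name: str
    family: str                 # cognition | imaging | csf
    offset: float
    sd: float                   # native-unit SD of the non-causal part
    noise: str = "normal"       # normal | lognormal (right-skewed)


#: default outcome families: a unit-SD cognitive composite, a mm-scale
#: cortical-thickness signature, and a right-skewed NfL-style CSF analyte.
DEFAULT_FAMILIES = (
    OutcomeFamilySpec("cognition_composite", "cognition", offset=0.0, sd=1.0),
    OutcomeFamilySpec("thickness_signature", "imaging", offset=2.5, sd=0.1),
    OutcomeFamilySpec("csf_nfl", "csf", offset=80.0, sd=40.0, noise="lognormal"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_snps: int = 20
    n_external: int = 78_592
    n_cohort: int = 2_233
    theta: float = 0.0                   # causal effect, outcome units per SD exposure
    instrument_z_min: float = 6.5        # smallest expected GWAS |z| of an instrument
    instrument_z_spread: float = 4.0     # half-normal spread of |z| above the minimum
    confounder_exposure: float = 0.0     # c_X, SD-of-exposure units
    confounder_outcome: float = 0.0      # c_Y, outcome-SD units
    pleiotropy_mode: str = "none"
    pleiotropy_scale: float = 0.05       # outcome SDs per allele
    age_effect: float = -0.02            # outcome SDs per year (age centered at 60)
    sex_effect: float = 0.1              # outcome SDs (male vs female)
    education_effect: float = 0.02       # outcome SDs per year (centered at 12)
    outcome_noise_sd: float = 1.0        # on the standardized outcome scale
    families: tuple = DEFAULT_FAMILIES
    apoe_haplotype_freqs: tuple = (0.08, 0.72, 0.20)   # (e2, e3, e4)
    n_prs_snps: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_external < 1 or self.n_cohort < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {_PLEIOTROPY_MODES}")
        if self.pleiotropy_scale < 0:
            raise ValueError("pleiotropy_scale must be >= 0")
        if self.outcome_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if self.instrument_z_min <= 0 or self.instrument_z_spread < 0:
            raise ValueError("instrument strength parameters must be positive")
        if abs(self.confounder_exposure) >= 1:
            raise ValueError("confounder_exposure^2 must be < 1 "
                             "for a unit-variance exposure")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = [dataclasses.asdict(f) for f in self.families]
        return d


@dataclass
class SyntheticCohort:
    dosages: pd.DataFrame        # individuals x SNPs, values in [0,2]
    covariates: pd.DataFrame     # age, sex, education, apoe_e4
    exposure: pd.Series          # latent exposure, SD units
    outcomes: pd.DataFrame       # one column per outcome family
    apoe_genotypes: pd.DataFrame
    confounder: pd.Series
    truth: dict                  # config + true panel record


def simulate_true_panel(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> TruePanel:
    """Draw the ground-truth instrument panel.

    Frequencies are uniform on [0.05, 0.95].  Per-allele exposure effects
    are all positive (the effect allele is by construction the
    longer-exposure allele, matching the harmonization convention) and are
    drawn conditional on genome-wide discoverability, as a GWAS hit list
    is: the expected association z-score in the external sample is
    ``instrument_z_min`` plus a half-normal with scale
    ``instrument_z_spread``, and the per-allele effect follows as
    ``b_j = z_j / sqrt(2 p_j (1-p_j) n_external)``.  At the defaults the
    realized exposure variance explained by the panel is ~2%, matching a
    telomere-length hit panel.  Pleiotropic direct effects follow
    ``pleiotropy_mode``: all zero (``none``), zero-mean normal
    (``balanced``), all-positive half-normal (``directional``), or zero
    except one SNP carrying ``pleiotropy_scale`` (``single_outlier``).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    j = config.n_snps
    eaf = rng.uniform(0.05, 0.95, size=j)
    z = config.instrument_z_min + np.abs(rng.standard_normal(j)) * config.instrument_z_spread
    beta = z * _analytic_se_x(eaf, config.n_external)

    mode, scale = config.pleiotropy_mode, config.pleiotropy_scale
    if mode == "none":
        alpha = np.zeros(j)
    elif mode == "balanced":
        alpha = rng.normal(0.0, scale, size=j)
    elif mode == "directional":
        alpha = np.abs(rng.normal(0.0, scale, size=j))
    else:  # single_outlier
        alpha = np.zeros(j)
        alpha[rng.integers(j)] = scale
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(len(_ALLELE_PAIRS), size=j)]
    return TruePanel(
        rsid=tuple(f"rs{1000001 + 7 * k}" for k in range(j)),
        eaf=eaf, beta_x_true=beta, alpha_pleio=alpha,
        effect_allele=tuple(p[0] for p in pairs),
        other_allele=tuple(p[1] for p in pairs),
    )


def _analytic_se_x(eaf: np.ndarray, n_external: int) -> np.ndarray:
    # regression SE of a per-allele effect on a unit-variance trait
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_external)


def simulate_external_gwas(
    panel: TruePanel,
    n_external: int,
    seed: int = 0,
    mode: str = "analytic",
) -> pd.DataFrame:
    """Exposure summary statistics as the external GWAS would report them.

    ``mode='analytic'`` (default) uses the unit-variance approximation
    ``se_j = 1/sqrt(2 p_j (1-p_j) n)`` and draws the reported effect as
    ``beta_x_true + N(0, se_j)``; ``mode='individual'`` actually simulates
    ``n_external`` genotype/exposure pairs and runs the per-SNP regressions
    (use only for small n).  P-values come from the Wald statistic.
    """
    if n_external < 1:
        raise ValueError("n_external must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "analytic":
        se = _analytic_se_x(panel.eaf, n_external)
        beta = panel.beta_x_true + rng.normal(0.0, se)
    elif mode == "individual":
        g = rng.binomial(2, panel.eaf, size=(n_external, panel.n_snps)).astype(float)
        noise_sd = np.sqrt(1.0 - np.sum(panel.beta_x_true ** 2
                                        * 2 * panel.eaf * (1 - panel.eaf)))
        x = (g - 2 * panel.eaf) @ panel.beta_x_true + rng.normal(0, noise_sd, n_external)
        beta = np.empty(panel.n_snps)
        se = np.empty(panel.n_snps)
        for k in range(panel.n_snps):
            gk = g[:, k]
            vk = gk.var(ddof=1)
            b = np.cov(gk, x, ddof=1)[0, 1] / vk
            resid = x - x.mean() - b * (gk - gk.mean())
            s2 = np.sum(resid ** 2) / (n_external - 2)
            beta[k] = b
            se[k] = np.sqrt(s2 / (vk * (n_external - 1)))
    else:
        raise ValueError("mode must be 'analytic' or 'individual'")
    z = beta / se
    return pd.DataFrame({
        "rsid": list(panel.rsid),
        "chr": [1 + k % 22 for k in range(panel.n_snps)],
        "pos": [100_000 * (k + 1) for k in range(panel.n_snps)],
        "effect_allele": list(panel.effect_allele) or ["A"] * panel.n_snps,
        "other_allele": list(panel.other_allele) or ["G"] * panel.n_snps,
        "beta": beta, "se": se, "pval": 2.0 * stats.norm.sf(np.abs(z)),
        "eaf": panel.eaf,
    })


def _standardized_noise(rng, n, kind):
    if kind == "normal":
        return rng.standard_normal(n)
    if kind == "lognormal":
        sigma = 0.5
        m = np.exp(sigma ** 2 / 2)
        s = np.sqrt((np.exp(sigma ** 2) - 1) * np.exp(sigma ** 2))
        return (rng.lognormal(0.0, sigma, n) - m) / s
    raise ValueError(f"unknown noise kind {kind!r}")


def simulate_cohort(panel: TruePanel, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Individual-level cohort under the generative model in the module docstring.

    Covariates emulate a middle-aged research cohort: age uniform on
    [45, 74], sex Bernoulli(0.5), education normal(12, 3.5) years; the APOE
    carrier covariate comes from :func:`simulate_apoe` haplotypes.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_cohort
    min_rows = 6 + 2  # intercept + dosage + 4 covariates, plus df for error
    if n < min_rows:
        raise ValueError(f"n_cohort must be at least {min_rows}")
    g = rng.binomial(2, panel.eaf, size=(n, panel.n_snps)).astype(float)
    conf = rng.standard_normal(n)
    genetic_var = float(np.sum(panel.beta_x_true ** 2 * 2 * panel.eaf * (1 - panel.eaf)))
    resid_var = 1.0 - genetic_var - config.confounder_exposure ** 2
    if resid_var <= 0:
        raise ValueError("panel genetic variance plus confounding exceeds the "
                         "unit exposure variance")
    s_x = np.sqrt(resid_var)
    exposure = ((g - 2 * panel.eaf) @ panel.beta_x_true
                + config.confounder_exposure * conf
                + s_x * rng.standard_normal(n))

    age = rng.uniform(45.0, 74.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    education = rng.normal(12.0, 3.5, n)
    apoe = simulate_apoe(n, config.apoe_haplotype_freqs, rng=rng)

    iid = [f"I{k:05d}" for k in range(1, n + 1)]
    covariates = pd.DataFrame({
        "age": age, "sex": sex, "education": education,
        "apoe_e4": apoe["e4_carrier"].astype(int).to_numpy(),
    }, index=iid)

    cov_part = (config.age_effect * (age - 60.0)
                + config.sex_effect * sex
                + config.education_effect * (education - 12.0))
    outcomes = {}
    for fam in config.families:
        y_std = (config.theta / fam.sd * exposure
                 + g @ panel.alpha_pleio
                 + config.confounder_outcome * conf
                 + cov_part
                 + config.outcome_noise_sd * _standardized_noise(rng, n, fam.noise))
        outcomes[fam.name] = fam.offset + fam.sd * y_std

    return SyntheticCohort(
        dosages=pd.DataFrame(g, index=iid, columns=list(panel.rsid)),
        covariates=covariates,
        exposure=pd.Series(exposure, index=iid, name="exposure"),
        outcomes=pd.DataFrame(outcomes, index=iid),
        apoe_genotypes=apoe.set_index(pd.Index(iid)),
        confounder=pd.Series(conf, index=iid, name="confounder"),
        truth={
            "config": config.as_dict(),
            "panel": {
                "rsid": list(panel.rsid),
                "eaf": panel.eaf.tolist(),
                "beta_x_true": panel.beta_x_true.tolist(),
                "alpha_pleio": panel.alpha_pleio.tolist(),
            },
        },
    )


_HAPLOTYPES = ("e2", "e3", "e4")
_HAP_ALLELES = {"e2": ("T", "T"), "e3": ("T", "C"), "e4": ("C", "C")}


def simulate_apoe(
    n: int,
    haplotype_freqs: Sequence[float] = (0.08, 0.72, 0.20),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw APOE genotypes from (e2, e3, e4) haplotype frequencies.

    Two haplotypes per individual are drawn independently; rs429358/rs7412
    genotypes follow from the haplotype->allele map, and the emitted labels
    are consistent with re-classification from the genotypes.  The default
    frequencies give the elevated e4 rate of an AD-enriched research cohort
    (carrier fraction 1 - 0.8^2 = 0.36).
    """
    freqs = np.asarray(haplotype_freqs, dtype=float)
    if freqs.shape != (3,) or abs(freqs.sum() - 1.0) > 1e-8 or np.any(freqs < 0):
        raise ValueError("haplotype_freqs must be 3 non-negative values summing to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    hap_idx = rng.choice(3, size=(n, 2), p=freqs)
    rows = []
    for h1, h2 in hap_idx:
        a, b = _HAPLOTYPES[h1], _HAPLOTYPES[h2]
        pair = tuple(sorted((a, b)))
        g1 = "".join(sorted(_HAP_ALLELES[a][0] + _HAP_ALLELES[b][0]))
        g2 = "".join(sorted(_HAP_ALLELES[a][1] + _HAP_ALLELES[b][1]))
        rows.append({
            "rs429358": g1, "rs7412": g2,
            "epsilon_pair": "/".join(pair),
            "e4_carrier": "e4" in pair,
            "excluded": pair == ("e2", "e4"),
        })
    return pd.DataFrame(rows)


def simulate_prs_panel(
    n: int,
    n_snps: int = 15,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Independent risk-SNP set with per-allele log-odds weights.

    The polygenic-score SNPs are disjoint from the exposure instruments (as
    a disease GWAS hit list is from a telomere GWAS hit list) and carry
    their own half-normal weights.  Returns (dosages, weights).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.1, 0.9, n_snps)
    weights = np.abs(rng.normal(0.0, 0.15, n_snps))
    rsids = [f"rs9{900001 + 13 * k}" for k in range(n_snps)]
    g = rng.binomial(2, eaf, size=(n, n_snps)).astype(float)
    dosages = pd.DataFrame(g, columns=rsids)
    return dosages, pd.Series(weights, index=rsids, name="weight")


def simulate_summary_mrinput(
    panel: TruePanel,
    config: SimulationConfig,
    outcome_sd: float = 1.0,
    seed: int = 0,
    outcome: str = "synthetic",
    stratum: str = "whole",
) -> MRInput:
    """Analytic summary-statistic shortcut: one MR replicate without a cohort.

    Draws observed summary statistics directly from their sampling
    distributions: ``beta_x ~ N(b_j, se_x_j)`` with the external-GWAS SE and
    ``beta_y ~ N(theta*b_j + sd*a_j, se_y_j)`` with the in-sample regression
    SE ``se_y_j = outcome_sd/sqrt(2 p_j (1-p_j) n_cohort)``.  First-order
    identical to running the full pipeline on a fresh cohort, at a fraction
    of the cost — the workhorse for calibration and power replication.
    """
    rng = np.random.default_rng(seed)
    se_x = _analytic_se_x(panel.eaf, config.n_external)
    se_y = outcome_sd / np.sqrt(2.0 * panel.eaf * (1.0 - panel.eaf) * config.n_cohort)
    true_y = config.theta * panel.beta_x_true + outcome_sd * panel.alpha_pleio
    return MRInput(
        rsid=panel.rsid,
        beta_x=panel.beta_x_true + rng.normal(0.0, se_x),
        se_x=se_x,
        beta_y=true_y + rng.normal(0.0, se_y),
        se_y=se_y,
        outcome=outcome, stratum=stratum,
    )


@dataclass
class SyntheticStudy:
    """Everything the study driver needs, generated from one config."""

    config: SimulationConfig
    panel: TruePanel
    exposure_gwas: pd.DataFrame
    cohort: SyntheticCohort
    prs_dosages: pd.DataFrame
    prs_weights: pd.Series


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full study: panel, external GWAS, cohort, PRS SNP set."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_true_panel(config, rng=rng)
    gwas = simulate_external_gwas(panel, config.n_external,
                                  seed=config.seed + 101)
    cohort = simulate_cohort(panel, config, rng=np.random.default_rng(config.seed + 202))
    prs_dos, prs_w = simulate_prs_panel(config.n_cohort, config.n_prs_snps,
                                        rng=np.random.default_rng(config.seed + 303))
    prs_dos.index = cohort.dosages.index
    return SyntheticStudy(config=config, panel=panel, exposure_gwas=gwas,
                          cohort=cohort, prs_dosages=prs_dos, prs_weights=prs_w)


def export_study(study: SyntheticStudy, outdir) -> dict:
    """Write the study to TSV/JSON files; returns the path map.

    Includes a PLINK ``.raw``-compatible dosage export (FID/IID/PAT/MAT/SEX/
    PHENOTYPE header then ``<rsid>_<effectallele>`` columns).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = study.cohort
    paths = {}

    def _write(name, df, index_label="iid"):
        p = outdir / name
        df.to_csv(p, sep="\t", index=index_label is not None,
                  index_label=index_label)
        paths[name] = p

    _write("dosages.tsv", c.dosages)
    _write("covariates.tsv", c.covariates)
    _write("outcomes.tsv", c.outcomes)
    _write("apoe_genotypes.tsv", c.apoe_genotypes[["rs429358", "rs7412"]])
    _write("prs_dosages.tsv", study.prs_dosages)
    _write("exposure_gwas.tsv", study.exposure_gwas.set_index("rsid"), "rsid")
    _write("prs_weights.tsv", study.prs_weights.to_frame(), "rsid")

    raw = c.dosages.copy()
    raw.columns = [f"{rs}_{ea}" for rs, ea in
                   zip(study.panel.rsid, study.panel.effect_allele)]
    raw.insert(0, "FID", raw.index)
    raw.insert(1, "IID", raw.index)
    for i, col in enumerate(("PAT", "MAT", "SEX", "PHENOTYPE")):
        raw.insert(2 + i, col, 0 if col != "PHENOTYPE" else -9)
    p = outdir / "dosages.raw"
    raw.to_csv(p, sep=" ", index=False)
    paths["dosages.raw"] = p

    alleles = pd.DataFrame({
        "rsid": list(study.panel.rsid),
        "counted_allele": list(study.panel.effect_allele),
        "other_allele": list(study.panel.other_allele),
        "eaf": study.panel.eaf,
    })
    _write("cohort_alleles.tsv", alleles.set_index("rsid"), "rsid")

    with open(outdir / "truth.json", "w") as fh:
        json.dump(c.truth, fh, indent=2)
    paths["truth.json"] = outdir / "truth.json"
    return paths
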