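"""Simulation studies validating the pipeline against its own generator.

Each routine runs many replicates of the synthetic study under a stated
condition (null effect, planted pleiotropy, a true causal effect) and
measures an operating characteristic of the estimators: type-I error,
heterogeneity-statistic calibration, bias and CI coverage, outlier
detection power.  The calibration routines use the analytic
summary-statistic shortcut (:func:`endomr.synthetic_cohort.
simulate_summary_mrinput`); parameter recovery runs the full
individual-level pipeline — cohort simulation, per-SNP covariate-adjusted
regressions, then IVW.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .endophenotypes import snp_outcome_associations
from .mr_core import MRInput, ivw_estimate, egger_regression
from .mr_sensitivity import cochran_q, mr_presso
from .synthetic_cohort import (
    SimulationConfig, OutcomeFamilySpec, simulate_true_panel,
    simulate_external_gwas, simulate_cohort, simulate_summary_mrinput,
    _analytic_se_x,
)

__all__ = [
    "ivw_null_calibration",
    "egger_balanced_calibration",
    "theta_recovery",
    "presso_outlier_power",
    "directional_pleiotropy_comparison",
]


def _panel_seed(seed: int, rep: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt * 10_007 + rep) % (2 ** 31 - 1))


def ivw_null_calibration(
    n_rep: int = 1000,
    n_cohort: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    ivw_model: str = "random",
) -> dict:
    """Type-I error of IVW and Cochran-Q calibration under the null.

    theta = 0, no pleiotropy, no confounding; a fresh instrument panel each
    replicate.  Returns the IVW rejection rate at ``alpha`` and the mean of
    Q/(J-1), which should be ~1 for a well-calibrated chi-square.
    """
    cfg = SimulationConfig(n_cohort=n_cohort, theta=0.0, seed=seed)
    rejections = 0
    q_ratios = np.empty(n_rep)
    for rep in range(n_rep):
        panel = simulate_true_panel(
            cfg, rng=np.random.default_rng(_panel_seed(seed, rep, 1)))
        mri = simulate_summary_mrinput(panel, cfg, seed=_panel_seed(seed, rep, 2))
        est = ivw_estimate(mri, model=ivw_model)
        rejections += est.pval < alpha
        q, df, _ = cochran_q(mri)
        q_ratios[rep] = q / df
    return {"rejection_rate": rejections / n_rep,
            "q_mean_ratio": float(q_ratios.mean()),
            "n_rep": n_rep, "alpha": alpha}


def egger_balanced_calibration(
    n_rep: int = 1000,
    n_cohort: int = 2000,
    pleiotropy_scale: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Egger-intercept rejection rate under *balanced* pleiotropy.

    Balanced (zero-mean) direct effects inflate heterogeneity but not the
    average intercept, so the directional-pleiotropy test should reject at
    its nominal level.
    """
    cfg = SimulationConfig(n_cohort=n_cohort, theta=0.0, seed=seed,
                           pleiotropy_mode="balanced",
                           pleiotropy_scale=pleiotropy_scale)
    rejections = 0
    for rep in range(n_rep):
        panel = simulate_true_panel(
            cfg, rng=np.random.default_rng(_panel_seed(seed, rep, 3)))
        mri = simulate_summary_mrinput(panel, cfg, seed=_panel_seed(seed, rep, 4))
        _, intercept = egger_regression(mri)
        rejections += intercept.pval < alpha
    return {"rejection_rate": rejections / n_rep, "n_rep": n_rep, "alpha": alpha}


def theta_recovery(
    n_rep: int = 200,
    theta: float = 0.06,
    n_cohort: int = 1000,
    seed: int = 0,
    ivw_model: str = "random",
) -> dict:
    """End-to-end parameter recovery through the full pipeline.

    Each replicate simulates a panel, its external GWAS, an individual-level
    cohort with an imaging-scale outcome carrying the true effect ``theta``,
    runs the per-SNP covariate-adjusted regressions, and estimates theta by
    IVW.  Reports the mean bias, the SE of that mean (Monte-Carlo error),
    and the 95% CI coverage.
    """
    family = OutcomeFamilySpec("signature", "imaging", offset=2.5, sd=0.1)
    betas = np.empty(n_rep)
    covered = 0
    for rep in range(n_rep):
        cfg = SimulationConfig(n_cohort=n_cohort, theta=theta,
                               families=(family,),
                               seed=_panel_seed(seed, rep, 5))
        rng = np.random.default_rng(cfg.seed)
        panel = simulate_true_panel(cfg, rng=rng)
        gwas = simulate_external_gwas(panel, cfg.n_external,
                                      seed=_panel_seed(seed, rep, 6))
        cohort = simulate_cohort(panel, cfg, rng=rng)
        assoc = snp_outcome_associations(
            cohort.dosages, cohort.outcomes[family.name], cohort.covariates,
            outcome_name=family.name)
        ok = np.isfinite(assoc["beta_y"].to_numpy())
        mri = MRInput(rsid=tuple(assoc.loc[ok, "rsid"]),
                      beta_x=gwas.loc[ok, "beta"].to_numpy(),
                      se_x=gwas.loc[ok, "se"].to_numpy(),
                      beta_y=assoc.loc[ok, "beta_y"].to_numpy(),
                      se_y=assoc.loc[ok, "se_y"].to_numpy())
        est = ivw_estimate(mri, model=ivw_model)
        betas[rep] = est.beta
        covered += est.ci_low <= theta <= est.ci_high
    return {"theta": theta,
            "mean_bias": float(betas.mean() - theta),
            "mc_se": float(betas.std(ddof=1) / np.sqrt(n_rep)),
            "coverage": covered / n_rep,
            "n_rep": n_rep}


def presso_outlier_power(
    n_rep: int = 200,
    theta: float = 0.06,
    n_cohort: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
) -> dict:
    """Detection of one planted pleiotropic outlier by MR-PRESSO.

    One SNP per replicate carries a direct outcome effect of 10x its
    SNP-outcome standard error; all others are valid.  Reports the fraction
    of replicates in which that SNP is flagged and in which the
    outlier-corrected IVW is closer to the truth than the uncorrected one.
    """
    cfg = SimulationConfig(n_cohort=n_cohort, theta=theta, seed=seed)
    flagged = corrected_better = 0
    for rep in range(n_rep):
        rng = np.random.default_rng(_panel_seed(seed, rep, 7))
        panel = simulate_true_panel(cfg, rng=rng)
        k = int(rng.integers(panel.n_snps))
        se_y_k = 1.0 / np.sqrt(2 * panel.eaf[k] * (1 - panel.eaf[k]) * n_cohort)
        alpha = np.zeros(panel.n_snps)
        alpha[k] = 10.0 * se_y_k
        spiked = dataclasses.replace(panel, alpha_pleio=alpha)
        mri = simulate_summary_mrinput(spiked, cfg, seed=_panel_seed(seed, rep, 8))
        res = mr_presso(mri, n_sim=n_sim, seed=_panel_seed(seed, rep, 9))
        hit = spiked.rsid[k] in res.outliers
        flagged += hit
        if res.corrected is not None:
            raw = ivw_estimate(mri, "fixed")
            corrected_better += (abs(res.corrected.beta - theta)
                                 < abs(raw.beta - theta))
    return {"flag_rate": flagged / n_rep,
            "corrected_better_rate": corrected_better / n_rep,
            "n_rep": n_rep}


def directional_pleiotropy_comparison(
    n_rep: int = 200,
    theta: float = 0.06,
    n_cohort: int = 1000,
    pleiotropy_scale: float = 0.05,
    seed: int = 0,
) -> dict:
    """Egger slope vs IVW under directional pleiotropy with InSIDE.

    All instruments carry positive direct effects drawn independently of
    instrument strength, biasing IVW; the Egger slope should have the
    smaller median absolute error.
    """
    cfg = SimulationConfig(n_cohort=n_cohort, theta=theta, seed=seed,
                           pleiotropy_mode="directional",
                           pleiotropy_scale=pleiotropy_scale)
    ivw_err = np.empty(n_rep)
    egger_err = np.empty(n_rep)
    for rep in range(n_rep):
        panel = simulate_true_panel(
            cfg, rng=np.random.default_rng(_panel_seed(seed, rep, 10)))
        mri = simulate_summary_mrinput(panel, cfg, seed=_panel_seed(seed, rep, 11))
        ivw_err[rep] = abs(ivw_estimate(mri, "fixed").beta - theta)
        egger_err[rep] = abs(egger_regression(mri)[0].beta - theta)
    return {"ivw_median_abs_error": float(np.median(ivw_err)),
            "egger_median_abs_error": float(np.median(egger_err)),
            "n_rep": n_rep}
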