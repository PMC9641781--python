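"""Heterogeneity, pleiotropy, outlier and influence diagnostics for one MRInput.

The suite mirrors the standard sensitivity battery run alongside IVW:
Cochran's Q for heterogeneity of the per-SNP Wald ratios, the MR-Egger
intercept test for directional pleiotropy, MR-PRESSO (residual sum and
outlier) for global pleiotropy and per-SNP outliers with an outlier-removed
corrected estimate, and leave-one-SNP-out influence re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .mr_core import MRInput, MREstimate, ivw_estimate, egger_regression, ratio_estimates

__all__ = [
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "sensitivity_suite",
]


@dataclass
class PressoResult:
    """MR-PRESSO global test and outlier search for one MRInput."""

    observed_rss: float
    global_pval: float
    outlier_pvals: pd.Series          # Bonferroni-adjusted, indexed by rsid
    outliers: tuple
    corrected: Optional[MREstimate]   # IVW on non-outliers; None if no outliers
    distortion_pval: Optional[float]  # informational only
    n_sim: int
    seed: int


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso: Optional[PressoResult]
    leave_one_out: pd.DataFrame
    meta: dict = field(default_factory=dict)


def cochran_q(mr_input: MRInput, beta_ref: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic over the per-SNP Wald ratios.

    ``Q = sum_j w_j (ratio_j - beta_ref)^2`` with inverse-variance weights;
    ``beta_ref`` defaults to the fixed-effect IVW estimate (the definitional
    center, regardless of which IVW flavor the main analysis reports).
    Returns ``(Q, df, p)`` with df = J-1 and an upper-tail chi-square p.
    """
    r = ratio_estimates(mr_input)
    j = len(r.ratio)
    if j < 2:
        raise ValueError("Cochran's Q requires at least 2 usable instruments")
    if beta_ref is None:
        beta_ref = float(np.sum(r.weight * r.ratio) / np.sum(r.weight))
    q = float(np.sum(r.weight * (r.ratio - beta_ref) ** 2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(mr_input: MRInput) -> float:
    """Two-sided t-test (J-2 df) that the MR-Egger intercept is zero."""
    _, intercept = egger_regression(mr_input)
    return intercept.pval


def _loo_slopes(x, y, w):
    """Leave-one-out IVW slopes (weighted through-origin), vectorized."""
    sxy = np.sum(w * x * y)
    sxx = np.sum(w * x * x)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    mr_input: MRInput,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global pleiotropy test and outlier detection.

    The observed global statistic is the weighted residual sum of squares
    ``RSS = sum_j w_j (beta_y_j - b^(-j) * beta_x_j)^2`` where ``b^(-j)`` is
    the IVW slope with SNP j left out.  Its null distribution is obtained by
    ``n_sim`` parametric draws: beta_x* ~ N(beta_x, se_x) and
    beta_y* ~ N(b^(-j) * beta_x, se_y), recomputing RSS* each time.  The
    global p-value is the smoothed empirical exceedance
    ``(1 + #{RSS* >= RSS}) / (n_sim + 1)``.  Per-SNP outlier p-values are the
    exceedance of SNP j's observed residual contribution against its own
    simulated distribution, Bonferroni-adjusted across J; SNPs with adjusted
    p < ``outlier_alpha`` are flagged and an outlier-removed IVW estimate is
    reported.  The distortion test (difference between raw and corrected
    estimates against outlier-resampled nulls) is informational.
    """
    j = mr_input.n_snps
    if j < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments "
                         "(leave-one-out IVW needs >= 3 remaining)")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    x, y = mr_input.beta_x, mr_input.beta_y
    sx, sy = mr_input.se_x, mr_input.se_y
    w = sy ** -2.0

    b_loo = _loo_slopes(x, y, w)
    obs_contrib = w * (y - b_loo * x) ** 2
    obs_rss = float(np.sum(obs_contrib))

    xs = rng.normal(x, sx, size=(n_sim, j))
    ys = rng.normal(b_loo * x, sy, size=(n_sim, j))  # null: fitted means
    sxy = np.sum(w * xs * ys, axis=1, keepdims=True)
    sxx = np.sum(w * xs * xs, axis=1, keepdims=True)
    b_loo_sim = (sxy - w * xs * ys) / (sxx - w * xs * xs)
    sim_contrib = w * (ys - b_loo_sim * xs) ** 2
    sim_rss = sim_contrib.sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))
    exceed = (1 + np.sum(sim_contrib >= obs_contrib, axis=0)) / (n_sim + 1)
    adj = np.minimum(exceed * j, 1.0)
    outlier_pvals = pd.Series(adj, index=list(mr_input.rsid), name="presso_outlier_p")
    flagged = np.flatnonzero(adj < outlier_alpha)
    outliers = tuple(np.asarray(mr_input.rsid)[flagged])

    corrected = None
    distortion_p = None
    if len(flagged) and j - len(flagged) >= 2:
        corrected = ivw_estimate(mr_input.drop(flagged), model="fixed")
        raw = ivw_estimate(mr_input, model="fixed")
        # distortion test: observed shift vs shifts from random outlier sets
        obs_shift = raw.beta - corrected.beta
        k = len(flagged)
        shifts = np.empty(min(n_sim, 500))
        for i in range(len(shifts)):
            drop = rng.choice(j, size=k, replace=False)
            shifts[i] = raw.beta - ivw_estimate(mr_input.drop(drop), model="fixed").beta
        distortion_p = float(
            (1 + np.sum(np.abs(shifts) >= abs(obs_shift))) / (len(shifts) + 1)
        )
    return PressoResult(
        observed_rss=obs_rss, global_pval=global_p, outlier_pvals=outlier_pvals,
        outliers=outliers, corrected=corrected, distortion_pval=distortion_p,
        n_sim=n_sim, seed=seed,
    )


def leave_one_out(mr_input: MRInput, ivw_model: str = "random") -> pd.DataFrame:
    """Re-estimate IVW with each instrument removed in turn.

    Rows follow the input rsid order.  ``crosses_alpha`` flags rows whose
    p-value crosses 0.05 relative to the full-panel estimate — the classic
    sign that a single SNP drives (or masks) the result.
    """
    if mr_input.n_snps < 2:
        raise ValueError("leave-one-out requires at least 2 instruments")
    full = ivw_estimate(mr_input, model=ivw_model)
    rows = []
    for i, rsid in enumerate(mr_input.rsid):
        est = ivw_estimate(mr_input.drop([i]), model=ivw_model)
        rows.append({
            "rsid_removed": rsid, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
            "crosses_alpha": (est.pval < 0.05) != (full.pval < 0.05),
        })
    return pd.DataFrame(rows)


def sensitivity_suite(
    mr_input: MRInput,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    ivw_model: str = "random",
) -> SensitivityReport:
    """Run the full diagnostic battery on one MRInput."""
    q, df, q_p = cochran_q(mr_input)
    _, intercept = egger_regression(mr_input)
    presso = mr_presso(mr_input, n_sim=n_sim, seed=seed,
                       outlier_alpha=outlier_alpha) if mr_input.n_snps >= 4 else None
    loo = leave_one_out(mr_input, ivw_model=ivw_model)
    return SensitivityReport(
        q_stat=q, q_df=df, q_pval=q_p,
        egger_intercept=intercept.beta, egger_intercept_se=intercept.se,
        egger_intercept_pval=intercept.pval,
        presso=presso, leave_one_out=loo,
        meta={"n_sim": n_sim, "seed": seed, "outlier_alpha": outlier_alpha},
    )
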