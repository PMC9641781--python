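"""Two-sample Mendelian randomization estimators on harmonized summary data.

All estimators consume an :class:`MRInput` — aligned per-SNP vectors of
SNP–exposure effects (``beta_x``, in SD of the exposure per effect-allele
copy, from an external GWAS) and SNP–outcome effects (``beta_y``, in outcome
units per effect-allele copy, from in-sample covariate-adjusted linear
regressions) — and return an :class:`MREstimate` whose ``beta`` is the causal
effect of a 1-SD increase in the genetically predicted exposure, in outcome
units.

Implemented methods:

* inverse-variance weighted (IVW), fixed- and multiplicative random-effects;
* maximum likelihood under a bivariate-normal measurement model that
  accounts for uncertainty in the SNP–exposure effects;
* weighted median (50% breakdown point against invalid instruments);
* weighted mode (plurality-valid assumption, Gaussian-kernel density);
* MR-Egger regression (slope plus directional-pleiotropy intercept).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MRInput",
    "MREstimate",
    "RatioEstimates",
    "ratio_estimates",
    "ivw_estimate",
    "max_likelihood_estimate",
    "weighted_median_estimate",
    "weighted_mode_estimate",
    "egger_regression",
    "all_estimates",
]

_Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class MRInput:
    """Aligned summary statistics for one outcome in one stratum.

    Attributes
    ----------
    rsid : sequence of str
        Instrument identifiers, length J >= 1.
    beta_x, se_x : arrays
        Per-allele SNP–exposure effect and its standard error (SD units).
    beta_y, se_y : arrays
        Per-allele SNP–outcome effect and its standard error (outcome units).
    outcome, stratum : str
        Labels carried through to the results grid.
    """

    rsid: tuple
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    outcome: str = ""
    stratum: str = ""

    def __post_init__(self):
        object.__setattr__(self, "rsid", tuple(str(r) for r in self.rsid))
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1 or len(arr) != len(self.rsid):
                raise ValueError(f"{name} must be 1-d with one entry per rsid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
        if len(self.rsid) < 1:
            raise ValueError("MRInput needs at least one instrument")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.rsid)

    def drop(self, idx) -> "MRInput":
        """Return a copy without the instruments at positions ``idx``."""
        keep = np.ones(self.n_snps, dtype=bool)
        keep[np.asarray(idx)] = False
        return MRInput(
            rsid=tuple(np.asarray(self.rsid)[keep]),
            beta_x=self.beta_x[keep], se_x=self.se_x[keep],
            beta_y=self.beta_y[keep], se_y=self.se_y[keep],
            outcome=self.outcome, stratum=self.stratum,
        )


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal effect (outcome units per SD exposure)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    auxiliary: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if not (0.0 <= self.pval <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("auxiliary")
        return d


@dataclass(frozen=True)
class RatioEstimates:
    """Per-SNP Wald ratios with first-order delta-method SEs."""

    rsid: tuple
    ratio: np.ndarray     # beta_y / beta_x
    se: np.ndarray        # se_y / |beta_x|
    weight: np.ndarray    # se ** -2
    excluded: tuple       # rsids dropped because beta_x == 0


def ratio_estimates(mr_input: MRInput) -> RatioEstimates:
    """Per-SNP causal-effect (Wald) ratios beta_y/beta_x.

    SNPs with ``beta_x == 0`` have an undefined ratio and are excluded
    (recorded in ``excluded``); the first-order standard error
    ``se_y/|beta_x|`` ignores uncertainty in beta_x (NOME convention).
    """
    ok = mr_input.beta_x != 0.0
    excluded = tuple(np.asarray(mr_input.rsid)[~ok])
    bx, by, sy = mr_input.beta_x[ok], mr_input.beta_y[ok], mr_input.se_y[ok]
    ratio = by / bx
    se = sy / np.abs(bx)
    return RatioEstimates(
        rsid=tuple(np.asarray(mr_input.rsid)[ok]),
        ratio=ratio, se=se, weight=se ** -2.0, excluded=excluded,
    )


def _wald(beta: float, se: float) -> tuple[float, float, float]:
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else np.nan
    return beta - _Z95 * se, beta + _Z95 * se, float(p)


def ivw_estimate(mr_input: MRInput, model: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate.

    Equivalent to weighted least squares of beta_y on beta_x through the
    origin with weights ``se_y**-2``.  ``model='fixed'`` uses the analytic
    fixed-effect SE ``(sum w)**-0.5``; ``model='random'`` inflates it by the
    multiplicative overdispersion factor ``max(1, sqrt(Q/(J-1)))`` (floored
    at the fixed-effect SE, so fixed SE <= random SE always).
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    r = ratio_estimates(mr_input)
    j = len(r.ratio)
    if j == 0:
        raise ValueError("no usable instruments after exclusions")
    if model == "random" and j < 2:
        model = "fixed"
    w = r.weight
    beta = float(np.sum(w * r.ratio) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    phi = 1.0
    if model == "random":
        q = float(np.sum(w * (r.ratio - beta) ** 2))
        phi = max(1.0, np.sqrt(q / (j - 1)))
        se *= phi
    lo, hi, p = _wald(beta, se)
    return MREstimate(
        method=f"ivw_{model}", beta=beta, se=se, ci_low=lo, ci_high=hi,
        pval=p, n_snps=j,
        auxiliary={"overdispersion": phi, "excluded": r.excluded},
    )


def _ml_profile_loglik(theta: float, mr_input: MRInput) -> float:
    # Profiling out the per-SNP true exposure effects mu_j gives the
    # closed-form marginal: beta_y_j - theta*beta_x_j ~ N(0, se_y^2 + theta^2 se_x^2).
    v = mr_input.se_y ** 2 + theta ** 2 * mr_input.se_x ** 2
    resid = mr_input.beta_y - theta * mr_input.beta_x
    return float(-0.5 * np.sum(resid ** 2 / v))


def max_likelihood_estimate(mr_input: MRInput) -> MREstimate:
    """Maximum-likelihood causal effect under the measurement model.

    The likelihood treats the observed (beta_x_j, beta_y_j) as independent
    normals around per-SNP nuisance means (mu_j, theta*mu_j); the nuisance
    means are profiled out in closed form and the resulting 1-d profile
    likelihood is maximized numerically.  The SE comes from the observed
    information (negative second derivative of the profile log-likelihood
    at the optimum).  Unlike IVW this propagates the SNP–exposure SEs.
    """
    if mr_input.n_snps < 2:
        raise ValueError("maximum likelihood requires at least 2 instruments")
    anchor = ivw_estimate(mr_input, model="fixed").beta
    span = 10.0 * (abs(anchor) + ivw_estimate(mr_input, model="fixed").se) + 1.0
    res = optimize.minimize_scalar(
        lambda t: -_ml_profile_loglik(t, mr_input),
        bounds=(anchor - span, anchor + span), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"ML optimizer failed: {res.message}")
    theta = float(res.x)
    h = 1e-4 * (abs(theta) + 1.0)
    d2 = (
        _ml_profile_loglik(theta + h, mr_input)
        - 2.0 * _ml_profile_loglik(theta, mr_input)
        + _ml_profile_loglik(theta - h, mr_input)
    ) / h ** 2
    if d2 >= 0:
        raise RuntimeError("profile likelihood not concave at optimum")
    se = float((-d2) ** -0.5)
    lo, hi, p = _wald(theta, se)
    return MREstimate(
        method="max_likelihood", beta=theta, se=se, ci_low=lo, ci_high=hi,
        pval=p, n_snps=mr_input.n_snps,
        auxiliary={"loglik": _ml_profile_loglik(theta, mr_input)},
    )


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio)
    r, w = ratio[order], weight[order]
    wn = w / np.sum(w)
    s = np.cumsum(wn) - 0.5 * wn  # standardized cumulative weights
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5, side="right") - 1)
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def _parametric_bootstrap(mr_input, point_fn, n_boot, seed):
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(mr_input.beta_x, mr_input.se_x)
        by = rng.normal(mr_input.beta_y, mr_input.se_y)
        draws[b] = point_fn(bx, by, mr_input.se_y)
    return float(np.std(draws, ddof=1))


def weighted_median_estimate(
    mr_input: MRInput, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median causal estimate.

    Consistent when instruments carrying at least half the total inverse-
    variance weight are valid.  The estimate interpolates the ordered Wald
    ratios at standardized cumulative weight 0.5; the SE is a parametric
    bootstrap (resampling beta_x and beta_y from normals with the reported
    SEs, ``n_boot`` draws, fixed ``seed``).
    """
    if mr_input.n_snps < 3:
        raise ValueError("weighted median requires at least 3 instruments")

    def point(bx, by, sy):
        ok = bx != 0
        ratio = by[ok] / bx[ok]
        w = (sy[ok] / np.abs(bx[ok])) ** -2.0
        return _weighted_median(ratio, w)

    r = ratio_estimates(mr_input)
    beta = _weighted_median(r.ratio, r.weight)
    se = _parametric_bootstrap(mr_input, point, n_boot, seed)
    lo, hi, p = _wald(beta, se)
    return MREstimate(
        method="weighted_median", beta=beta, se=se, ci_low=lo, ci_high=hi,
        pval=p, n_snps=mr_input.n_snps,
        auxiliary={"n_boot": n_boot, "seed": seed},
    )


def _mode_bandwidth(ratio: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratio, ddof=1)) if len(ratio) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(ratio, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return phi * 0.9 * spread * len(ratio) ** (-1.0 / 5.0)


def _weighted_mode(ratio: np.ndarray, weight: np.ndarray, phi: float) -> float:
    h = _mode_bandwidth(ratio, phi)
    if h <= 0:  # all ratios (numerically) identical
        return float(ratio[0])
    wn = weight / np.sum(weight)

    def neg_density(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - ratio[None, :]) / h
        return -(np.exp(-0.5 * z ** 2) * wn[None, :]).sum(axis=1)

    grid = np.linspace(ratio.min() - 2 * h, ratio.max() + 2 * h, 2048)
    dens = -neg_density(grid)
    k = int(np.argmax(dens))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda x: float(neg_density(x)[0]), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def weighted_mode_estimate(
    mr_input: MRInput,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode causal estimate.

    Consistent when the largest group of instruments sharing one ratio value
    is valid (plurality assumption).  The estimate is the argmax of a
    weighted Gaussian kernel density over the Wald ratios with Silverman-type
    bandwidth ``phi * 0.9 * min(sd, iqr/1.34) * J**(-1/5)``; SE by parametric
    bootstrap as in :func:`weighted_median_estimate`.
    """
    if mr_input.n_snps < 3:
        raise ValueError("weighted mode requires at least 3 instruments")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")

    def point(bx, by, sy):
        ok = bx != 0
        ratio = by[ok] / bx[ok]
        w = (sy[ok] / np.abs(bx[ok])) ** -2.0
        return _weighted_mode(ratio, w, bandwidth_factor)

    r = ratio_estimates(mr_input)
    beta = _weighted_mode(r.ratio, r.weight, bandwidth_factor)
    se = _parametric_bootstrap(mr_input, point, n_boot, seed)
    lo, hi, p = _wald(beta, se)
    return MREstimate(
        method="weighted_mode", beta=beta, se=se, ci_low=lo, ci_high=hi,
        pval=p, n_snps=mr_input.n_snps,
        auxiliary={"n_boot": n_boot, "seed": seed,
                   "bandwidth": _mode_bandwidth(r.ratio, bandwidth_factor)},
    )


def egger_regression(
    mr_input: MRInput, through_origin: bool = False
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger weighted regression of beta_y on beta_x with intercept.

    Inputs are first oriented so every beta_x >= 0 (flipping the sign of the
    (beta_x, beta_y) pair where needed; the fit is invariant to the original
    allele orientation only after this step).  The slope estimates the causal
    effect under InSIDE; the intercept estimates average directional
    pleiotropy.  SEs carry a multiplicative overdispersion factor
    ``max(1, sqrt(Q_egger/(J-2)))`` and p-values use a t distribution on
    J-2 degrees of freedom.

    Returns ``(slope, intercept)`` as two :class:`MREstimate` objects.
    ``through_origin=True`` drops the intercept (diagnostic mode; the slope
    then equals fixed-effect IVW and the returned intercept is exactly 0).
    """
    j = mr_input.n_snps
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.where(mr_input.beta_x < 0, -1.0, 1.0)
    x = mr_input.beta_x * flip
    y = mr_input.beta_y * flip
    w = mr_input.se_y ** -2.0
    if np.ptp(x) == 0:
        raise ValueError("all beta_x identical: no leverage for the intercept")
    if through_origin:
        slope_hat = float(np.sum(w * x * y) / np.sum(w * x * x))
        se_slope = float(np.sum(w * x * x) ** -0.5)
        lo, hi, p = _wald(slope_hat, se_slope)
        slope = MREstimate("egger_origin", slope_hat, se_slope, lo, hi, p, j)
        intercept = MREstimate("egger_intercept", 0.0, np.inf, -np.inf, np.inf, 1.0, j)
        return slope, intercept
    # two-column WLS: design (1, x)
    sw, swx = np.sum(w), np.sum(w * x)
    swxx, swy, swxy = np.sum(w * x * x), np.sum(w * y), np.sum(w * x * y)
    det = sw * swxx - swx ** 2
    a = (swxx * swy - swx * swxy) / det      # intercept
    b = (sw * swxy - swx * swy) / det        # slope
    resid = y - a - b * x
    q = float(np.sum(w * resid ** 2))
    phi = max(1.0, np.sqrt(q / (j - 2))) if j > 2 else 1.0
    se_a = phi * np.sqrt(swxx / det)
    se_b = phi * np.sqrt(sw / det)
    tdist = stats.t(df=j - 2)
    tq = float(tdist.ppf(0.975))

    def t_est(method, est, se):
        p = float(2.0 * tdist.sf(abs(est) / se))
        return MREstimate(method, float(est), float(se),
                          float(est - tq * se), float(est + tq * se), p, j,
                          auxiliary={"q_egger": q, "overdispersion": phi})

    return t_est("egger_slope", b, se_b), t_est("egger_intercept", a, se_a)


def all_estimates(
    mr_input: MRInput,
    methods: Sequence[str] = ("ivw", "max_likelihood", "weighted_median",
                              "weighted_mode", "egger"),
    ivw_model: str = "random",
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MREstimate]:
    """Run the requested estimators on one input; bundles the study's five."""
    out: list[MREstimate] = []
    for m in methods:
        if m == "ivw":
            out.append(ivw_estimate(mr_input, model=ivw_model))
        elif m == "max_likelihood":
            out.append(max_likelihood_estimate(mr_input))
        elif m == "weighted_median":
            out.append(weighted_median_estimate(mr_input, n_boot=n_boot, seed=seed))
        elif m == "weighted_mode":
            out.append(weighted_mode_estimate(mr_input, n_boot=n_boot, seed=seed))
        elif m == "egger":
            slope, intercept = egger_regression(mr_input)
            out.append(slope)
            out.append(intercept)
        else:
            raise ValueError(f"unknown method {m!r}")
    return out
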