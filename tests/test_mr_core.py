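"""Estimator unit tests against independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endomr.mr_core import (
    MRInput, ratio_estimates, ivw_estimate, max_likelihood_estimate,
    weighted_median_estimate, weighted_mode_estimate, egger_regression,
)
from conftest import random_mrinput


def wls_origin_oracle(x, y, w):
    """Weighted LS through the origin via explicit normal equations."""
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq((sw * x)[:, None], sw * y, rcond=None)
    return float(beta[0])


def make_input(beta_x, beta_y, se_y, se_x=None):
    beta_x = np.asarray(beta_x, float)
    if se_x is None:
        se_x = np.full_like(beta_x, 1e-3)
    return MRInput(rsid=tuple(f"s{i}" for i in range(len(beta_x))),
                   beta_x=beta_x, se_x=se_x, beta_y=beta_y, se_y=se_y)


class TestRatio:
    def test_hand_arithmetic(self):
        mri = make_input([0.1], [0.2], [0.05])
        r = ratio_estimates(mri)
        assert r.ratio[0] == pytest.approx(2.0)
        assert r.se[0] == pytest.approx(0.5)
        assert r.weight[0] == pytest.approx(4.0)

    def test_null_snp_and_sign_flip(self):
        r = ratio_estimates(make_input([0.1, -0.1], [0.0, 0.2], [0.05, 0.05]))
        assert r.ratio[0] == 0.0
        assert r.ratio[1] == pytest.approx(-2.0)
        assert r.se[1] == pytest.approx(0.5)  # |beta_x| in the denominator

    def test_zero_beta_x_excluded(self):
        r = ratio_estimates(make_input([0.1, 0.0], [0.2, 0.3], [0.05, 0.05]))
        assert r.excluded == ("s1",)
        assert len(r.ratio) == 1


class TestIVW:
    def test_single_snp_degenerate(self):
        est = ivw_estimate(make_input([0.1], [0.2], [0.05]), model="fixed")
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_homogeneous_panel(self):
        # J SNPs with identical ratio r and weight w: beta=r, SE=(J w)^-1/2
        j, r_val = 5, 1.5
        bx = np.full(j, 0.1)
        est = ivw_estimate(make_input(bx, r_val * bx, np.full(j, 0.05)),
                           model="fixed")
        w = (0.05 / 0.1) ** -2
        assert est.beta == pytest.approx(r_val)
        assert est.se == pytest.approx((j * w) ** -0.5)

    def test_matches_wls_origin_oracle(self, rng):
        for _ in range(20):
            mri = random_mrinput(rng, j=10, het=0.05)
            est = ivw_estimate(mri, model="fixed")
            oracle = wls_origin_oracle(mri.beta_x, mri.beta_y, mri.se_y ** -2)
            assert est.beta == pytest.approx(oracle, abs=1e-10)

    def test_fixed_se_never_exceeds_random(self, rng):
        for _ in range(20):
            mri = random_mrinput(rng, het=0.1)
            assert (ivw_estimate(mri, "fixed").se
                    <= ivw_estimate(mri, "random").se + 1e-15)

    def test_random_se_equals_classical_wls_when_overdispersed(self, rng):
        mri = random_mrinput(rng, het=0.5)
        est = ivw_estimate(mri, model="random")
        w = mri.se_y ** -2
        resid = mri.beta_y - est.beta * mri.beta_x
        sigma2 = np.sum(w * resid ** 2) / (mri.n_snps - 1)
        classical = np.sqrt(sigma2 / np.sum(w * mri.beta_x ** 2))
        if est.auxiliary["overdispersion"] > 1:
            assert est.se == pytest.approx(classical, rel=1e-10)


class TestMaximumLikelihood:
    def test_ivw_limit_when_exposure_exact(self, rng):
        # se_x -> 0 removes the measurement-error correction
        mri = random_mrinput(rng, het=0.02)
        tight = MRInput(rsid=mri.rsid, beta_x=mri.beta_x,
                        se_x=np.full(mri.n_snps, 1e-8),
                        beta_y=mri.beta_y, se_y=mri.se_y)
        ml = max_likelihood_estimate(tight)
        ivw = ivw_estimate(tight, model="fixed")
        assert ml.beta == pytest.approx(ivw.beta, abs=1e-6)

    def test_matches_profile_grid_oracle(self, rng):
        for _ in range(5):
            mri = random_mrinput(rng, j=5, het=0.05)
            ml = max_likelihood_estimate(mri)

            grid = np.linspace(ml.beta - 0.5, ml.beta + 0.5, 400_001)[:, None]
            v = mri.se_y[None, :] ** 2 + grid ** 2 * mri.se_x[None, :] ** 2
            loglik = -0.5 * np.sum((mri.beta_y[None, :] - grid * mri.beta_x[None, :]) ** 2 / v,
                                   axis=1)
            oracle = float(grid[np.argmax(loglik), 0])
            assert ml.beta == pytest.approx(oracle, abs=1e-5)

    def test_permutation_invariant(self, rng):
        mri = random_mrinput(rng, j=8, het=0.05)
        perm = np.array([3, 1, 7, 0, 2, 6, 4, 5])
        shuffled = MRInput(rsid=tuple(np.array(mri.rsid)[perm]),
                           beta_x=mri.beta_x[perm], se_x=mri.se_x[perm],
                           beta_y=mri.beta_y[perm], se_y=mri.se_y[perm])
        assert (max_likelihood_estimate(mri).beta
                == pytest.approx(max_likelihood_estimate(shuffled).beta, abs=1e-6))


def weighted_median_walk_oracle(ratio, weight):
    """Cumulative-weight walk: step through sorted ratios until half the
    weight is passed, then linearly interpolate."""
    order = np.argsort(ratio)
    r, w = np.asarray(ratio)[order], np.asarray(weight)[order]
    wn = w / w.sum()
    below = 0.0
    for i in range(len(r)):
        center = below + wn[i] / 2.0
        if center >= 0.5:
            if i == 0:
                return float(r[0])
            prev_center = below - wn[i - 1] / 2.0
            frac = (0.5 - prev_center) / (center - prev_center)
            return float(r[i - 1] + frac * (r[i] - r[i - 1]))
        below += wn[i]
    return float(r[-1])


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        bx = np.array([0.1, 0.1, 0.1])
        mri = make_input(bx, np.array([1, 2, 3]) * 0.1, np.full(3, 0.05))
        est = weighted_median_estimate(mri, n_boot=100, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_dominant_snp(self):
        # one SNP with >50% of the weight pins the estimate near its ratio
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.5, 0.01, 0.011, 0.012])
        se_y = np.array([0.001, 0.1, 0.1, 0.1])  # first SNP dominates
        mri = make_input(bx, by, se_y)
        est = weighted_median_estimate(mri, n_boot=100, seed=1)
        oracle = weighted_median_walk_oracle(by / bx, (se_y / bx) ** -2)
        assert est.beta == pytest.approx(oracle, abs=1e-12)
        assert abs(est.beta - 5.0) < 0.05

    def test_matches_walk_oracle_random(self, rng):
        for _ in range(50):
            mri = random_mrinput(rng, j=int(rng.integers(3, 15)), het=0.1)
            r = mri.beta_y / mri.beta_x
            w = (mri.se_y / np.abs(mri.beta_x)) ** -2
            est = weighted_median_estimate(mri, n_boot=100, seed=0)
            assert est.beta == pytest.approx(
                weighted_median_walk_oracle(r, w), abs=1e-12)

    def test_breakdown_resists_outlier(self, rng):
        theta = 0.5
        bx = np.full(10, 0.1)
        by = theta * bx
        by[-1] = 5.0 * bx[-1]  # wild outlier
        se_y = np.full(10, 0.01)
        se_y[-1] = 0.1        # small weight
        mri = make_input(bx, by, se_y)
        wm = weighted_median_estimate(mri, n_boot=100, seed=0)
        ivw = ivw_estimate(mri, "fixed")
        assert abs(wm.beta - theta) < 0.01
        assert abs(ivw.beta - theta) > abs(wm.beta - theta)


class TestWeightedMode:
    def test_point_mass(self):
        bx = np.full(4, 0.1)
        mri = make_input(bx, 0.7 * bx, np.full(4, 0.05))
        est = weighted_mode_estimate(mri, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.7)

    def test_majority_cluster_wins(self):
        bx = np.full(10, 0.1)
        ratios = np.array([0.5] * 7 + [3.0] * 3)
        se_y = np.array([0.01] * 7 + [0.05] * 3)  # low weight on the cluster at 3
        mri = make_input(bx, ratios * bx, se_y)
        est = weighted_mode_estimate(mri, n_boot=50, seed=0)
        assert abs(est.beta - 0.5) < 0.05
        assert abs(est.beta - np.mean(ratios)) > 0.4

    def test_matches_dense_grid_kde_argmax(self, rng):
        for _ in range(10):
            mri = random_mrinput(rng, j=12, het=0.15)
            est = weighted_mode_estimate(mri, n_boot=50, seed=0)
            r = mri.beta_y / mri.beta_x
            w = (mri.se_y / np.abs(mri.beta_x)) ** -2
            w = w / w.sum()
            sd = np.std(r, ddof=1)
            iqr = np.subtract(*np.percentile(r, [75, 25]))
            h = 0.9 * min(sd, iqr / 1.34) * len(r) ** -0.2
            grid = np.linspace(r.min() - 2 * h, r.max() + 2 * h, 200_001)
            dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
            oracle = grid[np.argmax(dens)]
            assert est.beta == pytest.approx(oracle, abs=2 * (grid[1] - grid[0]))


class TestEgger:
    def test_exact_line_recovered(self):
        a, b = 0.02, 0.8
        bx = np.array([0.05, 0.1, 0.2])
        by = a + b * bx
        mri = make_input(bx, by, np.full(3, 0.01))
        slope, intercept = egger_regression(mri)
        assert slope.beta == pytest.approx(b, abs=1e-10)
        assert intercept.beta == pytest.approx(a, abs=1e-10)

    def test_through_origin_equals_ivw(self, rng):
        mri = random_mrinput(rng, het=0.05)
        slope, intercept = egger_regression(mri, through_origin=True)
        assert slope.beta == pytest.approx(ivw_estimate(mri, "fixed").beta, abs=1e-12)
        assert intercept.beta == 0.0

    def test_matches_wls_matrix_oracle(self, rng):
        for _ in range(20):
            mri = random_mrinput(rng, j=10, het=0.1)
            slope, intercept = egger_regression(mri)
            x = np.abs(mri.beta_x)
            y = mri.beta_y * np.sign(mri.beta_x)
            w = mri.se_y ** -2
            X = np.column_stack([np.ones_like(x), x])
            WX = X * w[:, None]
            cov_u = np.linalg.inv(X.T @ WX)
            coef = cov_u @ (WX.T @ y)
            resid = y - X @ coef
            phi2 = max(1.0, np.sum(w * resid ** 2) / (len(x) - 2))
            se = np.sqrt(np.diag(cov_u) * phi2)
            assert intercept.beta == pytest.approx(coef[0], abs=1e-10)
            assert slope.beta == pytest.approx(coef[1], abs=1e-10)
            assert intercept.se == pytest.approx(se[0], rel=1e-10)
            assert slope.se == pytest.approx(se[1], rel=1e-10)

    def test_no_leverage_error(self):
        bx = np.full(3, 0.1)
        with pytest.raises(ValueError, match="leverage"):
            egger_regression(make_input(bx, bx, np.full(3, 0.01)))


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(0.1, 10.0), data=st.data())
def test_estimators_equivariant_under_outcome_rescaling(scale, data):
    """Rescaling all (beta_y, se_y) by c rescales every estimate and SE by c."""
    seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(seed)
    mri = random_mrinput(rng, j=8, het=0.05)
    scaled = MRInput(rsid=mri.rsid, beta_x=mri.beta_x, se_x=mri.se_x,
                     beta_y=scale * mri.beta_y, se_y=scale * mri.se_y)
    for fn in (lambda m: ivw_estimate(m, "random"),
               max_likelihood_estimate,
               lambda m: egger_regression(m)[0]):
        a, b = fn(mri), fn(scaled)
        assert b.beta == pytest.approx(scale * a.beta, rel=1e-6, abs=1e-9)
        assert b.se == pytest.approx(scale * a.se, rel=1e-6, abs=1e-9)
    # bootstrap-based estimators: point estimate only (bootstrap is seeded
    # identically, so SEs also scale exactly)
    wm_a = weighted_median_estimate(mri, n_boot=50, seed=3)
    wm_b = weighted_median_estimate(scaled, n_boot=50, seed=3)
    assert wm_b.beta == pytest.approx(scale * wm_a.beta, rel=1e-9)
    assert wm_b.se == pytest.approx(scale * wm_a.se, rel=1e-9)


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_estimators_flip_sign_with_exposure_orientation(seed):
    """Flipping the sign of every beta_x flips the sign of the estimate."""
    rng = np.random.default_rng(seed)
    mri = random_mrinput(rng, j=8, het=0.05)
    flipped = MRInput(rsid=mri.rsid, beta_x=-mri.beta_x, se_x=mri.se_x,
                      beta_y=mri.beta_y, se_y=mri.se_y)
    assert ivw_estimate(flipped, "fixed").beta == pytest.approx(
        -ivw_estimate(mri, "fixed").beta, rel=1e-12)
    assert max_likelihood_estimate(flipped).beta == pytest.approx(
        -max_likelihood_estimate(mri).beta, abs=1e-6)
    assert egger_regression(flipped)[0].beta == pytest.approx(
        -egger_regression(mri)[0].beta, rel=1e-10)


def test_valid_instrument_agreement_across_estimators(rng):
    """On valid-instrument data all five estimators agree within 2x the
    largest SE in at least 95% of replicates."""
    agree = 0
    n_rep = 60
    for rep in range(n_rep):
        r = np.random.default_rng(1000 + rep)
        mri = random_mrinput(r, j=20, theta=0.1, het=0.0)
        ests = [ivw_estimate(mri, "random"), max_likelihood_estimate(mri),
                weighted_median_estimate(mri, n_boot=60, seed=rep),
                weighted_mode_estimate(mri, n_boot=60, seed=rep),
                egger_regression(mri)[0]]
        betas = np.array([e.beta for e in ests])
        tol = 2.0 * max(e.se for e in ests)
        agree += np.ptp(betas) <= tol
    assert agree / n_rep >= 0.95
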