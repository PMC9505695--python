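import numpy as np
import pytest
from scipy import stats

from tsmr.errors import EstimationError
from tsmr.estimators import (cochran_q, egger, ivw, wald_ratio,
                             weighted_median, weighted_mode,
                             _weighted_median_point)

from conftest import make_hset


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.1, 0.002, 0.02, 0.01)
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        assert wald_ratio(0.1, 0.002, 0.0, 0.01).theta == 0.0

    def test_zero_exposure_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.002, 0.02, 0.01)

    def test_first_order_se_close_to_second_order_for_strong_instrument(self):
        # second-order delta method adds Gamma^2 sx^2 / gamma^4
        g, sx, G, sy = 0.1, 0.004, 0.02, 0.01  # sx/g = 0.04 < 0.05
        est = wald_ratio(g, sx, G, sy)
        se2 = np.sqrt(sy ** 2 / g ** 2 + G ** 2 * sx ** 2 / g ** 4)
        assert est.se == pytest.approx(se2, rel=0.01)


class TestIvw:
    def test_single_snp_reduces_to_wald(self):
        h = make_hset([0.1], [0.02])
        est = ivw(h)
        wald = wald_ratio(0.1, 0.002, 0.02, 0.006)
        assert est.theta == pytest.approx(wald.theta)
        assert est.se == pytest.approx(wald.se)

    def test_replicated_snp_shrinks_se_by_sqrt_j(self):
        one = ivw(make_hset([0.1], [0.02]), mode="fixed")
        five = ivw(make_hset([0.1] * 5, [0.02] * 5), mode="fixed")
        assert five.theta == pytest.approx(one.theta)
        assert five.se == pytest.approx(one.se / np.sqrt(5))

    def test_matches_normal_equation_oracle(self, random_hset):
        est = ivw(random_hset, mode="fixed")
        # independent weighted normal equations via explicit linear algebra
        g = random_hset.beta_exposure
        G = random_hset.beta_outcome
        W = np.diag(1.0 / random_hset.se_outcome ** 2)
        X = g[:, None]
        theta = np.linalg.solve(X.T @ W @ X, X.T @ W @ G)[0]
        se = np.sqrt(np.linalg.inv(X.T @ W @ X)[0, 0])
        assert est.theta == pytest.approx(theta, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-12)

    def test_mre_same_theta_se_scales_with_phi(self, random_hset):
        fe = ivw(random_hset, mode="fixed")
        mre = ivw(random_hset, mode="mre")
        assert mre.theta == pytest.approx(fe.theta)
        phi = mre.extras["phi"]
        assert mre.se == pytest.approx(fe.se * np.sqrt(phi))
        assert (mre.se >= fe.se) == (phi >= 1)


class TestEgger:
    def test_exact_interpolation_of_noise_free_pleiotropy(self):
        g = np.array([0.02, 0.05, 0.08, 0.11])
        a, theta = 0.003, -0.09
        h = make_hset(g, a + theta * g)
        est = egger(h)
        assert est.theta == pytest.approx(theta, abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(a, abs=1e-12)

    def test_orientation_invariance(self):
        # flipping the reported effect allele of some SNPs must not change Egger
        g = np.array([0.02, -0.05, 0.08, -0.11, 0.04])
        G = 0.001 + (-0.09) * g + np.array([1, -1, 1, -1, 1]) * 0.001
        h1 = make_hset(g, G)
        flip = np.array([1, -1, -1, 1, -1.0])
        h2 = make_hset(g * flip, G * flip)
        e1, e2 = egger(h1), egger(h2)
        assert e1.theta == pytest.approx(e2.theta, abs=1e-12)
        assert e1.extras["egger_intercept"] == pytest.approx(
            e2.extras["egger_intercept"], abs=1e-12)

    def test_requires_three_snps(self):
        with pytest.raises(EstimationError):
            egger(make_hset([0.1, 0.2], [0.01, 0.02]))


class TestWeightedMedian:
    def test_equal_weights_interpolates_to_middle_ratio(self):
        h = make_hset([0.1, 0.1, 0.1], [0.1, 0.2, 1.0])  # ratios 1, 2, 10
        est = weighted_median(h, bootstrap_reps=50, seed=1)
        assert est.theta == pytest.approx(2.0)

    def test_dominant_weight_snp_wins(self):
        h = make_hset([0.1, 0.1, 0.1], [0.05, 0.2, 0.9],
                      se_outcome=[1e-5, 10.0, 10.0])
        est = weighted_median(h, bootstrap_reps=50, seed=1)
        assert est.theta == pytest.approx(0.5, abs=0.01)

    def test_equals_plain_median_for_equal_weights_odd_j(self):
        ratios = np.array([0.3, 0.9, 0.1, 0.7, 0.5])
        theta = _weighted_median_point(ratios, np.ones(5))
        assert theta == pytest.approx(np.median(ratios))

    def test_seed_reproducibility(self):
        h = make_hset([0.05, 0.08, 0.12], [0.01, 0.015, 0.02])
        a = weighted_median(h, bootstrap_reps=100, seed=9)
        b = weighted_median(h, bootstrap_reps=100, seed=9)
        assert a.se == b.se


class TestWeightedMode:
    def test_point_mass_returns_common_ratio(self):
        h = make_hset([0.1, 0.2, 0.4], [0.05, 0.1, 0.2])  # all ratios 0.5
        est = weighted_mode(h, bootstrap_reps=20, seed=2)
        assert est.theta == pytest.approx(0.5)

    def test_translation_equivariance(self):
        g = np.array([0.1, 0.1, 0.1, 0.1])
        G = np.array([0.02, 0.025, 0.03, 0.08])
        est1 = weighted_mode(make_hset(g, G), bootstrap_reps=10, seed=3)
        est2 = weighted_mode(make_hset(g, G + 0.5 * g), bootstrap_reps=10, seed=3)
        assert est2.theta - est1.theta == pytest.approx(0.5, abs=1e-6)

    def test_plurality_cluster_found(self, rng):
        # 7 tight ratios at 0.5, 3 dispersed; all comparable weights
        g = np.full(10, 0.1)
        ratios = np.concatenate([0.5 + rng.normal(0, 0.005, 7),
                                 np.array([3.0, -2.0, 7.0])])
        est = weighted_mode(make_hset(g, ratios * g), bootstrap_reps=10, seed=4)
        h = est.extras["bandwidth"]
        assert abs(est.theta - 0.5) < max(h, 0.05)


class TestCochranQ:
    def test_noise_free_zero(self):
        g = np.array([0.05, 0.1, 0.2])
        h = make_hset(g, 0.3 * g)
        q, p = cochran_q(h, 0.3)
        assert q == pytest.approx(0.0, abs=1e-20)

    def test_quarter_scaling_when_se_doubles(self):
        g = np.array([0.05, 0.1, 0.2])
        G = np.array([0.02, 0.02, 0.07])
        q1, _ = cochran_q(make_hset(g, G, se_outcome=[0.01] * 3), 0.3)
        q2, _ = cochran_q(make_hset(g, G, se_outcome=[0.02] * 3), 0.3)
        assert q2 == pytest.approx(q1 / 4)

    def test_null_distribution_is_chisquare(self):
        # residual Q about the fitted slope should follow chi2(J-1) under
        # the null; check the Kolmogorov distance over many replicates
        rng = np.random.default_rng(31)
        J, reps, theta = 8, 2000, 0.1
        g = rng.uniform(0.05, 0.2, size=(reps, J))
        sy = np.full(J, 0.01)
        G = theta * g + rng.normal(0, 0.01, size=(reps, J))
        w = 1.0 / sy ** 2
        th = (w * g * G).sum(axis=1) / (w * g * g).sum(axis=1)
        q = (w * (G - th[:, None] * g) ** 2).sum(axis=1)
        ks = stats.ks_1samp(q, stats.chi2(J - 1).cdf)
        assert ks.statistic < 0.05


@pytest.mark.parametrize("method,kwargs", [
    (ivw, {}),
    (egger, {}),
    (weighted_median, {"bootstrap_reps": 20, "seed": 5}),
    (weighted_mode, {"bootstrap_reps": 20, "seed": 5}),
])
def test_estimators_equivariant_under_negation_and_scaling(method, kwargs, rng):
    g = rng.uniform(0.03, 0.1, 8)
    sy = rng.uniform(0.004, 0.01, 8)
    G = -0.09 * g + rng.normal(0, sy)
    base = method(make_hset(g, G, se_outcome=sy), **kwargs)
    negated = method(make_hset(g, -G, se_outcome=sy), **kwargs)
    # the mode's grid argmax is equivariant only to grid resolution (h/10)
    tol = base.extras["bandwidth"] / 5 if method is weighted_mode else 1e-9
    assert negated.theta == pytest.approx(-base.theta, abs=tol)
    c = 2.5
    scaled = method(make_hset(c * g, G, se_exposure=np.full(8, 0.005), se_outcome=sy), **kwargs)
    assert scaled.theta == pytest.approx(base.theta / c, rel=1e-6, abs=tol / c)
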