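import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import (
    egger_oracle,
    gls_egger_whitening_oracle,
    gls_ivw_oracle,
    ivw_oracle,
    weighted_median_oracle,
)
from conftest import random_harmonized
from mrkit.estimators import (
    egger,
    egger_correlated,
    ivw,
    ivw_correlated,
    ratio_estimates,
    to_odds_ratio,
    weighted_median,
)
from mrkit.simulate import make_ld_block_matrix
from mrkit.types import HarmonizedSet, LDMatrix


def hset(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    j = len(bx)
    return HarmonizedSet(
        rsids=[f"rs{i}" for i in range(j)],
        beta_x=bx,
        se_x=np.full(j, 0.02) if sx is None else np.asarray(sx, float),
        beta_y=np.asarray(by, float),
        se_y=np.asarray(sy, float),
        eaf_x=np.full(j, 0.3),
        eaf_y=np.full(j, 0.3),
    )


class TestRatioEstimates:
    def test_unit_ratios(self):
        h = hset([0.2, 0.3], [0.2, 0.3], [0.01, 0.01])
        theta, se = ratio_estimates(h)
        np.testing.assert_array_equal(theta, [1.0, 1.0])

    def test_zero_outcome_effect(self):
        h = hset([0.2], [0.0], [0.01])
        theta, se = ratio_estimates(h)
        assert theta[0] == 0.0 and se[0] == pytest.approx(0.05)

    def test_joint_negation_invariance(self):
        h1 = hset([0.2, -0.3], [0.1, 0.2], [0.01, 0.02])
        h2 = hset([-0.2, 0.3], [-0.1, -0.2], [0.01, 0.02])
        np.testing.assert_array_equal(ratio_estimates(h1)[0], ratio_estimates(h2)[0])

    def test_zero_exposure_effect_is_domain_error(self):
        with pytest.raises(ValueError, match="zero exposure"):
            ratio_estimates(hset([0.0, 0.2], [0.1, 0.1], [0.01, 0.01]))


class TestIVW:
    def test_single_variant_is_wald_ratio(self):
        h = hset([0.25], [0.05], [0.015])
        e = ivw(h)
        assert e.log_or == pytest.approx(0.2)
        assert e.se == pytest.approx(0.015 / 0.25)

    def test_equal_weights_average(self):
        h = hset([0.2, 0.2], [0.04, 0.08], [0.01, 0.01])  # ratios 0.2, 0.4
        assert ivw(h, variance_model="fixed").log_or == pytest.approx(0.3)

    def test_no_instruments_errors(self):
        with pytest.raises(ValueError, match="no instruments"):
            ivw(hset([], [], []))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_normal_equations_oracle(self, seed):
        h = random_harmonized(np.random.default_rng(seed), j=10)
        e = ivw(h, variance_model="fixed")
        theta, se = ivw_oracle(h.beta_x, h.beta_y, h.se_y)
        assert e.log_or == pytest.approx(theta, abs=1e-10)
        assert e.se == pytest.approx(se, abs=1e-10)

    def test_random_effects_never_below_fixed(self, rng):
        h = random_harmonized(rng, j=8)
        assert ivw(h, variance_model="multiplicative_random").se >= ivw(h, variance_model="fixed").se


class TestIVWCorrelated:
    def test_identity_ld_reduces_to_canonical(self, rng):
        h = random_harmonized(rng, j=7)
        ld = LDMatrix.identity(h.rsids)
        a = ivw_correlated(h, ld, variance_model="fixed")
        b = ivw(h, variance_model="fixed")
        assert a.log_or == pytest.approx(b.log_or, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_single_variant_is_wald_ratio(self):
        h = hset([0.25], [0.05], [0.015])
        e = ivw_correlated(h, LDMatrix.identity(h.rsids))
        assert e.log_or == pytest.approx(0.2)

    def test_compound_symmetry_matches_elimination_oracle(self):
        h = hset([0.2, 0.3, 0.4], [0.05, 0.04, 0.09], [0.01, 0.02, 0.015])
        ld = make_ld_block_matrix([(3, "compound", 0.5)], h.rsids)
        omega = np.outer(h.se_y, h.se_y) * ld.rho
        # hand-coded Gaussian elimination for the two solves
        def solve(a, b):
            a = [row[:] for row in a.tolist()]
            b = list(b)
            n = len(b)
            for i in range(n):
                piv = a[i][i]
                for k in range(i + 1, n):
                    f = a[k][i] / piv
                    for c in range(i, n):
                        a[k][c] -= f * a[i][c]
                    b[k] -= f * b[i]
            x = [0.0] * n
            for i in reversed(range(n)):
                x[i] = (b[i] - sum(a[i][c] * x[c] for c in range(i + 1, n))) / a[i][i]
            return np.array(x)

        oi_bx = solve(omega, h.beta_x)
        oi_by = solve(omega, h.beta_y)
        theta = (h.beta_x @ oi_by) / (h.beta_x @ oi_bx)
        e = ivw_correlated(h, ld, variance_model="fixed")
        assert e.log_or == pytest.approx(theta, abs=1e-10)
        assert e.se == pytest.approx((h.beta_x @ oi_bx) ** -0.5, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_direct_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_harmonized(rng, j=6)
        ld = make_ld_block_matrix([(3, "ar1", 0.6), (3, "compound", 0.4)], h.rsids)
        omega = np.outer(h.se_y, h.se_y) * ld.rho
        theta, se = gls_ivw_oracle(h.beta_x, h.beta_y, omega)
        e = ivw_correlated(h, ld, variance_model="fixed")
        assert e.log_or == pytest.approx(theta, abs=1e-10)
        assert e.se == pytest.approx(se, abs=1e-10)


class TestEgger:
    def test_points_through_origin_give_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = hset(bx, 0.5 * bx, [0.01, 0.02, 0.015, 0.01])
        e = egger(h, variance_model="fixed")
        assert e.intercept == pytest.approx(0.0, abs=1e-12)
        assert e.log_or == pytest.approx(0.5, abs=1e-12)

    def test_orientation_invariance(self, rng):
        h = random_harmonized(rng, j=8)
        flip = rng.random(8) < 0.5
        s = np.where(flip, -1.0, 1.0)
        h2 = hset(h.beta_x * s, h.beta_y * s, h.se_y, h.se_x)
        a, b = egger(h), egger(h2)
        assert a.log_or == pytest.approx(b.log_or, abs=1e-12)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)

    def test_insufficient_instruments(self):
        with pytest.raises(ValueError, match="insufficient"):
            egger(hset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_design_matrix_oracle(self, seed):
        h = random_harmonized(np.random.default_rng(seed), j=10)
        e = egger(h, variance_model="fixed")
        alpha, theta, se_a, se_t = egger_oracle(h.beta_x, h.beta_y, h.se_y)
        assert e.log_or == pytest.approx(theta, abs=1e-10)
        assert e.intercept == pytest.approx(alpha, abs=1e-10)
        assert e.se == pytest.approx(se_t, abs=1e-10)
        assert e.intercept_se == pytest.approx(se_a, abs=1e-10)


class TestEggerCorrelated:
    def test_identity_ld_reduces_to_canonical(self, rng):
        h = random_harmonized(rng, j=6)
        a = egger_correlated(h, LDMatrix.identity(h.rsids), variance_model="fixed")
        b = egger(h, variance_model="fixed")
        assert a.log_or == pytest.approx(b.log_or, abs=1e-12)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_whitening_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_harmonized(rng, j=4)
        ld = make_ld_block_matrix([(4, "compound", 0.6)], h.rsids)
        omega = np.outer(h.se_y, h.se_y) * ld.rho
        alpha, theta, se_a, se_t = gls_egger_whitening_oracle(h.beta_x, h.beta_y, omega)
        e = egger_correlated(h, ld, variance_model="fixed")
        assert e.log_or == pytest.approx(theta, abs=1e-10)
        assert e.intercept == pytest.approx(alpha, abs=1e-10)
        assert e.se == pytest.approx(se_t, abs=1e-10)

    def test_singular_covariance_without_ridge_errors(self):
        h = hset([0.2, 0.2, 0.3], [0.05, 0.05, 0.07], [0.01, 0.01, 0.02])
        rho = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="ridge|singular"):
            egger_correlated(h, LDMatrix(h.rsids, rho))


class TestWeightedMedian:
    def test_equal_weights_middle_order_statistic(self):
        h = hset([0.2, 0.2, 0.2], [0.2 * 1, 0.2 * 2, 0.2 * 3], [0.01, 0.01, 0.01])
        e = weighted_median(h, seed=1)
        assert e.log_or == pytest.approx(2.0)

    def test_dominant_weight_with_symmetric_flanks(self):
        # middle variant carries 0.6 of the weight; its half-mass point is
        # exactly 0.5, so the estimate equals its ratio
        sy = np.array([0.01, 0.01, 0.01])
        bx = np.array([0.2, 0.2 * math.sqrt(3.0), 0.2])
        by = np.array([1.0, 2.0, 3.0]) * bx
        e = weighted_median(hset(bx, by, sy), seed=1)
        assert e.log_or == pytest.approx(2.0)

    def test_same_seed_reproduces_se_bitwise(self):
        h = hset([0.1, 0.2, 0.3, 0.4], [0.02, 0.05, 0.04, 0.1], [0.01, 0.02, 0.01, 0.03])
        a = weighted_median(h, n_boot=300, seed=42)
        b = weighted_median(h, n_boot=300, seed=42)
        assert a.se == b.se

    def test_different_seeds_agree_within_bootstrap_noise(self):
        h = hset([0.1, 0.2, 0.3, 0.4], [0.02, 0.05, 0.04, 0.1], [0.01, 0.02, 0.01, 0.03])
        n_boot = 2000
        a = weighted_median(h, n_boot=n_boot, seed=1)
        b = weighted_median(h, n_boot=n_boot, seed=2)
        mc_sd = a.se / math.sqrt(2 * (n_boot - 1))
        assert abs(a.se - b.se) < 3 * mc_sd

    @given(st.integers(0, 2**31 - 1))
    def test_point_estimate_matches_exhaustive_scan(self, seed):
        h = random_harmonized(np.random.default_rng(seed), j=5)
        e = weighted_median(h, n_boot=2, seed=0)
        theta = weighted_median_oracle(h.beta_y / h.beta_x, h.beta_x**2 / h.se_y**2)
        assert e.log_or == pytest.approx(theta, abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(ValueError, match="insufficient"):
            weighted_median(hset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]), seed=0)


class TestOddsRatioScale:
    def test_null_effect(self):
        or_v, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_v == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_reproduces_printed_interval(self):
        # back-solved from OR 0.872 (0.786-0.967): log-midpoint and half-width
        or_v, lo, hi = to_odds_ratio(-0.13699, 0.05287)
        assert or_v == pytest.approx(0.872, abs=5e-4)
        assert lo == pytest.approx(0.786, abs=5e-4)
        assert hi == pytest.approx(0.967, abs=5e-4)

    def test_monotone_in_log_or(self):
        ors = [to_odds_ratio(x, 0.05)[0] for x in (-0.2, -0.1, 0.0, 0.1)]
        assert all(a < b for a, b in zip(ors, ors[1:]))


class TestCrossEstimatorInvariants:
    def test_joint_negation_leaves_all_five_unchanged(self, rng):
        # reorienting a variant to its other allele negates (beta_x, beta_y)
        # jointly and flips the sign of that variant's LD correlations, so
        # the LD matrix is conjugated consistently with the flip
        h = random_harmonized(rng, j=6)
        ld = make_ld_block_matrix([(6, "ar1", 0.5)], h.rsids)
        s = np.where(rng.random(6) < 0.5, -1.0, 1.0)
        h2 = hset(h.beta_x * s, h.beta_y * s, h.se_y, h.se_x)
        ld2 = LDMatrix(h.rsids, ld.rho * np.outer(s, s))
        for f, g in (
            (lambda x: ivw(x).log_or,) * 2,
            (lambda x: egger(x).log_or,) * 2,
            (lambda x: weighted_median(x, n_boot=2, seed=0).log_or,) * 2,
            (lambda x: ivw_correlated(x, ld).log_or, lambda x: ivw_correlated(x, ld2).log_or),
            (lambda x: egger_correlated(x, ld).log_or, lambda x: egger_correlated(x, ld2).log_or),
        ):
            assert f(h) == pytest.approx(g(h2), abs=1e-12)

    def test_all_ratios_equal_returns_the_constant(self, rng):
        c = 0.5  # power of two so the ratios are exact in floating point
        bx = rng.uniform(0.1, 0.5, 6)
        h = hset(bx, c * bx, rng.uniform(0.01, 0.05, 6))
        ld = LDMatrix.identity(h.rsids)
        assert ivw(h).log_or == c
        assert ivw_correlated(h, ld).log_or == c
        assert weighted_median(h, n_boot=2, seed=0).log_or == c
        assert egger(h).log_or == pytest.approx(c, abs=1e-12)
        assert egger_correlated(h, ld).log_or == pytest.approx(c, abs=1e-12)

    def test_parameter_recovery_with_vanishing_noise(self):
        theta = -0.137
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.1, 0.6, 8)
        se = 1e-6
        by = theta * bx + se * rng.standard_normal(8)
        h = hset(bx, by, np.full(8, se), np.full(8, se))
        ld = LDMatrix.identity(h.rsids)
        for est in (
            ivw(h), ivw_correlated(h, ld), egger(h), egger_correlated(h, ld),
            weighted_median(h, n_boot=50, seed=0),
        ):
            assert est.log_or == pytest.approx(theta, abs=1e-4)
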