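"""Distance covariance/correlation estimators against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goalder.distance import (
    check_weight_vector,
    conditional_distance_correlation,
    conditional_distance_correlation_profile,
    distance_correlation,
    weighted_distance_correlation,
    weighted_distance_covariance_sq,
)

from conftest import (
    loop_dcor,
    loop_weighted_dcor,
    loop_weighted_dcov_sq,
    random_weight_vector,
)


class TestDistanceCorrelation:
    def test_perfect_dependence_of_self(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert distance_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_variable_convention(self):
        x = np.ones(6)
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        assert distance_correlation(x, y) == 0.0
        assert distance_correlation(y, x) == 0.0

    def test_matches_bruteforce_on_fixed_example(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 0.0, 3.0, 2.0, 5.0])
        assert distance_correlation(x, y) == pytest.approx(loop_dcor(x, y), abs=1e-10)

    @pytest.mark.parametrize("n", [4, 7, 12])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_instances(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        assert distance_correlation(x, y) == pytest.approx(loop_dcor(x, y), abs=1e-10)

    def test_vector_valued_observations(self, rng):
        x = rng.standard_normal((9, 3))
        y = rng.standard_normal(9)
        assert distance_correlation(x, y) == pytest.approx(loop_dcor(x, y), abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        r = distance_correlation(x, y)
        assert 0.0 <= r <= 1.0
        assert distance_correlation(y, x) == pytest.approx(r, abs=1e-12)
        assert distance_correlation(2.5 * x - 3.0, y) == pytest.approx(r, abs=1e-9)
        assert distance_correlation(x, -0.7 * y + 11.0) == pytest.approx(r, abs=1e-9)

    def test_small_sample_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            distance_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            distance_correlation([1.0, np.nan, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])

    def test_independent_gaussians_rarely_exceed_point_one(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(1000)
            y = rng.standard_normal(1000)
            if distance_correlation(x, y) < 0.1:
                hits += 1
        assert hits >= 95


class TestWeightedDistanceStatistics:
    def test_uniform_weights_reduce_to_unweighted(self, rng):
        x = rng.standard_normal(11)
        y = rng.standard_normal(11)
        ones = np.ones(11)
        dcov2_w = weighted_distance_covariance_sq(x, y, ones)
        assert dcov2_w == pytest.approx(loop_weighted_dcov_sq(x, y, ones), abs=1e-10)
        assert weighted_distance_correlation(x, y, ones) == pytest.approx(
            distance_correlation(x, y), abs=1e-10
        )

    def test_weighted_dcov_matches_loop_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        w = random_weight_vector(rng, 6)
        assert weighted_distance_covariance_sq(x, y, w) == pytest.approx(
            loop_weighted_dcov_sq(x, y, w), abs=1e-10
        )

    def test_weighted_dcor_matches_loop_oracle(self):
        rng = np.random.default_rng(43)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        w = random_weight_vector(rng, 8)
        assert weighted_distance_correlation(x, y, w) == pytest.approx(
            loop_weighted_dcor(x, y, w), abs=1e-10
        )

    def test_matched_arguments_nonnegative_and_unit_dcor(self, rng):
        x = rng.standard_normal(10)
        w = random_weight_vector(rng, 10)
        assert weighted_distance_covariance_sq(x, x, w) >= 0.0
        assert weighted_distance_correlation(x, x, w) == pytest.approx(1.0, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_quadratic_form_nonnegative_for_any_weights(self, seed):
        # -A and -B are PSD, so the Hadamard quadratic form never goes negative
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(9)
        y = rng.standard_normal(9)
        w = random_weight_vector(rng, 9)
        assert weighted_distance_covariance_sq(x, y, w) >= -1e-12

    def test_mismatched_lengths_and_bad_weights_rejected(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        with pytest.raises(ValueError):
            weighted_distance_covariance_sq(x, y, np.ones(7))
        with pytest.raises(ValueError):
            weighted_distance_covariance_sq(x, y, -np.ones(8))
        with pytest.raises(ValueError):
            check_weight_vector(np.full(8, 2.0), 8)  # sums to 16, not 8


class TestConditionalDistanceCorrelation:
    def test_independent_covariate_scores_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = rng.standard_normal(500)
            y = t + rng.standard_normal(500)
            z = rng.standard_normal(500)  # independent of (Y, T)
            vals.append(conditional_distance_correlation(z, y, t))
        assert np.mean(vals) < 0.1

    def test_strong_conditional_dependence_detected(self):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = rng.standard_normal(500)
            z = rng.standard_normal(500)
            y = z.copy()
            vals.append(conditional_distance_correlation(z, y, t))
        assert np.mean(vals) > 0.5

    def test_constant_covariate_convention(self, rng):
        t = rng.standard_normal(50)
        y = rng.standard_normal(50)
        assert conditional_distance_correlation(np.ones(50), y, t) == 0.0

    def test_constant_conditioning_falls_back_with_warning(self, rng):
        z = rng.standard_normal(40)
        y = rng.standard_normal(40)
        with pytest.warns(RuntimeWarning):
            val = conditional_distance_correlation(z, y, np.ones(40))
        assert val == pytest.approx(distance_correlation(z, y), abs=1e-10)

    def test_affine_invariance_in_z_and_y(self, rng):
        t = rng.standard_normal(120)
        z = t + rng.standard_normal(120)
        y = z + rng.standard_normal(120)
        base = conditional_distance_correlation(z, y, t)
        scaled = conditional_distance_correlation(3.0 * z - 5.0, -2.0 * y + 1.0, t)
        assert scaled == pytest.approx(base, abs=1e-8)

    def test_profile_matches_scalar_calls(self, rng):
        t = rng.standard_normal(60)
        z = rng.standard_normal((60, 3))
        y = z[:, 0] + rng.standard_normal(60)
        prof = conditional_distance_correlation_profile(z, y, t)
        for j in range(3):
            assert prof[j] == pytest.approx(
                conditional_distance_correlation(z[:, j], y, t), abs=1e-12
            )

    def test_minimum_sample_size_enforced(self, rng):
        with pytest.raises(ValueError):
            conditional_distance_correlation(
                rng.standard_normal(8), rng.standard_normal(8), rng.standard_normal(8)
            )
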