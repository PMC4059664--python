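"""Uniform and robust combinations: exact values, range law, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mp2rage import (
    ComplexVolumePair,
    beta_sweep,
    estimate_beta,
    make_phantom,
    robust_combination,
    robust_from_magnitude,
    robust_image,
    simulate_acquisition,
    uniform_combination,
    uniform_image,
)
from conftest import random_signal_pairs

finite_complex = st.complex_numbers(
    allow_nan=False, allow_infinity=False, max_magnitude=1e12
)
small_beta = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestUniform:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            (3.0, 3.0, 0.5),          # identical signals
            (2.0, -2.0, -0.5),        # anti-phase
            (0.0, 1.0, 0.0),          # orthogonal
            (1j, 1j, 0.5),            # common phase irrelevant
        ],
    )
    def test_closed_form_values(self, s1, s2, expected):
        assert uniform_combination(s1, s2) == pytest.approx(expected, abs=1e-15)

    def test_degenerate_zero_over_zero(self):
        assert uniform_combination(0.0, 0.0) == 0.0

    def test_degenerate_voxels_flagged(self):
        pair = ComplexVolumePair(np.array([0j, 1.0]), np.array([0j, 1.0]))
        img = uniform_image(pair)
        assert img.degenerate.tolist() == [True, False]
        assert img.values.tolist() == [0.0, 0.5]

    @given(s1=finite_complex, s2=finite_complex)
    @settings(max_examples=300, deadline=None)
    def test_range_law(self, s1, s2):
        assert abs(uniform_combination(s1, s2)) <= 0.5 + 1e-12

    @given(s1=finite_complex, s2=finite_complex, c=finite_complex)
    @settings(max_examples=300, deadline=None)
    def test_self_bias_correction(self, s1, s2, c):
        """A common complex factor (PD, B1-, T2*, phase) cancels exactly."""
        if abs(c) < 1e-6 or abs(c) > 1e6:
            return
        u0 = uniform_combination(s1, s2)
        u1 = uniform_combination(c * s1, c * s2)
        assert u1 == pytest.approx(u0, abs=1e-12)


class TestRobust:
    def test_zero_signal_forced_to_floor(self):
        for beta in (1e-6, 1.0, 1e6):
            assert robust_combination(0.0, 0.0, beta) == -0.5

    def test_hand_evaluated_value(self):
        # (1*2 - 1) / (1 + 4 + 2*1) = 1/7
        assert robust_combination(1.0, 2.0, 1.0) == pytest.approx(1.0 / 7.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            robust_combination(1.0, 1.0, -0.1)

    def test_beta_zero_reduces_to_uniform(self, rng):
        s1, s2 = random_signal_pairs(rng, 1000)
        np.testing.assert_allclose(
            robust_combination(s1, s2, 0.0),
            uniform_combination(s1, s2),
            atol=1e-12,
        )

    @given(s1=finite_complex, s2=finite_complex, beta=small_beta)
    @settings(max_examples=300, deadline=None)
    def test_range_law(self, s1, s2, beta):
        assert abs(robust_combination(s1, s2, beta)) <= 0.5 + 1e-12

    def test_scale_equivalence(self, rng):
        """robust(c*s, beta) == robust(s, beta/|c|^2): beta lives in squared units."""
        s1, s2 = random_signal_pairs(rng, 500)
        c = 3.0 - 4.0j  # |c|^2 = 25
        np.testing.assert_allclose(
            robust_combination(c * s1, c * s2, 2.5),
            robust_combination(s1, s2, 2.5 / 25.0),
            atol=1e-12,
        )

    def test_bias_vanishes_at_high_signal(self):
        """Deviation from the uniform value decreases with signal power."""
        beta = 1.0
        devs = []
        for scale in (1.0, 3.0, 10.0, 100.0):
            s1, s2 = scale * (1.0 + 0.5j), scale * (2.0 - 0.3j)
            devs.append(
                abs(robust_combination(s1, s2, beta) - uniform_combination(s1, s2))
            )
        assert devs == sorted(devs, reverse=True)

    def test_approaches_uniform_value(self):
        s1, s2 = 100.0, 200.0
        assert robust_combination(s1, s2, 1.0) == pytest.approx(
            uniform_combination(s1, s2), abs=1e-3
        )


class TestRobustFromMagnitude:
    def test_beta_zero_identity(self):
        u = np.array([-0.3, 0.0, 0.4])
        m = np.ones(3)
        np.testing.assert_allclose(robust_from_magnitude(u, m, m, 0.0), u)

    def test_zero_signal_floor(self):
        assert robust_from_magnitude(0.0, 0.0, 0.0, 1.0) == -0.5

    def test_hand_evaluated_value(self):
        # (0.2*5 - 1) / (5 + 2) = 0
        assert robust_from_magnitude(0.2, 1.0, 2.0, 1.0) == pytest.approx(0.0)

    def test_out_of_range_uniform_rejected(self):
        with pytest.raises(ValueError):
            robust_from_magnitude(0.7, 1.0, 1.0, 1.0)

    def test_matches_complex_route(self, rng):
        """Magnitude+uniform reconstruction equals the complex-valued formula."""
        s1, s2 = random_signal_pairs(rng, 1000)
        # common phase so that conj(s1)*s2 is as in a real acquisition
        u = uniform_combination(s1, s2)
        beta = 0.37
        expected = robust_combination(s1, s2, beta)
        got = robust_from_magnitude(u, np.abs(s1), np.abs(s2), beta)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestEstimateBeta:
    def test_noise_free_phantom_gives_zero(self, clean_pair):
        assert estimate_beta(clean_pair) == 0.0

    def test_linear_in_multiplier(self, noisy_pair):
        b1 = estimate_beta(noisy_pair, multiplier=10.0)
        b2 = estimate_beta(noisy_pair, multiplier=20.0)
        assert b2 == pytest.approx(2.0 * b1, rel=1e-12)

    def test_all_zero_volume_warns(self):
        pair = ComplexVolumePair(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))
        with pytest.warns(UserWarning):
            assert estimate_beta(pair) == 0.0

    def test_monte_carlo_accuracy(self, phantom64, protocol):
        """sigma^2 estimate within 15% of the generating value over 10 seeds."""
        sigma = 3.5e-4
        estimates = []
        for seed in range(10):
            pair = simulate_acquisition(phantom64, protocol, noise_sigma=sigma, seed=seed)
            estimates.append(estimate_beta(pair, multiplier=1.0))
        estimates = np.array(estimates)
        assert np.all(np.abs(estimates / sigma**2 - 1.0) < 0.15)

    def test_magnitude_input_route(self, noisy_pair):
        b_complex = estimate_beta(noisy_pair)
        b_mag = estimate_beta(np.abs(noisy_pair.s1), m2=np.abs(noisy_pair.s2))
        assert b_mag == pytest.approx(b_complex, rel=1e-12)


class TestBetaSweep:
    def test_empty_list(self, noisy_pair):
        assert beta_sweep(noisy_pair, []) == []

    def test_beta_zero_equals_uniform(self, noisy_pair):
        (img,) = beta_sweep(noisy_pair, [0.0])
        np.testing.assert_allclose(img.values, uniform_image(noisy_pair).values)

    def test_repeated_beta_deterministic(self, noisy_pair):
        a, b = beta_sweep(noisy_pair, [1e-5, 1e-5])
        np.testing.assert_array_equal(a.values, b.values)

    def test_background_std_decreases_with_beta(self, noisy_pair, phantom64):
        beta = estimate_beta(noisy_pair)
        images = beta_sweep(noisy_pair, [beta / 10, beta, 10 * beta])
        bg = phantom64.background_mask
        stds = [img.values[bg].std() for img in images]
        assert stds[0] > stds[1] > stds[2]

    def test_output_order_and_metadata(self, noisy_pair):
        betas = [1e-6, 1e-5, 1e-4]
        images = beta_sweep(noisy_pair, betas)
        assert [img.beta for img in images] == betas
        assert all(img.mode == "robust" for img in images)


class TestCombinedImage:
    def test_rejects_out_of_range_values(self):
        from mp2rage import CombinedImage

        with pytest.raises(ValueError):
            CombinedImage(values=np.array([0.7]), mode="uniform")
        with pytest.raises(ValueError):
            CombinedImage(values=np.array([np.nan]), mode="robust", beta=1.0)
        with pytest.raises(ValueError):
            CombinedImage(values=np.array([0.1]), mode="sharp")

    def test_integer_export_range(self, noisy_pair):
        img = robust_image(noisy_pair, 1e-5)
        exported = img.rescaled()
        assert exported.min() >= 0 and exported.max() <= 4095

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ComplexVolumePair(np.ones(3), np.ones(4))
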