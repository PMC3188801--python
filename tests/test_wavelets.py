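"""Haar transform, noise filtering and the center statistic."""

import numpy as np
import pytest
import pywt
from hypothesis import given, strategies as st

from steppco.wavelets import (
    LevelSummary,
    drop_high_levels,
    default_max_level,
    estimate_noise_filter,
    filtered_center,
    haar_transform,
    haar_wavelet,
    inverse_haar,
    normalize_center,
    subtract_baseline,
    threshold_filter,
    wavelet_center,
    wavelet_summary,
)


def _square_wave(L: int, level: int) -> np.ndarray:
    """±1 square wave whose half-period is 2^(L-level) samples."""
    half = 2 ** (L - level)
    return np.tile(np.concatenate([np.ones(half), -np.ones(half)]),
                   2 ** (level - 1))


class TestTransform:
    def test_constant_signal_has_zero_coefficients(self):
        spec = haar_transform(np.full(32, 3.7))
        assert spec.average == pytest.approx(3.7)
        assert all(np.all(c == 0) for c in spec.coeffs)

    def test_hand_cascade_on_four_samples(self):
        spec = haar_transform([1.0, 1.0, -1.0, -1.0])
        assert spec.average == 0.0
        np.testing.assert_allclose(spec.coeffs[1], [0.0, 0.0])  # level 2
        assert abs(spec.coeffs[0][0]) == pytest.approx(1.0)     # level 1
        s = wavelet_summary(spec).s
        np.testing.assert_allclose(s, [1.0, 0.0])

    def test_matches_reference_dwt_up_to_normalization(self):
        rng = np.random.default_rng(8)
        for L in (4, 6):
            x = rng.normal(size=2 ** L)
            spec = haar_transform(x)
            details = pywt.wavedec(x, "haar")[1:]  # coarsest..finest
            for l in range(1, L + 1):
                ref = np.abs(details[l - 1]) / np.sqrt(2.0 ** (L - l + 1))
                np.testing.assert_allclose(np.abs(spec.coeffs[l - 1]), ref,
                                           atol=1e-12)

    @given(st.integers(1, 8), st.integers(0, 2**32 - 1))
    def test_roundtrip_is_lossless(self, L, seed):
        x = np.random.default_rng(seed).normal(size=2 ** L)
        back = inverse_haar(haar_transform(x))
        np.testing.assert_allclose(back, x, rtol=1e-12, atol=1e-12)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            haar_transform(np.ones(12))

    def test_single_coefficient_reconstructs_the_wavelet(self):
        L = 5
        for (l, p) in [(1, 1), (3, 2), (5, 16)]:
            spec = haar_transform(np.zeros(2 ** L))
            spec.coeffs[l - 1][p - 1] = 1.0
            np.testing.assert_allclose(inverse_haar(spec), haar_wavelet(L, l, p))

    def test_basis_orthogonality_zero_mean_unit_amplitude(self):
        L = 4
        basis = [haar_wavelet(L, l, p)
                 for l in range(1, L + 1) for p in range(1, 2 ** (l - 1) + 1)]
        assert len(basis) == 2 ** L - 1
        for i, wi in enumerate(basis):
            assert wi.sum() == 0.0
            assert set(np.unique(wi[wi != 0])) == {-1.0, 1.0}
            for wj in basis[i + 1:]:
                assert np.dot(wi, wj) == 0.0


class TestFilters:
    def test_zero_threshold_is_identity(self):
        spec = haar_transform(np.random.default_rng(0).normal(size=64))
        out = threshold_filter(spec, 0.0)
        for a, b in zip(out.coeffs, spec.coeffs):
            np.testing.assert_array_equal(a, b)

    def test_infinite_threshold_leaves_only_the_average(self):
        x = np.random.default_rng(1).normal(size=64) + 5.0
        out = threshold_filter(haar_transform(x), np.inf)
        np.testing.assert_allclose(inverse_haar(out), np.full(64, x.mean()))

    def test_mixed_thresholds_follow_the_printed_rule(self):
        rng = np.random.default_rng(2)
        spec = haar_transform(rng.normal(size=128))
        t = [np.abs(rng.normal(size=2 ** (l - 1))) for l in range(1, 8)]
        out = threshold_filter(spec, t)
        for l in range(7):
            expect = np.where(np.abs(spec.coeffs[l]) <= t[l], 0.0, spec.coeffs[l])
            np.testing.assert_array_equal(out.coeffs[l], expect)

    def test_negative_threshold_rejected(self):
        spec = haar_transform(np.ones(8))
        with pytest.raises(ValueError, match="non-negative"):
            threshold_filter(spec, -0.1)

    def test_level_drop(self):
        spec = haar_transform(np.random.default_rng(3).normal(size=1024))
        assert default_max_level(10) == 7
        out = drop_high_levels(spec, 7)
        for l in range(1, 8):
            np.testing.assert_array_equal(out.coeffs[l - 1], spec.coeffs[l - 1])
        for l in range(8, 11):
            assert np.all(out.coeffs[l - 1] == 0)
        assert np.all(wavelet_summary(out).s[7:] == 0)
        same = drop_high_levels(spec, 10)
        for a, b in zip(same.coeffs, spec.coeffs):
            np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            drop_high_levels(spec, 11)

    def test_denoising_recovers_a_blocky_signal(self):
        rng = np.random.default_rng(4)
        clean = _square_wave(8, 3)
        noisy = clean + rng.uniform(-0.05, 0.05, clean.size)
        spec = threshold_filter(haar_transform(noisy), 0.06)
        np.testing.assert_allclose(inverse_haar(spec), clean, atol=0.12)


class TestSummaryAndCenter:
    def test_summary_single_coefficient(self):
        spec = haar_transform(np.zeros(64))
        spec.coeffs[4][2] = -0.8  # level 5 has 16 positions
        s = wavelet_summary(spec).s
        assert s[4] == pytest.approx(0.8 / 16)
        assert np.all(np.delete(s, 4) == 0)

    def test_summary_matches_brute_force(self):
        spec = haar_transform(np.random.default_rng(5).normal(size=256))
        s = wavelet_summary(spec).s
        brute = [np.abs(spec.coeffs[l]).sum() / 2 ** l for l in range(8)]
        np.testing.assert_allclose(s, brute)

    def test_center_simple_cases(self):
        assert wavelet_center(LevelSummary(np.array([2.0, 0, 0]))) == 1.0
        assert wavelet_center(LevelSummary(np.array([1.0, 1.0, 0]))) == 1.5
        rng = np.random.default_rng(6)
        s = rng.uniform(0, 1, 9)
        expect = (np.arange(1, 10) * s).sum() / s.sum()
        assert wavelet_center(LevelSummary(s)) == pytest.approx(expect)
        with pytest.raises(ValueError, match="undefined"):
            wavelet_center(LevelSummary(np.zeros(4)))

    def test_center_is_scale_invariant(self):
        x = np.random.default_rng(7).normal(size=128)
        c1 = wavelet_center(wavelet_summary(haar_transform(x)))
        c2 = wavelet_center(wavelet_summary(haar_transform(7.5 * x)))
        assert c1 == pytest.approx(c2)

    def test_square_wave_center_equals_its_level(self):
        L = 8
        for level in range(1, L + 1):
            spec = haar_transform(_square_wave(L, level))
            assert wavelet_center(wavelet_summary(spec)) == pytest.approx(level)

    def test_halving_block_width_raises_center_by_one(self):
        c3 = wavelet_center(wavelet_summary(haar_transform(_square_wave(9, 3))))
        c4 = wavelet_center(wavelet_summary(haar_transform(_square_wave(9, 4))))
        assert c4 - c3 == pytest.approx(1.0)

    def test_subtract_baseline(self):
        s = LevelSummary(np.array([0.5, 0.2, 0.0]))
        same = subtract_baseline(s, np.zeros(3))
        np.testing.assert_array_equal(same.s, s.s)
        gone = subtract_baseline(s, np.array([1.0, 1.0, 1.0]))
        assert gone.total == 0.0
        with pytest.raises(ValueError):
            wavelet_center(gone)
        with pytest.raises(ValueError):
            subtract_baseline(s, np.zeros(2))

    def test_normalize_center_shifts_by_log2_length_ratio(self):
        assert normalize_center(3.0, 2.78, 2.78) == 3.0
        assert normalize_center(3.0, 2.0, 1.0) == pytest.approx(2.0)
        chained = normalize_center(normalize_center(5.0, 4.0, 2.0), 2.0, 1.0)
        assert chained == pytest.approx(normalize_center(5.0, 4.0, 1.0))
        with pytest.raises(ValueError):
            normalize_center(3.0, 0.0, 1.0)


class TestNoiseFilterEstimation:
    def test_internal_parental_admixture_is_subtracted(self):
        """Shared block structure present in parents and admixed alike must
        not move the admixed cohort's center (the parental signal is
        removed by thresholding/baseline subtraction)."""
        rng = np.random.default_rng(10)
        L, n = 10, 1024
        shared = 0.35 * _square_wave(L, 2)
        admixed_blocks = _square_wave(L, 4)

        def center_with(pattern):
            parents = [pole + 0.04 * rng.normal(size=n) + pattern
                       for pole in (1.0, -1.0) for _ in range(20)]
            spectra = [haar_transform(p, 2.78) for p in parents]
            nf = estimate_noise_filter(spectra)
            admixed = admixed_blocks + 0.04 * rng.normal(size=n) + pattern
            return filtered_center(admixed, 2.78, 2.78, noise_filter=nf)

        c_plain = center_with(np.zeros(n))
        c_shared = center_with(shared)
        assert abs(c_plain - c_shared) <= 0.1

    def test_threshold_modes(self):
        rng = np.random.default_rng(11)
        spectra = [haar_transform(rng.normal(size=64)) for _ in range(10)]
        for mode in ("level_quantile", "level_max", "scalar"):
            nf = estimate_noise_filter(spectra, mode=mode)
            assert nf.max_level == default_max_level(6)
            assert np.all(np.asarray(nf.baseline) >= 0)
        with pytest.raises(ValueError, match="mode"):
            estimate_noise_filter(spectra, mode="bogus")

    def test_filtered_center_returns_nan_when_nothing_survives(self):
        assert np.isnan(filtered_center(np.zeros(64), 1.0, 1.0))
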