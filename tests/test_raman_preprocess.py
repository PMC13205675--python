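"""Preprocessing chain: truncation, despiking, SNIP, smoothing, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovamat.errors import (
    DegenerateSpectrumError,
    ParameterError,
    RangeError,
)
from ovamat.raman import (
    PreprocessConfig,
    area_normalize,
    preprocess_map,
    remove_cosmic_spikes,
    savitzky_golay,
    snip_baseline,
    subtract_baseline,
    truncate_range,
)
from ovamat.raman.types import HyperspectralMap, RamanSpectrum
from ovamat.synthetic import default_raman_phantom, gen_raman_cube


def spectrum(w, y):
    return RamanSpectrum(np.asarray(w, float), np.asarray(y, float))


def snip_oracle(y, M):
    """Independent plain clipping recurrence (naive loop implementation)."""
    v = list(map(float, y))
    n = len(v)
    for m in range(1, M + 1):
        new = v[:]
        for i in range(m, n - m):
            new[i] = min(v[i], 0.5 * (v[i - m] + v[i + m]))
        v = new
    return np.array(v)


class TestTruncate:
    def test_inclusive_channel_count(self):
        w = np.arange(100.0, 3001.0)
        s = spectrum(w, np.ones_like(w))
        out = truncate_range(s, 400, 2000)
        assert len(out) == 1601
        assert out.wavenumbers[0] == 400 and out.wavenumbers[-1] == 2000

    def test_full_span_is_identity(self):
        w = np.linspace(400, 2000, 50)
        s = spectrum(w, np.sin(w))
        out = truncate_range(s, 0, 5000)
        assert np.array_equal(out.wavenumbers, s.wavenumbers)
        assert np.array_equal(out.intensities, s.intensities)

    def test_degenerate_interval_errors(self):
        w = np.linspace(400, 2000, 50)
        with pytest.raises(RangeError):
            truncate_range(spectrum(w, w), 800, 800)

    def test_works_on_maps(self):
        w = np.linspace(100, 3000, 30)
        A = np.outer(np.ones(30), np.arange(6.0))
        out = truncate_range(HyperspectralMap(w, A, (3, 2)), 400, 2000)
        keep = (w >= 400) & (w <= 2000)
        assert out.A.shape == (keep.sum(), 6)


class TestDespike:
    def test_spike_free_map_unchanged(self):
        # spatially flat abundances: the residual against the neighborhood
        # median is pure noise, far below the z=8 threshold
        from ovamat.synthetic import RamanPhantomSpec

        axis = np.linspace(400, 2000, 201)
        spec = RamanPhantomSpec(
            n_components=2,
            peak_tables=[[(900, 20, 1.0)], [(1500, 25, 0.8)]],
            wavenumber_axis=axis, grid_shape=(10, 8),
            abundance_fields=[np.full((8, 10), 1.0),
                              np.full((8, 10), 0.6)],
            noise_sd=0.01, spike_rate=0.0, seed=3,
        )
        hmap, _, _ = gen_raman_cube(spec)
        out, mask = remove_cosmic_spikes(hmap)
        assert mask.sum() == 0
        assert np.array_equal(out.A, hmap.A)

    def test_known_spikes_recalled_with_low_fpr(self):
        spec = default_raman_phantom(seed=7)  # 0.1% spikes, 20x noise
        hmap, _, truth_mask = gen_raman_cube(spec)
        _, found = remove_cosmic_spikes(hmap, z_threshold=8.0)
        tp = (found & truth_mask).sum()
        fp = (found & ~truth_mask).sum()
        assert tp / truth_mask.sum() >= 0.99
        assert fp / truth_mask.size <= 1e-4

    def test_spike_on_every_pixel_is_invisible(self):
        """A coherent spike moves the neighborhood median with it: the
        documented limitation of neighbor-based despiking."""
        spec = default_raman_phantom(grid_shape=(8, 8), n_channels=201,
                                     spike_rate=0.0, seed=5)
        hmap, _, _ = gen_raman_cube(spec)
        A = hmap.A.copy()
        A[100, :] += 50 * spec.noise_sd  # same channel, every pixel
        spiked = HyperspectralMap(hmap.wavenumbers, A, hmap.grid)
        _, mask = remove_cosmic_spikes(spiked)
        assert mask[100, :].sum() == 0

    def test_single_pixel_fallback(self):
        w = np.linspace(400, 2000, 201)
        rng = np.random.default_rng(0)
        y = 10 + rng.normal(0, 0.5, 201)
        y[77] += 60.0
        hmap = HyperspectralMap(w, y[:, None], (1, 1))
        out, mask = remove_cosmic_spikes(hmap)
        assert mask[77, 0]
        assert out.A[77, 0] < 30


class TestSnip:
    def test_constant_spectrum_is_fixed_point(self):
        w = np.linspace(400, 2000, 101)
        s = spectrum(w, np.full(101, 7.0))
        b = snip_baseline(s, use_lls=False)
        assert np.allclose(b.intensities, 7.0, atol=1e-12)

    def test_linear_ramp_is_fixed_point(self):
        w = np.linspace(400, 2000, 201)
        ramp = 2.0 + 0.01 * (w - 400)
        b = snip_baseline(spectrum(w, ramp), max_half_window=40,
                          use_lls=False)
        assert np.abs(b.intensities - ramp).max() < 1e-9

    def test_ramp_plus_peak_recovered_away_from_peak(self):
        """Baseline under a ramp+Gaussian phantom deviates < 5 (5% of the
        100-unit peak) beyond 3 sigma from the peak center."""
        n = 401
        w = np.linspace(400, 2000, n)
        ramp = 10 + 0.02 * (w - 400)
        center_idx = 200
        sigma = 5  # channels
        peak = 100 * np.exp(
            -0.5 * ((np.arange(n) - center_idx) / sigma) ** 2
        )
        y = ramp + peak
        b = snip_baseline(spectrum(w, y), max_half_window=40, use_lls=False)
        away = np.abs(np.arange(n) - center_idx) >= 3 * sigma
        assert np.abs(b.intensities - ramp)[away].max() < 5.0

    def test_matches_independent_recurrence(self):
        rng = np.random.default_rng(12)
        w = np.linspace(400, 2000, 120)
        y = 5 + rng.random(120) * 3
        got = snip_baseline(spectrum(w, y), max_half_window=20,
                            use_lls=False).intensities
        assert np.allclose(got, snip_oracle(y, 20), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), use_lls=st.booleans())
    def test_baseline_never_exceeds_input(self, seed, use_lls):
        rng = np.random.default_rng(seed)
        w = np.linspace(400, 2000, 150)
        y = np.abs(rng.normal(5, 3, 150)) + 20 * rng.random(150)
        b = snip_baseline(spectrum(w, y), max_half_window=30,
                          use_lls=use_lls)
        assert (b.intensities <= y + 1e-9).all()

    def test_window_too_large_rejected(self):
        w = np.linspace(400, 2000, 20)
        with pytest.raises(ParameterError):
            snip_baseline(spectrum(w, w), max_half_window=10)


class TestSubtract:
    def test_result_clipped_at_zero(self):
        w = np.linspace(400, 2000, 10)
        s = spectrum(w, np.full(10, 1.0))
        b = spectrum(w, np.full(10, 2.0))
        out = subtract_baseline(s, b)
        assert (out.intensities == 0).all()

    def test_mismatched_axes_rejected(self):
        w = np.linspace(400, 2000, 10)
        with pytest.raises(ParameterError):
            subtract_baseline(
                spectrum(w, w), spectrum(w + 1, w)
            )


class TestSavitzkyGolay:
    def test_cubic_polynomial_reproduced_in_interior(self):
        w = np.linspace(400, 2000, 201)
        y = 1e-8 * w**3 - 2e-5 * w**2 + 0.01 * w + 3
        out = savitzky_golay(spectrum(w, y), window=9, order=3)
        assert np.abs(out.intensities[4:-4] - y[4:-4]).max() < 1e-9

    def test_edges_match_mirror_convolution_oracle(self):
        from scipy.signal import savgol_coeffs

        rng = np.random.default_rng(3)
        w = np.linspace(400, 2000, 61)
        y = rng.normal(0, 1, 61)
        out = savitzky_golay(spectrum(w, y), window=9, order=3)
        # independent: convolve the mirror-padded signal explicitly
        padded = np.concatenate([y[4:0:-1], y, y[-2:-6:-1]])
        coeffs = savgol_coeffs(9, 3)[::-1]
        manual = np.convolve(padded, coeffs[::-1], mode="valid")
        assert np.allclose(out.intensities, manual, atol=1e-10)

    def test_constant_unchanged(self):
        w = np.linspace(400, 2000, 50)
        out = savitzky_golay(spectrum(w, np.full(50, 4.0)))
        assert np.allclose(out.intensities, 4.0, atol=1e-12)

    def test_variance_reduced_on_white_noise(self):
        rng = np.random.default_rng(99)
        w = np.linspace(400, 2000, 1601)
        y = rng.normal(0, 1, 1601)
        out = savitzky_golay(spectrum(w, y))
        assert out.intensities.var() < y.var()

    def test_too_short_spectrum_rejected(self):
        w = np.linspace(400, 2000, 5)
        with pytest.raises(ParameterError):
            savitzky_golay(spectrum(w, w), window=9)

    def test_even_window_rejected(self):
        w = np.linspace(400, 2000, 50)
        with pytest.raises(ParameterError):
            savitzky_golay(spectrum(w, w), window=8)


class TestAreaNormalize:
    def test_unit_integral(self):
        w = np.linspace(400, 2000, 100)
        out = area_normalize(spectrum(w, np.random.default_rng(0).random(100)))
        assert np.trapezoid(out.intensities, w) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_idempotent(self):
        w = np.linspace(400, 2000, 100)
        s = spectrum(w, 1 + np.sin(w / 100) ** 2)
        once = area_normalize(s)
        twice = area_normalize(once)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-12)

    def test_zero_spectrum_errors(self):
        w = np.linspace(400, 2000, 10)
        with pytest.raises(DegenerateSpectrumError):
            area_normalize(spectrum(w, np.zeros(10)))


class TestPreprocessMap:
    def test_pure_function_deterministic(self, small_phantom):
        hmap, _, _, _ = small_phantom
        a = preprocess_map(hmap)
        b = preprocess_map(hmap)
        assert np.array_equal(a.A, b.A)

    def test_output_nonnegative_unit_area(self, small_phantom):
        hmap, _, _, _ = small_phantom
        out = preprocess_map(hmap)
        assert (out.A >= 0).all()
        areas = np.trapezoid(out.A, out.wavenumbers, axis=0)
        assert np.allclose(areas, 1.0, atol=1e-9)

    def test_window_truncated(self, small_phantom):
        hmap, _, _, _ = small_phantom
        out = preprocess_map(hmap, PreprocessConfig(lo=600, hi=1500))
        assert out.wavenumbers[0] >= 600 and out.wavenumbers[-1] <= 1500
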