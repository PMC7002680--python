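import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seerpy as sp
from seerpy import ValidationError

from conftest import delta_cube


def brute_phasor(spectrum, harmonic, bandwidth=8.9):
    """Straight-from-definition oracle for one spectrum."""
    n = len(spectrum)
    c = np.arange(n)
    num_g = sum(spectrum[i] * np.cos(2 * np.pi * harmonic * i / n) * bandwidth for i in c)
    num_s = sum(spectrum[i] * np.sin(2 * np.pi * harmonic * i / n) * bandwidth for i in c)
    den = sum(spectrum) * bandwidth
    return num_g / den, num_s / den


class TestSpectralPhasor:
    def test_delta_spectrum_at_first_channel(self):
        field = sp.spectral_phasor(delta_cube(0), harmonic=2)
        assert field.g[0, 0, 0] == pytest.approx(1.0)
        assert field.s[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_flat_spectrum_maps_to_origin(self, axis32):
        cube = sp.SpectralImage(np.ones((1, 3, 3, 32)), axis32)
        field = sp.spectral_phasor(cube, harmonic=2)
        assert np.abs(field.g).max() < 1e-12
        assert np.abs(field.s).max() < 1e-12

    def test_mixture_lies_at_weighted_midpoint(self, axis32):
        """50/50 intensity mix of two deltas lands midway between the pure
        phasors (linearity of the transform)."""
        data = np.zeros((1, 1, 3, 32))
        data[0, 0, 0, 5] = 1.0
        data[0, 0, 1, 20] = 1.0
        data[0, 0, 2, 5] = 0.5
        data[0, 0, 2, 20] = 0.5
        f = sp.spectral_phasor(sp.SpectralImage(data, axis32), harmonic=2)
        assert f.g[0, 0, 2] == pytest.approx((f.g[0, 0, 0] + f.g[0, 0, 1]) / 2, abs=1e-9)
        assert f.s[0, 0, 2] == pytest.approx((f.s[0, 0, 0] + f.s[0, 0, 1]) / 2, abs=1e-9)

    @given(
        weights=st.lists(st.floats(0.0, 10.0), min_size=8, max_size=8),
        harmonic=st.sampled_from([1, 2, 3]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle_and_unit_disc(self, weights, harmonic):
        spectrum = np.array(weights)
        if spectrum.sum() <= 0:
            return
        cube = sp.SpectralImage(
            spectrum[None, None, None, :], sp.make_wavelength_axis(400, 10, 8)
        )
        f = sp.spectral_phasor(cube, harmonic=harmonic)
        g_ref, s_ref = brute_phasor(spectrum, harmonic, 10)
        assert f.g[0, 0, 0] == pytest.approx(g_ref, abs=1e-9)
        assert f.s[0, 0, 0] == pytest.approx(s_ref, abs=1e-9)
        assert f.g[0, 0, 0] ** 2 + f.s[0, 0, 0] ** 2 <= 1 + 1e-9

    def test_linearity_of_combinations(self, axis32, rng):
        """Phasor of a·S1 + b·S2 is the intensity-weighted convex combination
        of the component phasors."""
        s1 = rng.random(32)
        s2 = rng.random(32)
        a, b = 2.0, 5.0
        mix = a * s1 + b * s2
        cube = sp.SpectralImage(np.stack([s1, s2, mix])[None, None], axis32)
        f = sp.spectral_phasor(cube, harmonic=2)
        w1 = a * s1.sum() / mix.sum()
        w2 = b * s2.sum() / mix.sum()
        assert f.g[0, 0, 2] == pytest.approx(w1 * f.g[0, 0, 0] + w2 * f.g[0, 0, 1], abs=1e-9)
        assert f.s[0, 0, 2] == pytest.approx(w1 * f.s[0, 0, 0] + w2 * f.s[0, 0, 1], abs=1e-9)

    def test_zero_pixels_flagged_null(self, axis32):
        data = np.ones((1, 2, 2, 32))
        data[0, 0, 0] = 0.0
        f = sp.spectral_phasor(sp.SpectralImage(data, axis32))
        assert f.null_mask[0, 0, 0]
        assert not f.null_mask[0, 1, 1]
        assert f.g[0, 0, 0] == 0.0 and f.s[0, 0, 0] == 0.0

    def test_invalid_harmonic(self, random_cube):
        with pytest.raises(ValidationError):
            sp.spectral_phasor(random_cube, harmonic=4)


class TestDenoise:
    def test_zero_cycles_is_identity(self, random_cube):
        f = sp.spectral_phasor(random_cube)
        f0 = sp.phasor_denoise(f, cycles=0)
        assert np.array_equal(f0.g, f.g) and np.array_equal(f0.s, f.s)

    def test_single_outlier_removed(self, axis32):
        data = np.zeros((1, 7, 7, 32))
        data[..., 4] = 1.0  # constant spectrum everywhere
        data[0, 3, 3] = 0.0
        data[0, 3, 3, 20] = 1.0  # one outlier spectrum
        f = sp.spectral_phasor(sp.SpectralImage(data, axis32))
        d = sp.phasor_denoise(f, cycles=1, kernel=3)
        assert d.g[0, 3, 3] == pytest.approx(f.g[0, 0, 0])
        assert d.s[0, 3, 3] == pytest.approx(f.s[0, 0, 0])

    def test_variance_decreases_on_noisy_field(self, axis32, rng):
        data = rng.poisson(50, size=(1, 30, 30, 32)).astype(float) + 1.0
        f = sp.spectral_phasor(sp.SpectralImage(data, axis32))
        d = sp.phasor_denoise(f, cycles=1)
        assert d.g.var() < f.g.var()
        assert d.s.var() < f.s.var()

    def test_preserves_null_mask_and_intensity(self, axis32, rng):
        data = rng.random((1, 10, 10, 32))
        data[0, :3, :3] = 0.0
        f = sp.spectral_phasor(sp.SpectralImage(data, axis32))
        d = sp.phasor_denoise(f, cycles=2)
        assert np.array_equal(d.null_mask, f.null_mask)
        assert np.array_equal(d.intensity_sum, f.intensity_sum)
        assert np.all(d.g[d.null_mask] == 0)

    @pytest.mark.parametrize("kernel", [2, 4])
    def test_even_kernel_rejected(self, random_cube, kernel):
        f = sp.spectral_phasor(random_cube)
        with pytest.raises(ValidationError):
            sp.phasor_denoise(f, cycles=1, kernel=kernel)


class TestHistogram:
    def test_single_spectrum_occupies_one_bin(self):
        f = sp.spectral_phasor(delta_cube(3, shape=(1, 6, 6)))
        h = sp.phasor_histogram(f, n_bins=64)
        assert (h.counts > 0).sum() == 1
        assert h.counts.max() == 36

    def test_two_spectra_counts_match_region_sizes(self, axis32):
        data = np.zeros((1, 4, 6, 32))
        data[0, :, :2, 3] = 1.0
        data[0, :, 2:, 25] = 1.0
        f = sp.spectral_phasor(sp.SpectralImage(data, axis32))
        h = sp.phasor_histogram(f, n_bins=64)
        assert sorted(h.counts[h.counts > 0]) == [8, 16]

    def test_total_count_conserved(self, random_cube):
        f = sp.spectral_phasor(random_cube)
        h = sp.phasor_histogram(f, n_bins=32)
        assert h.total_count == (~f.null_mask).sum()

    def test_bin_indices_consistent_with_counts(self, random_cube):
        f = sp.spectral_phasor(random_cube)
        h = sp.phasor_histogram(f, n_bins=16)
        rebuilt = np.zeros_like(h.counts)
        for ig, is_ in zip(h.bin_index_g.ravel(), h.bin_index_s.ravel()):
            if ig >= 0:
                rebuilt[ig, is_] += 1
        assert np.array_equal(rebuilt, h.counts)


class TestToPolar:
    @pytest.mark.parametrize(
        "g,s,r,theta",
        [
            (1, 0, 1, 0),
            (0, -1, 1, 3 * np.pi / 2),
            (-0.3, 0.4, 0.5, np.pi - np.arctan(4 / 3)),
            (0, 0, 0, 0),
        ],
    )
    def test_known_points(self, g, s, r, theta):
        rr, tt = sp.to_polar(g, s)
        assert rr == pytest.approx(r)
        assert tt == pytest.approx(theta)

    def test_theta_range(self, rng):
        g, s = rng.normal(size=(2, 100))
        _, theta = sp.to_polar(g, s)
        assert np.all((theta >= 0) & (theta < 2 * np.pi))
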