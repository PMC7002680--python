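import numpy as np
import pytest

import seerpy as sp
from seerpy.modes import MODES, BoundingBox

from conftest import delta_cube


def hist_from_points(points, counts=None, n_bins=5):
    """Histogram with occupied bins at given (g, s) coordinates (which must
    coincide with bin centers for the chosen n_bins)."""
    c = np.zeros((n_bins, n_bins), dtype=np.int64)
    edges = np.linspace(-1, 1, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = counts or [1] * len(points)
    for (g, s), k in zip(points, counts):
        i = int(np.argmin(np.abs(centers - g)))
        j = int(np.argmin(np.abs(centers - s)))
        assert centers[i] == pytest.approx(g) and centers[j] == pytest.approx(s)
        c[i, j] = k
    zero = np.zeros((1, 1, 1), dtype=np.int64)
    return sp.PhasorHistogram(counts=c, bin_edges=edges, bin_index_g=zero, bin_index_s=zero)


class TestApex:
    def test_single_bin_both_methods(self):
        hist = hist_from_points([(0.4, 0.4)])
        for method in ("max", "mass"):
            apex = sp.compute_apex(hist, method)
            assert (apex.g, apex.s) == (pytest.approx(0.4), pytest.approx(0.4))

    def test_mass_apex_weighted_mean(self):
        hist = hist_from_points([(0.0, 0.4), (0.4, 0.0)], counts=[3, 1])
        apex = sp.compute_apex(hist, "mass")
        assert apex.g == pytest.approx(0.1)
        assert apex.s == pytest.approx(0.3)

    def test_symmetric_histogram_mass_apex_at_origin(self):
        hist = hist_from_points([(0.4, 0.4), (-0.4, -0.4)])
        apex = sp.compute_apex(hist, "mass")
        assert abs(apex.g) < 1e-12 and abs(apex.s) < 1e-12

    def test_empty_histogram_rejected(self):
        hist = hist_from_points([])
        with pytest.raises(sp.ValidationError):
            sp.compute_apex(hist)

    def test_apex_outside_circle_rejected(self):
        with pytest.raises(sp.ValidationError):
            sp.ApexPoint(0.8, 0.8)


class TestScaleTransform:
    def test_unit_square_box_is_identity(self, rng):
        box = BoundingBox(-1, 1, -1, 1)
        g, s = rng.uniform(-1, 1, size=(2, 50))
        go, so = sp.scale_transform(g, s, box)
        assert np.allclose(go, g) and np.allclose(so, s)

    def test_ellipse_boundary_maps_to_unit_circle(self):
        box = BoundingBox(-0.5, 0.5, -0.5, 0.5)
        theta = np.linspace(0, 2 * np.pi, 40)
        go, so = sp.scale_transform(0.5 * np.cos(theta), 0.5 * np.sin(theta), box)
        assert np.allclose(np.hypot(go, so), 1.0)

    def test_off_center_box_boundary(self):
        box = BoundingBox(0.1, 0.5, -0.3, 0.3)
        a, b = box.semi_axes
        cg, cs = box.center
        theta = np.linspace(0, 2 * np.pi, 25)
        go, so = sp.scale_transform(cg + a * np.cos(theta), cs + b * np.sin(theta), box)
        assert np.allclose(np.hypot(go, so), 1.0)

    def test_origin_fixed_for_centered_box(self):
        go, so = sp.scale_transform(0.0, 0.0, BoundingBox(-0.5, 0.5, -0.5, 0.5))
        assert go == 0 and so == 0

    def test_degenerate_box_rejected(self):
        with pytest.raises(sp.ValidationError):
            sp.scale_transform(0.1, 0.1, BoundingBox(0.2, 0.2, -0.5, 0.5))


class TestBoundingBox:
    def test_covering_ellipse_contains_all_occupied_bins(self, random_cube):
        f = sp.spectral_phasor(random_cube)
        h = sp.phasor_histogram(f, n_bins=64)
        box = BoundingBox.from_histogram(h)
        centers = h.bin_centers
        gg, ss = np.meshgrid(centers, centers, indexing="ij")
        go, so = sp.scale_transform(gg[h.counts > 0], ss[h.counts > 0], box)
        assert np.all(np.hypot(go, so) <= 1.0 + 1e-9)

    def test_tight_box_hugs_occupied_bins(self):
        hist = hist_from_points([(-0.4, 0.0), (0.4, 0.4)])
        box = BoundingBox.from_histogram(hist, cover="box")
        assert box.gmin == pytest.approx(-0.4) and box.gmax == pytest.approx(0.4)
        assert box.smin == pytest.approx(0.0) and box.smax == pytest.approx(0.4)


class TestMorphTransform:
    def test_zero_apex_is_identity(self, rng):
        apex = sp.ApexPoint(0.0, 0.0)
        theta = rng.uniform(0, 2 * np.pi, 100)
        r = np.sqrt(rng.uniform(0, 1, 100))
        g, s = r * np.cos(theta), r * np.sin(theta)
        go, so = sp.morph_transform(g, s, apex)
        assert np.abs(go - g).max() < 1e-9
        assert np.abs(so - s).max() < 1e-9

    @pytest.mark.parametrize("apex", [(0.3, 0.0), (-0.2, 0.4), (0.0, -0.6)])
    def test_unit_circle_points_are_fixed(self, apex):
        apex = sp.ApexPoint(*apex)
        theta = np.linspace(0, 2 * np.pi, 60)
        g, s = np.cos(theta), np.sin(theta)
        go, so = sp.morph_transform(g, s, apex)
        assert np.abs(go - g).max() < 1e-9
        assert np.abs(so - s).max() < 1e-9

    def test_point_at_apex_maps_to_origin(self):
        go, so = sp.morph_transform(0.3, 0.0, sp.ApexPoint(0.3, 0.0))
        assert go == 0.0 and so == 0.0

    def test_alpha_satisfies_cone_identity(self, rng):
        """Output point lies on the shrunken circle: |p − αA| = 1 − α with
        α recovered from the output radius direction."""
        apex = sp.ApexPoint(0.25, -0.35)
        g, s = rng.uniform(-0.6, 0.6, size=(2, 50))
        go, so = sp.morph_transform(g, s, apex)
        alpha_g = (g - go) / apex.g
        alpha_s = (s - so) / apex.s
        assert np.allclose(alpha_g, alpha_s, atol=1e-9)  # shift along the apex direction
        assert np.allclose(np.hypot(go, so), 1 - alpha_g, atol=1e-9)


class TestBuildLut:
    def _hist(self, cube):
        f = sp.spectral_phasor(cube)
        return f, sp.phasor_histogram(f, n_bins=64)

    def test_standard_lut_dataset_independent(self, random_cube):
        _, h1 = self._hist(random_cube)
        _, h2 = self._hist(delta_cube(5, shape=(1, 6, 6)))
        lut1 = sp.build_lut("gradient_descent", "standard", h1)
        lut2 = sp.build_lut("gradient_descent", "standard", h2)
        assert np.array_equal(lut1.rgb, lut2.rgb)

    def test_scale_mode_spreads_hues(self, axis32, rng):
        """A small off-center cluster covers a wider hue range under scale
        mode than under the standard map."""
        from matplotlib.colors import rgb_to_hsv

        base = rng.random(32) + 0.1
        data = np.stack([base * (1 + 0.25 * rng.random(32)) for _ in range(64)])
        cube = sp.SpectralImage(data.reshape(1, 8, 8, 32), axis32)
        f, h = self._hist(cube)
        occupied = h.counts > 0
        def hue_spread(lut):
            hues = rgb_to_hsv(np.clip(lut.rgb[occupied], 0, 1))[:, 0]
            angles = hues * 2 * np.pi
            # circular variance
            return 1 - np.abs(np.exp(1j * angles).mean())
        spread_std = hue_spread(sp.build_lut("angular", "standard", h))
        spread_scale = hue_spread(sp.build_lut("angular", "scale", h))
        assert spread_scale > spread_std

    def test_morph_mass_symmetric_equals_standard(self):
        hist = hist_from_points([(0.4, 0.4), (-0.4, -0.4)])
        lut_m = sp.build_lut("gradient_descent", "morph_mass", hist)
        lut_s = sp.build_lut("gradient_descent", "standard", hist)
        assert np.allclose(lut_m.rgb, lut_s.rgb, atol=1e-9)

    def test_standard_mode_occupied_bins_colored(self, random_cube):
        f, h = self._hist(random_cube)
        lut = sp.build_lut("gradient_descent", "standard", h)
        occupied_colors = lut.rgb[h.counts > 0]
        assert np.all(occupied_colors.sum(axis=1) > 0)

    @pytest.mark.parametrize("mode", ["morph_max", "morph_mass"])
    def test_morph_on_empty_histogram_rejected(self, mode):
        hist = hist_from_points([])
        with pytest.raises(sp.ValidationError):
            sp.build_lut("gradient_descent", mode, hist)

    def test_modes_registry(self):
        assert MODES == ("standard", "scale", "morph_max", "morph_mass")
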