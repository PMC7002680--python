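"""Dataset-adaptive contrast modes and the phasor→RGB lookup table.

The standard reference maps span the whole unit disc, but real phasor
clusters occupy a small patch of it, so most of the color range goes
unused. Two adaptive modes re-spread the map over the data:

* **Scale mode** — spectral contrast stretching. The bounding box
  (width ω, height h) of the occupied phasor bins defines the largest
  inscribed ellipse (semi-axes a = ω/2, b = h/2); the reference map's unit
  circle is warped onto that ellipse, i.e. a data point is translated by
  the box center and divided by (a, b) before color lookup, so the ellipse
  boundary picks up the map-edge colors.

* **Morph mode** — shifted-cone apex displacement. The map is read as the
  top view of a unit-height cone with apex over the origin; the apex is
  shifted to a data-derived point A (the histogram maximum for *max morph*,
  the count-weighted centroid for *mass morph*) while the unit circle stays
  anchored. Each horizontal cut of the oblique cone is a circle of radius
  (1 − α) centered at α·A, so a data point p is assigned the α solving

      (p − α·A)·(p − α·A) = (1 − α)²,

  and looked up at p − α·A. With A at the origin the standard map is
  recovered exactly.

Modes are exclusive (not composed). ``build_lut`` bakes one map + one mode
into a per-histogram-bin RGB table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ValidationError
from .maps import STANDARD_MAPS, standard_map_color
from .phasor import PhasorHistogram, to_polar

MODES = ("standard", "scale", "morph_max", "morph_mass")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned bounding box of the occupied phasor bins."""

    gmin: float
    gmax: float
    smin: float
    smax: float

    @property
    def width(self) -> float:
        return self.gmax - self.gmin

    @property
    def height(self) -> float:
        return self.smax - self.smin

    @property
    def semi_axes(self) -> tuple[float, float]:
        return self.width / 2.0, self.height / 2.0

    @property
    def center(self) -> tuple[float, float]:
        return (self.gmin + self.gmax) / 2.0, (self.smin + self.smax) / 2.0

    def inflate(self, factor: float) -> "BoundingBox":
        """Scale the box about its center."""
        cg, cs = self.center
        a, b = self.semi_axes
        return BoundingBox(
            gmin=cg - a * factor, gmax=cg + a * factor,
            smin=cs - b * factor, smax=cs + b * factor,
        )

    @classmethod
    def from_histogram(
        cls,
        hist: PhasorHistogram,
        trim_percentile: float = 0.0,
        cover: str = "ellipse",
    ) -> "BoundingBox":
        """Box around bins with count > 0; ``trim_percentile`` optionally
        drops that percentage of total counts from each marginal tail to
        guard against single-bin outliers.

        With ``cover="ellipse"`` (default) the tight box is inflated by √2
        about its center so its inscribed ellipse passes through the tight
        box's corners: every occupied bin is then guaranteed a color. A
        hand-drawn box around a cluster encloses it with margin for the same
        reason; the tight data box itself (``cover="box"``) leaves anything
        near its corners outside the ellipse and therefore black."""
        if hist.total_count == 0:
            raise ValidationError("cannot bound an empty histogram")
        centers = hist.bin_centers
        occ_g = hist.counts.sum(axis=1)
        occ_s = hist.counts.sum(axis=0)

        def _bounds(marginal: np.ndarray) -> tuple[float, float]:
            if trim_percentile > 0:
                cum = np.cumsum(marginal) / marginal.sum()
                lo = np.searchsorted(cum, trim_percentile / 100.0)
                hi = np.searchsorted(cum, 1.0 - trim_percentile / 100.0)
                hi = max(hi, lo)
                return centers[lo], centers[min(hi, len(centers) - 1)]
            idx = np.nonzero(marginal)[0]
            return centers[idx[0]], centers[idx[-1]]

        gmin, gmax = _bounds(occ_g)
        smin, smax = _bounds(occ_s)
        if cover not in ("ellipse", "box"):
            raise ValidationError(f"cover must be 'ellipse' or 'box', got {cover!r}")
        box = cls(gmin=gmin, gmax=gmax, smin=smin, smax=smax)
        return box.inflate(np.sqrt(2.0)) if cover == "ellipse" else box


@dataclass(frozen=True)
class ApexPoint:
    """Shifted apex A of the morph-mode cone; must lie inside the unit circle."""

    g: float
    s: float

    def __post_init__(self) -> None:
        if self.g**2 + self.s**2 >= 1.0:
            raise ValidationError(f"apex ({self.g}, {self.s}) must lie inside the unit circle")


def compute_apex(hist: PhasorHistogram, method: str = "mass") -> ApexPoint:
    """Apex for morph mode: bin center of the highest-count bin (``max``) or
    the count-weighted centroid of the histogram (``mass``)."""
    if hist.total_count == 0:
        raise ValidationError("cannot compute an apex from an empty histogram")
    centers = hist.bin_centers
    if method == "max":
        i, j = np.unravel_index(np.argmax(hist.counts), hist.counts.shape)
        return ApexPoint(g=float(centers[i]), s=float(centers[j]))
    if method == "mass":
        F = hist.counts.astype(np.float64)
        total = F.sum()
        g = float((F.sum(axis=1) * centers).sum() / total)
        s = float((F.sum(axis=0) * centers).sum() / total)
        return ApexPoint(g=g, s=s)
    raise ValidationError(f"unknown apex method {method!r}; use 'max' or 'mass'")


def scale_transform(g, s, box: BoundingBox):
    """Map data coordinates into the reference frame whose unit circle is
    the box's inscribed ellipse: translate by the box center, divide by the
    semi-axes. Points on the ellipse boundary come out at radius 1."""
    a, b = box.semi_axes
    if a <= 0 or b <= 0:
        raise ValidationError(f"degenerate bounding box (a={a}, b={b})")
    cg, cs = box.center
    g = np.asarray(g, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    return (g - cg) / a, (s - cs) / b


def morph_transform(g, s, apex: ApexPoint):
    """Shifted-cone warp: returns the lookup coordinates p − α·A with α the
    root in [0, 1) of (p − α·A)² = (1 − α)².

    Unit-circle points are fixed (α = 0); apex (0, 0) gives the identity; a
    point exactly at the apex maps to the map origin. Points outside the
    unit disc are passed through unchanged (they render black downstream).
    """
    g = np.asarray(g, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    g, s = np.broadcast_arrays(g, s)
    ga, sa = apex.g, apex.s
    r2 = g**2 + s**2
    outside = r2 > 1.0 + 1e-12
    at_apex = (np.abs(g - ga) < 1e-12) & (np.abs(s - sa) < 1e-12)

    # quadratic A·α² + B·α + C = 0 from the cutting-plane identity
    A = ga**2 + sa**2 - 1.0  # < 0 since |apex| < 1
    B = 2.0 * (1.0 - g * ga - s * sa)
    C = r2 - 1.0
    disc = np.maximum(B**2 - 4.0 * A * C, 0.0)
    sq = np.sqrt(disc)
    r1 = (-B + sq) / (2.0 * A)
    r2_ = (-B - sq) / (2.0 * A)
    roots = np.stack([r1, r2_])
    in_range = (roots >= 0.0) & (roots < 1.0)
    # prefer the smaller admissible root (closest to the standard map)
    roots_masked = np.where(in_range, roots, np.inf)
    alpha = roots_masked.min(axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)

    go = g - alpha * ga
    so = s - alpha * sa
    go = np.where(at_apex, 0.0, go)
    so = np.where(at_apex, 0.0, so)
    go = np.where(outside, g, go)
    so = np.where(outside, s, so)
    return go, so


@dataclass
class ColorLUT:
    """Bin-indexed phasor→RGB table encoding one reference map + one mode."""

    rgb: np.ndarray  # (n_bins, n_bins, 3)
    map_name: str
    mode: str
    box: BoundingBox | None = None
    apex: ApexPoint | None = None
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_bins = self.rgb.shape[0]


def build_lut(
    map_name: str,
    mode: str,
    hist: PhasorHistogram,
    box: BoundingBox | None = None,
    apex: ApexPoint | None = None,
    trim_percentile: float = 0.0,
) -> ColorLUT:
    """Bake map + mode into an RGB color per histogram bin center.

    Mode parameters are auto-computed from the histogram (bounding box for
    scale, apex for morph) unless supplied explicitly, which allows holding
    the palette constant across samples. Standard mode ignores the data
    entirely, so its LUT is identical across datasets. Bins whose
    transformed coordinates fall outside the unit circle are black.
    """
    if map_name not in STANDARD_MAPS:
        raise ValidationError(f"unknown map {map_name!r}")
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; choose from {MODES}")
    centers = hist.bin_centers
    gg, ss = np.meshgrid(centers, centers, indexing="ij")
    if mode == "standard":
        go, so = gg, ss
    elif mode == "scale":
        if box is None:
            box = BoundingBox.from_histogram(hist, trim_percentile=trim_percentile)
        go, so = scale_transform(gg, ss, box)
    else:
        if apex is None:
            apex = compute_apex(hist, method="max" if mode == "morph_max" else "mass")
        go, so = morph_transform(gg, ss, apex)
    r, theta = to_polar(go, so)
    rgb = standard_map_color(r, theta, map_name)
    return ColorLUT(rgb=rgb, map_name=map_name, mode=mode, box=box, apex=apex)
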