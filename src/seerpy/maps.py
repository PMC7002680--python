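"""Standard reference maps and the tensor (gradient-of-counts) map.

A reference map assigns a color to every phasor coordinate. The four
standard maps work in HSV on the polar form (r, θ) of the phasor:

=================  =========  ==========  =============
map                hue        saturation  value
=================  =========  ==========  =============
gradient_descent   θ / 2π     1           1 − 0.85·r
gradient_ascent    θ / 2π     1           r
angular            θ / 2π     1           1
radial             jet colormap lookup on r
=================  =========  ==========  =============

Hue tracks the phase angle, i.e. shifts in emission maximum; the two
gradient maps add a radial brightness ramp (descent bright at the center,
ascent dark at the center) that couples color to intensity/magnitude.
Any coordinate outside the r = 1 unit circle is rendered black.

The tensor map instead colors each image pixel by the normalized magnitude
D(g, s) of the 2D gradient of the phasor-histogram counts — a spectral edge
detector: rare spectral populations at the fringe of a phasor cluster get
colors far from the dense cluster core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .io import ValidationError
from .phasor import PhasorField, PhasorHistogram, to_polar

logger = logging.getLogger(__name__)

STANDARD_MAPS = ("gradient_descent", "gradient_ascent", "radial", "angular")

# Fixed piecewise-linear jet ramp so results do not depend on a plotting
# library's colormap revision.
_JET_STOPS = np.array([0.0, 0.125, 0.375, 0.625, 0.875, 1.0])
_JET_RGB = np.array(
    [
        [0.0, 0.0, 0.5],
        [0.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, 0.0, 0.0],
    ]
)

_warned_jet_clamp = False


def jet_lookup(v) -> np.ndarray:
    """Evaluate the fixed jet ramp at value(s) v ∈ [0, 1]; out-of-range
    input is clamped (logged once)."""
    global _warned_jet_clamp
    v = np.asarray(v, dtype=np.float64)
    if (np.any(v < 0) or np.any(v > 1)) and not _warned_jet_clamp:
        logger.warning("jet_lookup: values outside [0, 1] clamped")
        _warned_jet_clamp = True
    v = np.clip(v, 0.0, 1.0)
    out = np.stack([np.interp(v, _JET_STOPS, _JET_RGB[:, c]) for c in range(3)], axis=-1)
    return out


def standard_map_color(r, theta, map_name: str) -> np.ndarray:
    """RGB color(s) for polar phasor coordinates under a standard map.

    Accepts scalars or arrays; returns RGB in [0, 1] with trailing axis 3.
    Coordinates with r > 1 come back black.
    """
    if map_name not in STANDARD_MAPS:
        raise ValidationError(f"unknown map {map_name!r}; choose from {STANDARD_MAPS}")
    r = np.asarray(r, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    r, theta = np.broadcast_arrays(r, theta)
    hue = np.mod(theta / (2.0 * np.pi), 1.0)
    if map_name == "radial":
        rgb = jet_lookup(np.clip(r, 0.0, 1.0))
    else:
        if map_name == "gradient_descent":
            value = 1.0 - 0.85 * r
        elif map_name == "gradient_ascent":
            value = r
        else:  # angular
            value = np.ones_like(r)
        hsv = np.stack([hue, np.ones_like(hue), np.clip(value, 0.0, 1.0)], axis=-1)
        rgb = hsv_to_rgb(hsv)
    rgb = np.where((r > 1.0)[..., None], 0.0, rgb)
    return rgb


@dataclass
class GradientField:
    """Gradient-magnitude field of a phasor histogram.

    ``d`` holds D(g, s) = √((∂F/∂g)² + (∂F/∂s)²) per bin, normalized so the
    maximum is 1 whenever any gradient is nonzero; ``dF_dg`` / ``dF_ds`` are
    the raw finite differences (unit bin spacing).
    """

    d: np.ndarray
    dF_dg: np.ndarray
    dF_ds: np.ndarray
    spacing: float = 1.0


def tensor_gradient(hist: PhasorHistogram) -> GradientField:
    """Finite-difference gradient magnitude of the histogram counts.

    Second-order central differences in the interior; one-sided forward /
    backward differences on the boundary rows and columns where the central
    stencil is undefined. D is normalized to max 1.
    """
    F = hist.counts.astype(np.float64)
    if F.sum() == 0:
        logger.warning("tensor_gradient: empty histogram, zero field")
        zero = np.zeros_like(F)
        return GradientField(d=zero, dF_dg=zero.copy(), dF_ds=zero.copy())
    dg = np.empty_like(F)
    ds = np.empty_like(F)
    # axis 0 is g, axis 1 is s
    dg[1:-1, :] = (F[2:, :] - F[:-2, :]) / 2.0
    dg[0, :] = F[1, :] - F[0, :]
    dg[-1, :] = F[-1, :] - F[-2, :]
    ds[:, 1:-1] = (F[:, 2:] - F[:, :-2]) / 2.0
    ds[:, 0] = F[:, 1] - F[:, 0]
    ds[:, -1] = F[:, -1] - F[:, -2]
    d = np.sqrt(dg**2 + ds**2)
    dmax = d.max()
    if dmax > 0:
        d = d / dmax
    return GradientField(d=d, dF_dg=dg, dF_ds=ds)


def tensor_map_render(field: PhasorField, hist: PhasorHistogram,
                      grad: GradientField | None = None) -> np.ndarray:
    """Recolor the image by the gradient of phasor counts at each pixel's bin.

    Bins with equal D share one color (jet ramp on D), so iso-gradient
    contours of the phasor plot appear as single colors in the image. Null
    pixels are black. Returns an ``(z, y, x, 3)`` RGB array.
    """
    if grad is None:
        grad = tensor_gradient(hist)
    if grad.d.shape != hist.counts.shape:
        raise ValidationError("gradient field and histogram geometries differ")
    ig = np.clip(hist.bin_index_g, 0, hist.n_bins - 1)
    is_ = np.clip(hist.bin_index_s, 0, hist.n_bins - 1)
    rgb = jet_lookup(grad.d[ig, is_])
    rgb[field.null_mask] = 0.0
    return rgb


def map_legend(map_name: str, n: int = 256) -> np.ndarray:
    """Render a reference-map colorwheel legend (n × n RGB image over the
    [−1, 1]² phasor square; outside the unit circle black)."""
    coords = np.linspace(-1.0, 1.0, n)
    gg, ss = np.meshgrid(coords, coords, indexing="ij")
    r, theta = to_polar(gg, ss)
    return standard_map_color(r, theta, map_name)
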