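"""Final RGB renderings: LUT application plus baseline visualizations.

The baselines are the conventional compressions a hyperspectral rendering
is judged against:

* ``truecolor_gaussian`` — weight each spectral channel by a Gaussian
  similarity kernel to fixed R/G/B center wavelengths and sum.
* ``adaptive_centers`` — re-center those kernels on the dataset's own
  average spectrum (blue/red at the fractional-intensity crossings, green
  halfway between).
* ``peak_wavelength_rgb`` — paint each pixel with the visible-spectrum
  color of its brightest channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import SpectralImage, ValidationError
from .modes import ColorLUT
from .phasor import PhasorField, PhasorHistogram

logger = logging.getLogger(__name__)

#: Default Gaussian kernel centers (nm) for the R, G, B channels.
DEFAULT_CENTERS = (650.0, 510.0, 470.0)
#: Default kernel width (nm); covers ~5-6 channels of the 8.9 nm detector.
DEFAULT_SIGMA = 50.0

NTSC_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class KernelCenters:
    """Gaussian-kernel center wavelengths (nm) for the R, G, B channels and
    the shared deviation parameter σ (nm)."""

    red: float = DEFAULT_CENTERS[0]
    green: float = DEFAULT_CENTERS[1]
    blue: float = DEFAULT_CENTERS[2]
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")


def apply_lut(field: PhasorField, hist: PhasorHistogram, lut: ColorLUT,
              intensity_mode: str = "scaled") -> np.ndarray:
    """Color the image through a phasor LUT.

    ``intensity_mode="flat"`` returns the pure RGB color mask (each pixel
    exactly its bin's LUT color); ``"scaled"`` multiplies by the pixel's
    integrated intensity normalized to the image maximum, trading color
    purity for structural brightness. Null pixels are black either way.
    """
    if lut.n_bins != hist.n_bins:
        raise ValidationError(
            f"LUT has {lut.n_bins} bins but histogram has {hist.n_bins}"
        )
    if intensity_mode not in ("flat", "scaled"):
        raise ValidationError(f"intensity_mode must be 'flat' or 'scaled', got {intensity_mode!r}")
    ig = np.clip(hist.bin_index_g, 0, hist.n_bins - 1)
    is_ = np.clip(hist.bin_index_s, 0, hist.n_bins - 1)
    rgb = lut.rgb[ig, is_].copy()
    if intensity_mode == "scaled":
        peak = field.intensity_sum.max()
        if peak > 0:
            rgb *= (field.intensity_sum / peak)[..., None]
    rgb[field.null_mask] = 0.0
    return rgb


def truecolor_gaussian(cube: SpectralImage, centers: KernelCenters | None = None) -> np.ndarray:
    """Gaussian-kernel TrueColor compression of a cube to RGB.

    Per output channel c with center wavelength x′ the kernel over spectral
    channels i is K_i = exp(−(λ_i − x′)²/(2σ²)), normalized to sum 1; the
    channel value is the dot product of the pixel spectrum with K. The
    result is normalized by the global maximum into [0, 1] (linear in the
    spectrum up to that final scaling).
    """
    if centers is None:
        centers = KernelCenters()
    lam = cube.axis.centers
    rgb_centers = (centers.red, centers.green, centers.blue)
    out = np.zeros(cube.data.shape[:-1] + (3,), dtype=np.float64)
    for c, x0 in enumerate(rgb_centers):
        k = np.exp(-((lam - x0) ** 2) / (2.0 * centers.sigma**2))
        ksum = k.sum()
        if ksum > 0:
            k = k / ksum
        out[..., c] = cube.data @ k
    peak = out.max()
    if peak > 0:
        out /= peak
    return np.clip(out, 0.0, 1.0)


def adaptive_centers(cube: SpectralImage, fraction: float = 0.10,
                     sigma: float = DEFAULT_SIGMA) -> KernelCenters:
    """Re-center the TrueColor kernels on the dataset's average spectrum.

    The mean spectrum is normalized to max 1; the blue and red centers are
    the leftmost and rightmost wavelengths where it crosses ``fraction``
    (linear interpolation between channels), and green sits halfway
    between. If the spectrum never crosses, the axis endpoints are used and
    a warning logged.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    lam = cube.axis.centers
    mean = cube.data.reshape(-1, cube.n_channels).mean(axis=0)
    peak = mean.max()
    if peak <= 0:
        logger.warning("adaptive_centers: empty cube; falling back to axis endpoints")
        blue, red = lam[0], lam[-1]
        return KernelCenters(red=red, green=(red + blue) / 2, blue=blue, sigma=sigma)
    mean = mean / peak
    above = mean >= fraction
    if not above.any():
        logger.warning("adaptive_centers: spectrum never reaches %.2f; using endpoints", fraction)
        blue, red = lam[0], lam[-1]
    else:
        first = int(np.argmax(above))
        last = len(above) - 1 - int(np.argmax(above[::-1]))
        if first == 0:
            blue = lam[0]
        else:  # interpolate the upward crossing between first-1 and first
            y0, y1 = mean[first - 1], mean[first]
            blue = lam[first - 1] + (fraction - y0) / (y1 - y0) * (lam[first] - lam[first - 1])
        if last == len(lam) - 1:
            red = lam[-1]
        else:  # downward crossing between last and last+1
            y0, y1 = mean[last], mean[last + 1]
            red = lam[last] + (y0 - fraction) / (y0 - y1) * (lam[last + 1] - lam[last])
    return KernelCenters(red=float(red), green=float((red + blue) / 2.0),
                         blue=float(blue), sigma=sigma)


def wavelength_to_rgb(wavelength: float) -> tuple[float, float, float]:
    """Classical piecewise-linear visible-spectrum color of a wavelength (nm).

    Segments: 380–440 violet ramp, 440–490 blue→cyan, 490–510 cyan→green,
    510–580 green→yellow, 580–645 yellow→red, 645–780 red, with linear
    intensity falloff below 420 nm and above 700 nm; black outside 380–780.
    """
    w = float(wavelength)
    if w < 380.0 or w > 780.0:
        return (0.0, 0.0, 0.0)
    if w < 440.0:
        r, g, b = -(w - 440.0) / 60.0, 0.0, 1.0
    elif w < 490.0:
        r, g, b = 0.0, (w - 440.0) / 50.0, 1.0
    elif w < 510.0:
        r, g, b = 0.0, 1.0, -(w - 510.0) / 20.0
    elif w < 580.0:
        r, g, b = (w - 510.0) / 70.0, 1.0, 0.0
    elif w < 645.0:
        r, g, b = 1.0, -(w - 645.0) / 65.0, 0.0
    else:
        r, g, b = 1.0, 0.0, 0.0
    if w < 420.0:
        factor = 0.3 + 0.7 * (w - 380.0) / 40.0
    elif w > 700.0:
        factor = 0.3 + 0.7 * (780.0 - w) / 80.0
    else:
        factor = 1.0
    return (r * factor, g * factor, b * factor)


def peak_wavelength_rgb(cube: SpectralImage) -> np.ndarray:
    """Color each pixel by the visible-spectrum color of its argmax channel.

    Ties break toward the lowest wavelength; zero pixels are black. The
    result is invariant to per-pixel intensity scaling by construction.
    """
    palette = np.array([wavelength_to_rgb(w) for w in cube.axis.centers])
    idx = np.argmax(cube.data, axis=-1)  # first max → lowest wavelength
    rgb = palette[idx]
    rgb[cube.data.sum(axis=-1) <= 0] = 0.0
    return rgb


def truecolor_32ch(cube: SpectralImage, excitation_cutoff: float | None = None,
                   top_fraction: float | None = None) -> np.ndarray:
    """Wavelength-to-RGB weighted channel sum (32-channel TrueColor style).

    Optional channel-exclusion rules: drop channels below the excitation
    line (``excitation_cutoff`` in nm, for 1-photon data) and keep only
    channels within the top ``top_fraction`` of the normalized average
    spectrum. Both default to off.
    """
    lam = cube.axis.centers
    keep = np.ones(cube.n_channels, dtype=bool)
    if excitation_cutoff is not None:
        keep &= lam >= excitation_cutoff
    if top_fraction is not None:
        mean = cube.data.reshape(-1, cube.n_channels).mean(axis=0)
        if mean.max() > 0:
            keep &= mean / mean.max() >= (1.0 - top_fraction)
    if not keep.any():
        raise ValidationError("channel-exclusion rules removed every channel")
    palette = np.array([wavelength_to_rgb(w) for w in lam])
    data = cube.data[..., keep]
    out = np.tensordot(data, palette[keep], axes=([-1], [0]))
    peak = out.max()
    if peak > 0:
        out /= peak
    return np.clip(out, 0.0, 1.0)


def mip(volume: np.ndarray) -> np.ndarray:
    """Luminance maximum-intensity projection of a (z, y, x, 3) RGB stack:
    each output pixel is the full RGB triple of the z-plane with maximal
    NTSC luminance, so projected colors stay physically co-located."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim == 3:
        volume = volume[None]
    if volume.ndim != 4 or volume.shape[-1] != 3:
        raise ValidationError(f"expected (z, y, x, 3) stack, got shape {volume.shape}")
    lr, lg, lb = NTSC_WEIGHTS
    lum = lr * volume[..., 0] + lg * volume[..., 1] + lb * volume[..., 2]
    zbest = np.argmax(lum, axis=0)
    yy, xx = np.meshgrid(
        np.arange(volume.shape[1]), np.arange(volume.shape[2]), indexing="ij"
    )
    return volume[zbest, yy, xx]
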