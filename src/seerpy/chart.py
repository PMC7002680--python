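"""Simulated Hyperspectral Test Chart (SHTC) and noise model.

The chart emulates a specimen carrying three fluorophores with overlapping
emission: a 3×3 grid of cells, each cell drawn as three concentric square
regions (outer ring, middle ring, center square) filled with three spectra
S1, S2, S3. S1 and S3 are shifted by d1 and d2 nanometers relative to S2,
so the chart presents a controlled gradient of spectral overlap; the center
cell always carries the unshifted base spectra.

Because the acquired CFP/YFP/RFP emission spectra are not tabulated, the
generator uses Gaussian surrogates peaked at 475, 527 and 580 nm (σ 15 nm)
by default — CFP-, YFP- and RFP-like — with every parameter exposed.
Shot noise is modelled as Poisson counts at a chosen photon scale plus
additive zero-mean Gaussian detector read noise, clipped at zero. Real
detector spectral response curves and bleed-through are deliberately not
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import SpectralImage, ValidationError, WavelengthAxis, make_wavelength_axis

#: shift steps (nm) matching one to four channel bandwidths of the default axis
SHIFT_STEPS = (0.0, 8.9, 17.8, 26.7, 35.6)


@dataclass(frozen=True)
class SpectrumModel:
    """Gaussian surrogate emission spectrum: peak center (nm), width σ (nm),
    peak amplitude (photons at the maximum)."""

    peak: float
    width: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"width must be positive, got {self.width}")
        if self.amplitude < 0:
            raise ValidationError(f"amplitude must be nonnegative, got {self.amplitude}")


#: default CFP-, YFP- and RFP-like surrogates
DEFAULT_SPECTRA = (
    SpectrumModel(peak=475.0, width=15.0),
    SpectrumModel(peak=527.0, width=15.0),
    SpectrumModel(peak=580.0, width=15.0),
)


def gaussian_spectrum(model: SpectrumModel, axis: WavelengthAxis) -> np.ndarray:
    """Sample a Gaussian spectrum at the axis channel wavelengths."""
    lam = axis.centers
    return model.amplitude * np.exp(-((lam - model.peak) ** 2) / (2.0 * model.width**2))


@dataclass(frozen=True)
class SHTCSpec:
    """Layout and spectra of the test chart.

    ``d1`` shifts S1 blue-ward and ``d2`` shifts S3 red-ward relative to
    their base peaks; each may be a scalar (uniform over cells) or a 3×3
    array (per cell). The center cell of the grid always carries the
    unshifted base spectra. Per 100×100 cell the outer ring is 25 px wide,
    the middle ring 15 px, leaving a 20×20 center square.
    """

    size: tuple[int, int] = (300, 300)
    grid: tuple[int, int] = (3, 3)
    d1: float | np.ndarray = 0.0
    d2: float | np.ndarray = 0.0
    spectra: tuple[SpectrumModel, SpectrumModel, SpectrumModel] = DEFAULT_SPECTRA
    ring_fractions: tuple[float, float] = (0.25, 0.15)

    def shift_grids(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.grid
        g1 = np.broadcast_to(np.asarray(self.d1, dtype=np.float64), (rows, cols)).copy()
        g2 = np.broadcast_to(np.asarray(self.d2, dtype=np.float64), (rows, cols)).copy()
        return g1, g2


def _region_slices(y0, x0, cell_h, cell_w, fractions):
    """Outer/middle/center mask slices for one cell."""
    f_outer, f_middle = fractions
    o_h, o_w = int(round(cell_h * f_outer)), int(round(cell_w * f_outer))
    m_h, m_w = int(round(cell_h * f_middle)), int(round(cell_w * f_middle))
    outer = (slice(y0, y0 + cell_h), slice(x0, x0 + cell_w))
    middle = (slice(y0 + o_h, y0 + cell_h - o_h), slice(x0 + o_w, x0 + cell_w - o_w))
    center = (
        slice(y0 + o_h + m_h, y0 + cell_h - o_h - m_h),
        slice(x0 + o_w + m_w, x0 + cell_w - o_w - m_w),
    )
    return outer, middle, center


def build_shtc(
    spec: SHTCSpec | None = None, axis: WavelengthAxis | None = None
) -> tuple[SpectralImage, dict[str, np.ndarray]]:
    """Build the noiseless test chart and its three region masks.

    Returns the cube (1, y, x, λ) and a dict of disjoint boolean masks
    ``{"outer", "middle", "center"}`` over the full image, suitable as the
    region triple for separation-accuracy scoring. The outer rings carry
    S1 (shifted −d1), the middle rings S2, the center squares S3
    (shifted +d2); the grid's center cell carries the unshifted spectra.
    """
    spec = spec or SHTCSpec()
    axis = axis or make_wavelength_axis()
    height, width = spec.size
    rows, cols = spec.grid
    cell_h, cell_w = height // rows, width // cols
    g1, g2 = spec.shift_grids()
    s1, s2, s3 = spec.spectra

    lo, hi = axis.centers[0], axis.centers[-1]
    for name, model, shifts, sign in (("S1", s1, g1, -1.0), ("S3", s3, g2, +1.0)):
        peaks = model.peak + sign * shifts
        if peaks.min() < lo or peaks.max() > hi:
            raise ValidationError(
                f"{name} shifts push the peak outside the wavelength axis "
                f"({lo:.1f}-{hi:.1f} nm)"
            )

    cube = np.zeros((1, height, width, axis.n_channels), dtype=np.float64)
    masks = {
        name: np.zeros((1, height, width), dtype=bool)
        for name in ("outer", "middle", "center")
    }
    center_cell = (rows // 2, cols // 2)
    base_s2 = gaussian_spectrum(s2, axis)
    for i in range(rows):
        for j in range(cols):
            if (i, j) == center_cell:
                sp1 = gaussian_spectrum(s1, axis)
                sp3 = gaussian_spectrum(s3, axis)
            else:
                sp1 = gaussian_spectrum(replace(s1, peak=s1.peak - g1[i, j]), axis)
                sp3 = gaussian_spectrum(replace(s3, peak=s3.peak + g2[i, j]), axis)
            outer, middle, center = _region_slices(
                i * cell_h, j * cell_w, cell_h, cell_w, spec.ring_fractions
            )
            cube[0][outer] = sp1
            cube[0][middle] = base_s2
            cube[0][center] = sp3
            masks["outer"][0][outer] = True
            masks["middle"][0][middle] = True
            masks["center"][0][center] = True
    # differencing: outer excludes middle, middle excludes center
    masks["outer"] &= ~masks["middle"]
    masks["middle"] &= ~masks["center"]
    return SpectralImage(data=cube, axis=axis), masks


def overlap_chart(
    separations: tuple[float, float],
    base: SpectrumModel = DEFAULT_SPECTRA[1],
    axis: WavelengthAxis | None = None,
    size: tuple[int, int] = (300, 300),
) -> tuple[SpectralImage, dict[str, np.ndarray]]:
    """Chart whose three spectra all derive from one base peak, for
    controlled-overlap experiments: S1 = base − separations[0] nm,
    S2 = base, S3 = base + separations[1] nm, in every cell."""
    d1, d2 = separations
    spec = SHTCSpec(
        size=size,
        d1=np.full((3, 3), d1),
        d2=np.full((3, 3), d2),
        spectra=(base, base, base),
    )
    # shift the center cell too: use explicit per-cell spectra by rebuilding
    cube, masks = build_shtc(spec, axis)
    # build_shtc leaves the center cell unshifted; overwrite it for uniformity
    axis = axis or make_wavelength_axis()
    height, width = size
    cell_h, cell_w = height // 3, width // 3
    outer, middle, center = _region_slices(cell_h, cell_w, cell_h, cell_w, spec.ring_fractions)
    cube.data[0][outer] = gaussian_spectrum(replace(base, peak=base.peak - d1), axis)
    cube.data[0][middle] = gaussian_spectrum(base, axis)
    cube.data[0][center] = gaussian_spectrum(replace(base, peak=base.peak + d2), axis)
    return cube, masks


def add_noise(
    cube: SpectralImage,
    photon_scale: float = 100.0,
    read_sigma: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> SpectralImage:
    """Add Poisson shot noise and Gaussian detector read noise to a cube.

    The cube is normalized to its maximum and scaled so the brightest
    spectral sample expects ``photon_scale`` photons; per channel a Poisson
    count is drawn and zero-mean Gaussian read noise (sd ``read_sigma``)
    added, then clipped at zero. A seed (or Generator) is mandatory so every
    noisy cube is reproducible.
    """
    if photon_scale <= 0:
        raise ValidationError(f"photon_scale must be positive, got {photon_scale}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peak = cube.data.max()
    expected = photon_scale * (cube.data / peak if peak > 0 else cube.data)
    noisy = rng.poisson(expected).astype(np.float64)
    if read_sigma > 0:
        noisy += rng.normal(0.0, read_sigma, size=noisy.shape)
    return SpectralImage(data=np.clip(noisy, 0.0, None), axis=cube.axis)
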