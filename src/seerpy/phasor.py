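"""Spectral phasor transform, phasor-space denoising and the 2D histogram.

Each pixel spectrum I(λ) is compressed to a single point on the phasor
plane: the pair (g, s) of its intensity-normalized cosine and sine Fourier
coefficients at harmonic k,

    g = Σ_c I_c · cos(2πkc/N) · Δλ / Σ_c I_c · Δλ
    s = Σ_c I_c · sin(2πkc/N) · Δλ / Σ_c I_c · Δλ

with c = 0…N−1 the spectral channel index. The transform is linear in the
spectrum: a mixture of two spectra lands on the segment joining the two pure
phasors, at the intensity-weighted position. Nonnegative spectra always land
inside the unit disc. All pixels of an image plotted together form the
phasor plot, stored here as a 2D histogram of counts over [−1, 1]².

Denoising is done *in phasor space*: median filters applied to the g and s
images reduce the spread of phasor clusters without touching intensities or
moving pixels, so the operation is spatially lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .io import SpectralImage, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_HARMONIC = 2
DEFAULT_N_BINS = 256


@dataclass
class PhasorField:
    """Per-voxel phasor coordinates of a cube.

    ``g``, ``s`` and ``intensity_sum`` all have the cube's spatial shape
    ``(z, y, x)``. Voxels with zero integrated intensity have no defined
    phasor; they carry the sentinel (0, 0) and are flagged in ``null_mask``.
    """

    g: np.ndarray
    s: np.ndarray
    intensity_sum: np.ndarray
    harmonic: int
    null_mask: np.ndarray

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.g.shape


@dataclass
class PhasorHistogram:
    """2D histogram F(g, s) of phasor counts on an n_bins × n_bins grid
    covering [−1, 1] × [−1, 1].

    ``counts[i, j]`` counts phasors with g in bin i and s in bin j.
    ``bin_index_g`` / ``bin_index_s`` store each voxel's bin (−1 for null
    voxels) so renderers can look colors up per pixel.
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    bin_index_g: np.ndarray
    bin_index_s: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")


def spectral_phasor(cube: SpectralImage, harmonic: int = DEFAULT_HARMONIC) -> PhasorField:
    """Fourier-transform every spectrum of a cube into phasor coordinates.

    Parameters
    ----------
    cube : SpectralImage
        Nonnegative intensity cube.
    harmonic : int
        Fourier harmonic k (1–3). Higher harmonics increase the angular
        dispersion of similar spectra; k = 2 is the working default.
    """
    if harmonic not in (1, 2, 3):
        raise ValidationError(f"harmonic must be 1, 2 or 3; got {harmonic}")
    data = cube.data
    n = cube.n_channels
    c = np.arange(n)
    arg = 2.0 * np.pi * harmonic * c / n
    dlam = cube.axis.bandwidth
    total = data.sum(axis=-1) * dlam
    null = total <= 0
    if null.all():
        logger.warning("all-zero cube: every voxel is null")
    denom = np.where(null, 1.0, total)
    g = (data @ np.cos(arg)) * dlam / denom
    s = (data @ np.sin(arg)) * dlam / denom
    g[null] = 0.0
    s[null] = 0.0
    return PhasorField(g=g, s=s, intensity_sum=total, harmonic=harmonic, null_mask=null)


def phasor_denoise(field: PhasorField, cycles: int = 1, kernel: int = 3) -> PhasorField:
    """Median-filter the g and s planes, per z-slice, ``cycles`` times.

    Filtering happens in phasor space only: intensities and pixel positions
    are untouched, and null voxels stay null. Edges are handled with
    reflective padding. ``cycles`` ranges 0–5 (0 is the identity); the
    kernel is an odd square size ≥ 3.
    """
    if not 0 <= cycles <= 5:
        raise ValidationError(f"cycles must be in 0…5, got {cycles}")
    if kernel % 2 == 0 or kernel < 3:
        raise ValidationError(f"kernel must be odd and ≥ 3, got {kernel}")
    if cycles == 0:
        return field
    g = field.g.copy()
    s = field.s.copy()
    for _ in range(cycles):
        for z in range(g.shape[0]):
            g[z] = median_filter(g[z], size=kernel, mode="reflect")
            s[z] = median_filter(s[z], size=kernel, mode="reflect")
    g[field.null_mask] = 0.0
    s[field.null_mask] = 0.0
    return PhasorField(
        g=g, s=s, intensity_sum=field.intensity_sum,
        harmonic=field.harmonic, null_mask=field.null_mask,
    )


def phasor_histogram(field: PhasorField, n_bins: int = DEFAULT_N_BINS) -> PhasorHistogram:
    """Bin the non-null phasors of a field on the [−1, 1]² grid.

    Each voxel's bin index is kept alongside the counts so a color lookup
    table indexed by bin can be applied back to the image. Values exactly at
    +1 fall in the last bin.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be ≥ 2, got {n_bins}")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    width = 2.0 / n_bins
    ig = np.clip(((field.g + 1.0) / width).astype(np.int64), 0, n_bins - 1)
    is_ = np.clip(((field.s + 1.0) / width).astype(np.int64), 0, n_bins - 1)
    ig[field.null_mask] = -1
    is_[field.null_mask] = -1
    valid = ~field.null_mask
    flat = ig[valid] * n_bins + is_[valid]
    counts = np.bincount(flat, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    return PhasorHistogram(counts=counts, bin_edges=edges, bin_index_g=ig, bin_index_s=is_)


def to_polar(g, s) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian (g, s) → polar (r, θ) with θ the quadrant-aware angle
    mapped to [0, 2π). The origin maps to (0, 0) by convention."""
    g = np.asarray(g, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    r = np.hypot(g, s)
    theta = np.mod(np.arctan2(s, g), 2.0 * np.pi)
    # θ is undefined at the origin; snap to 0 there (tolerance absorbs
    # floating-point noise in nominally-zero coordinates)
    theta = np.where(r < 1e-12, 0.0, theta)
    if r.ndim == 0:
        return float(r), float(theta)
    return r, theta
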