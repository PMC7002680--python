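"""Reading and writing hyperspectral cubes and rendered images.

The package-wide conventions live here: cubes are stored as ``(z, y, x, λ)``
float arrays with a calibrated :class:`WavelengthAxis`, and rendered RGB
images are ``(y, x, 3)`` (or ``(z, y, x, 3)``) floats in ``[0, 1]``.

Supported on-disk formats are multichannel TIFF (ImageJ hyperstack dialect,
one plane per spectral channel) and HDF5 (dataset ``/cube`` with attributes
``lambda0`` and ``bandwidth``). Vendor microscope formats are out of scope;
convert to TIFF or HDF5 first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Default detector calibration: 32 spectral bins starting at 410.5 nm with
#: 8.9 nm bandwidth each (410.5–695.3 nm span).
DEFAULT_LAMBDA0 = 410.5
DEFAULT_BANDWIDTH = 8.9
DEFAULT_N_CHANNELS = 32


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class WavelengthAxis:
    """Calibrated spectral axis of a hyperspectral cube.

    Parameters
    ----------
    lambda0 : float
        Start wavelength of the first spectral bin, in nm.
    bandwidth : float
        Width of each spectral bin, in nm. Bins are contiguous.
    n_channels : int
        Number of spectral channels (at least 2).

    Attributes
    ----------
    centers : ndarray
        ``lambda0 + i * bandwidth`` for ``i = 0 … n_channels - 1``; the
        wavelength labelling each channel.
    midpoints : ndarray
        Bin midpoints ``lambda0 + (i + 1/2) * bandwidth``.
    """

    lambda0: float
    bandwidth: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValidationError(f"need at least 2 channels, got {self.n_channels}")
        if self.bandwidth <= 0:
            raise ValidationError(f"bandwidth must be positive, got {self.bandwidth}")

    @property
    def centers(self) -> np.ndarray:
        return self.lambda0 + self.bandwidth * np.arange(self.n_channels)

    @property
    def midpoints(self) -> np.ndarray:
        return self.centers + 0.5 * self.bandwidth

    @property
    def span(self) -> tuple[float, float]:
        """(start of first bin, end of last bin) in nm."""
        return (self.lambda0, self.lambda0 + self.bandwidth * self.n_channels)


def make_wavelength_axis(
    lambda0: float = DEFAULT_LAMBDA0,
    bandwidth: float = DEFAULT_BANDWIDTH,
    n: int = DEFAULT_N_CHANNELS,
) -> WavelengthAxis:
    """Build an evenly spaced wavelength axis; defaults match the 32-channel
    410.5 nm / 8.9 nm detector calibration used throughout."""
    return WavelengthAxis(lambda0=float(lambda0), bandwidth=float(bandwidth), n_channels=int(n))


@dataclass
class SpectralImage:
    """Hyperspectral intensity cube ``I(z, y, x, λ)`` with its axis.

    Intensities are nonnegative floats; a z size of 1 encodes a single
    optical section. The spectral dimension is always last.
    """

    data: np.ndarray
    axis: WavelengthAxis = field(default_factory=make_wavelength_axis)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:  # (y, x, λ) → (1, y, x, λ)
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValidationError(f"cube must be (z, y, x, λ); got shape {self.data.shape}")
        if self.data.shape[-1] != self.axis.n_channels:
            raise ValidationError(
                f"cube has {self.data.shape[-1]} channels but axis declares "
                f"{self.axis.n_channels}"
            )
        if np.any(self.data < 0):
            raise ValidationError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]


def read_cube(path: str | Path, axis: WavelengthAxis | None = None) -> SpectralImage:
    """Read a hyperspectral cube from multichannel TIFF or HDF5.

    TIFF files follow the channel-as-plane convention: an array of shape
    ``(λ, y, x)`` or ``(z, λ, y, x)``; the λ dimension is moved last. HDF5
    files hold dataset ``/cube`` (already ``(z, y, x, λ)`` or ``(y, x, λ)``)
    with ``lambda0`` / ``bandwidth`` attributes. If no wavelength metadata is
    present and no ``axis`` is supplied, the default 32-channel 410.5/8.9 nm
    axis is attached and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "cube" not in f:
                raise IOError(f"{path}: HDF5 file has no /cube dataset")
            ds = f["cube"]
            data = np.asarray(ds)
            if axis is None and "lambda0" in ds.attrs and "bandwidth" in ds.attrs:
                axis = make_wavelength_axis(
                    float(ds.attrs["lambda0"]), float(ds.attrs["bandwidth"]), data.shape[-1]
                )
    elif suffix in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        if data.ndim == 2:
            raise ValidationError(f"{path}: single-plane TIFF; at least 2 channels required")
        # channel-as-plane: (λ, y, x) or (z, λ, y, x) → λ last
        data = np.moveaxis(data, -3, -1)
    else:
        raise IOError(f"unsupported cube format: {path.suffix} (use TIFF or HDF5)")

    if axis is None:
        if data.shape[-1] != DEFAULT_N_CHANNELS:
            axis = make_wavelength_axis(DEFAULT_LAMBDA0, DEFAULT_BANDWIDTH, data.shape[-1])
        else:
            axis = make_wavelength_axis()
        logger.warning(
            "%s: no wavelength metadata; assuming %d channels from %.1f nm, %.1f nm bandwidth",
            path, axis.n_channels, axis.lambda0, axis.bandwidth,
        )
    return SpectralImage(data=np.asarray(data, dtype=np.float64), axis=axis)


def write_cube(image: SpectralImage, path: str | Path) -> None:
    """Write a cube to HDF5 (dataset /cube + axis attributes), losslessly."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("cube", data=image.data)
        ds.attrs["lambda0"] = image.axis.lambda0
        ds.attrs["bandwidth"] = image.axis.bandwidth


def write_rgb(image: np.ndarray, path: str | Path, format: str | None = None) -> None:
    """Write an RGB image (floats in [0, 1]) as an 8-bit PNG or TIFF.

    Values are quantized with round-half-up (``np.rint``); a round-trip read
    recovers each channel to within 1/255.
    """
    rgb = np.asarray(image, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValidationError(f"expected (y, x, 3) image, got shape {rgb.shape}")
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValidationError("RGB values must lie in [0, 1]")
    quantized = np.rint(rgb * 255).astype(np.uint8)
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"png", "tif", "tiff"}:
        raise ValidationError(f"unsupported RGB format: {fmt}")
    if fmt == "png":
        iio.imwrite(path, quantized, extension=".png")
    else:
        tifffile.imwrite(path, quantized)


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image back to floats in [0, 1]."""
    arr = iio.imread(path)
    return np.asarray(arr[..., :3], dtype=np.float64) / 255.0
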