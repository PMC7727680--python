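"""Core image and mask containers plus readers/writers.

Conventions used throughout the package: arrays are row-major, 0-based,
indexed (row, col) with the origin at the top-left; larger intensity means
brighter tissue (MONOCHROME1 DICOMs are inverted on load to honour this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, InputError, UnsupportedFormatError

__all__ = [
    "CTSlice",
    "BinaryMask",
    "ProbabilityMap",
    "read_dicom_slice",
    "read_image_slice",
    "read_mask",
    "write_mask",
    "normalize_intensity",
]


@dataclass
class CTSlice:
    """A single 2-D grayscale CT slice.

    Parameters
    ----------
    pixels
        2-D float array of intensities; every value must be finite.
    pixel_spacing_mm
        Optional (row, col) spacing in millimetres, taken from DICOM tags.
    source_id
        Free-text provenance (file path, phantom seed, ...).
    calibrated
        True when DICOM rescale slope/intercept were applied, i.e. the
        values are on the modality's calibrated scale.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] | None = None
    source_id: str = ""
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("slice pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("slice contains non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A 2-D {0,1} mask aligned with a slice (ground truth, coarse, or refined)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.size == 0:
            raise InputError("mask must be a non-empty 2-D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise InputError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


@dataclass
class ProbabilityMap:
    """Per-pixel lung-membership probability in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise InputError("probability map must be a non-empty 2-D array")
        if arr.min() < 0.0 or arr.max() > 1.0 or not np.all(np.isfinite(arr)):
            raise InputError("probabilities must lie in [0, 1]")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_dicom_slice(path: str | Path) -> CTSlice:
    """Read a single-frame DICOM image, applying rescale slope/intercept.

    MONOCHROME1 images are inverted (max - value) so that larger always
    means brighter. Raises :class:`UnsupportedFormatError` for multi-frame
    or non-image DICOMs and for files that are not DICOM at all.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        ds = pydicom.dcmread(str(path), force=False)
    except InvalidDicomError as exc:
        raise UnsupportedFormatError(f"not a DICOM file: {path}") from exc
    if "PixelData" not in ds:
        raise UnsupportedFormatError(f"DICOM without image data: {path}")
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise UnsupportedFormatError(f"multi-frame DICOM unsupported: {path}")

    pixels = ds.pixel_array.astype(np.float64)
    if pixels.ndim != 2:
        raise UnsupportedFormatError(f"non 2-D DICOM pixel data: {path}")

    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    calibrated = ("RescaleSlope" in ds) or ("RescaleIntercept" in ds)
    pixels = pixels * slope + intercept

    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        pixels = pixels.max() - pixels

    spacing = None
    if "PixelSpacing" in ds:
        sp = ds.PixelSpacing
        spacing = (float(sp[0]), float(sp[1]))

    return CTSlice(
        pixels=pixels,
        pixel_spacing_mm=spacing,
        source_id=str(path),
        calibrated=calibrated,
    )


def read_image_slice(path: str | Path) -> CTSlice:
    """Read a grayscale PNG/TIFF slice losslessly (8- or 16-bit).

    RGB input is converted to luminance with a warning.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise InputError(f"unreadable image file: {path}") from exc
    if arr.ndim == 3:
        warnings.warn(f"RGB image {path} converted to luminance", stacklevel=2)
        arr = arr[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    return CTSlice(pixels=arr.astype(np.float64), source_id=str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with 0 -> 0 and 1 -> 255."""
    import imageio.v3 as iio

    path = Path(path)
    try:
        iio.imwrite(path, (mask.values * 255).astype(np.uint8))
    except OSError as exc:
        raise InputError(f"cannot write mask to {path}") from exc


def read_mask(path: str | Path) -> BinaryMask:
    """Read a {0,255} PNG mask back to {0,1} (any non-zero pixel -> 1)."""
    sl = read_image_slice(path)
    return BinaryMask((sl.pixels > 0).astype(np.uint8))


def normalize_intensity(ct: CTSlice, mode: str = "minmax") -> CTSlice:
    """Rescale intensities.

    ``minmax`` maps min -> 0 and max -> 1 (a constant image maps to all
    zeros); ``zscore`` standardises to mean 0 and population sd 1 and
    raises :class:`DegenerateInputError` on a constant image.
    """
    v = ct.pixels
    if mode == "minmax":
        lo, hi = float(v.min()), float(v.max())
        out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    elif mode == "zscore":
        sd = float(v.std())
        if sd == 0.0:
            raise DegenerateInputError("constant image cannot be z-scored")
        out = (v - v.mean()) / sd
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return CTSlice(
        pixels=out,
        pixel_spacing_mm=ct.pixel_spacing_mm,
        source_id=ct.source_id,
        calibrated=ct.calibrated,
    )
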