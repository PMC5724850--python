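"""Reading and writing CT volumes and lung masks.

One in-memory representation is used throughout the package: a dense numpy
array in Hounsfield Units with axis order ``(z, y, x)`` — axis 0 iterates
over axial slices — together with per-axis spacing and origin in millimetres.
A voxel at index ``(k, j, i)`` sits at physical position
``z = oz + k*sz`` (and analogously for y and x).

Supported formats: MetaImage (``.mha``/``.mhd``), NIfTI-1 (``.nii``,
``.nii.gz``) and, read-only, a directory holding a single DICOM series
(rescale slope/intercept applied, slices sorted along the scan normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

log = logging.getLogger(__name__)

#: Plausible Hounsfield range enforced on ingest; values outside are clamped.
HU_MIN = -1100.0
HU_MAX = 3200.0

_VOLUME_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")


class VolumeIOError(RuntimeError):
    """Raised when a volume or mask cannot be read or written."""


def _check_grid(voxels: np.ndarray, spacing, what: str) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"{what} must be a 3-D array, got ndim={voxels.ndim}")
    nz, ny, nx = voxels.shape
    if nz < 2 or ny < 8 or nx < 8:
        raise ValueError(
            f"{what} too small: need >= 2 slices of >= 8x8 pixels, got {voxels.shape}"
        )
    if len(spacing) != 3:
        raise ValueError(f"{what} spacing must have 3 entries, got {spacing!r}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"{what} spacing must be strictly positive, got {spacing!r}")


@dataclass
class CTVolume:
    """A 3-D CT image in Hounsfield Units.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx), float32
        Intensity in HU, axis order (slice z, row y, column x).
    spacing : (sz, sy, sx)
        Voxel spacing in mm; ``spacing[0]`` is the slice thickness.
    origin : (oz, oy, ox)
        Physical position of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.voxels, self.spacing, "CTVolume")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CTVolume voxels must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def slice_thickness(self) -> float:
        return self.spacing[0]

    def index_to_physical(self, k: int, j: int, i: int) -> tuple[float, float, float]:
        """Physical (z, y, x) position in mm of voxel index (k, j, i)."""
        return (
            self.origin[0] + k * self.spacing[0],
            self.origin[1] + j * self.spacing[1],
            self.origin[2] + i * self.spacing[2],
        )


@dataclass
class LungMask:
    """Binary lung mask on the same grid as its parent :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = (np.asarray(self.voxels) > 0).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.voxels, self.spacing, "LungMask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    def check_aligned(self, volume: CTVolume) -> None:
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


def clamp_hu(voxels: np.ndarray) -> tuple[np.ndarray, int]:
    """Clamp intensities to the plausible HU range; return (array, #clamped)."""
    n_out = int(np.count_nonzero((voxels < HU_MIN) | (voxels > HU_MAX)))
    if n_out:
        voxels = np.clip(voxels, HU_MIN, HU_MAX)
    return voxels, n_out


def _has_volume_suffix(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _VOLUME_SUFFIXES)


def _from_sitk(img: sitk.Image, what: str) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img).astype(np.float32)
    if arr.ndim == 4 and arr.shape[-1] == 1:  # some writers add a component axis
        arr = arr[..., 0]
    spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
    origin = tuple(float(o) for o in img.GetOrigin()[::-1])
    if not all(s > 0 for s in spacing):
        raise VolumeIOError(
            f"{what}: non-positive voxel spacing {spacing} in header "
            "(PixelSpacing / slice spacing)"
        )
    return arr, spacing, origin


def _read_dicom_series(directory: Path) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(str(directory))
    if not series_ids:
        raise VolumeIOError(f"no readable DICOM series found in {directory}")
    if len(series_ids) > 1:
        raise VolumeIOError(
            f"directory {directory} contains {len(series_ids)} DICOM series; "
            "expected exactly one"
        )
    # GDCM sorts files by ImagePositionPatient along the slice normal and
    # applies RescaleSlope/RescaleIntercept, so intensities arrive in HU.
    file_names = reader.GetGDCMSeriesFileNames(str(directory), series_ids[0])
    reader.SetFileNames(file_names)
    return reader.Execute()


def read_volume(path) -> CTVolume:
    """Read a CT volume from ``.mha``/``.mhd``, ``.nii``/``.nii.gz`` or a
    directory holding one DICOM series; intensities are returned in HU,
    clamped to ``[HU_MIN, HU_MAX]`` (clamped voxels are counted in the log).
    """
    path = Path(path)
    if path.is_dir():
        img = _read_dicom_series(path)
    elif _has_volume_suffix(path):
        if not path.exists():
            raise VolumeIOError(f"file not found: {path}")
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # pragma: no cover - backend message varies
            raise VolumeIOError(f"cannot read {path}: {exc}") from exc
    else:
        raise VolumeIOError(
            f"unsupported volume format: {path} (expected {_VOLUME_SUFFIXES} "
            "or a DICOM directory)"
        )
    arr, spacing, origin = _from_sitk(img, str(path))
    arr, n_clamped = clamp_hu(arr)
    if n_clamped:
        log.warning("%s: clamped %d voxels to [%g, %g] HU", path, n_clamped, HU_MIN, HU_MAX)
    return CTVolume(arr, spacing, origin)


def write_volume(volume: CTVolume, path) -> None:
    """Write a volume as float32 MetaImage or NIfTI; lossless round trip."""
    path = Path(path)
    if not _has_volume_suffix(path):
        raise VolumeIOError(f"unsupported output format for volume: {path}")
    img = sitk.GetImageFromArray(volume.voxels.astype(np.float32))
    img.SetSpacing(tuple(volume.spacing[::-1]))
    img.SetOrigin(tuple(volume.origin[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mask(path) -> LungMask:
    """Read a mask; any strictly positive value maps to 1."""
    path = Path(path)
    if path.is_dir():
        img = _read_dicom_series(path)
    elif _has_volume_suffix(path):
        if not path.exists():
            raise VolumeIOError(f"file not found: {path}")
        img = sitk.ReadImage(str(path))
    else:
        raise VolumeIOError(f"unsupported mask format: {path}")
    arr, spacing, origin = _from_sitk(img, str(path))
    mask = LungMask((arr > 0).astype(np.uint8), spacing, origin)
    if mask.is_empty:
        log.warning("%s: mask is empty", path)
    return mask


def write_mask(mask: LungMask, path) -> None:
    path = Path(path)
    if not _has_volume_suffix(path):
        raise VolumeIOError(f"unsupported output format for mask: {path}")
    img = sitk.GetImageFromArray(mask.voxels.astype(np.uint8))
    img.SetSpacing(tuple(mask.spacing[::-1]))
    img.SetOrigin(tuple(mask.origin[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)
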