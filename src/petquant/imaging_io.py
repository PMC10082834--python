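"""Volumetric image I/O and SUV conversion.

The pipeline's common currency is the :class:`SUVImage`: a 3-D scalar
volume on the conventional body-weight SUV scale,

    SUV = activity concentration (Bq/mL) / injected activity (Bq) x body weight (g)

which is dimensionless on the usual g/mL convention.  Arrays are always
ordered ``(z, y, x)`` with 0-based voxel indices; physical coordinates
refer to voxel centers and are expressed in millimetres.  NIfTI-1 is the
canonical on-disk format (scalar volumes as float64, masks as uint8); a
DICOM-series importer is provided as a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, VolumeFormatError

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

Spacing = tuple[float, float, float]


def _validate_grid(voxels: np.ndarray, spacing: Sequence[float]) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got ndim={voxels.ndim}")
    if voxels.size == 0:
        raise ValueError("volume must contain at least one voxel per axis")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive lengths (mm), got {spacing}")


def _validate_scalar(voxels: np.ndarray) -> None:
    if not np.all(np.isfinite(voxels)):
        raise ValueError("voxel values must be finite")
    if np.any(voxels < 0):
        raise ValueError("voxel values must be non-negative")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Scan acquisition metadata needed for SUV normalization.

    Parameters
    ----------
    injected_activity_bq:
        Injected tracer activity in Bq.
    body_weight_g:
        Animal body weight in grams.
    injection_time, scan_time:
        Timestamps; only required when decay correction is requested.
    half_life_min:
        Radionuclide half-life in minutes (default: 18F).
    """

    injected_activity_bq: float
    body_weight_g: float
    injection_time: Optional[datetime] = None
    scan_time: Optional[datetime] = None
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self):
        if self.injected_activity_bq <= 0:
            raise ValueError("injected activity must be > 0 Bq")
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be > 0 g")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be > 0 min")

    def uptake_minutes(self) -> float:
        if self.injection_time is None or self.scan_time is None:
            raise ConfigurationError(
                "decay correction requires both injection_time and scan_time"
            )
        dt = (self.scan_time - self.injection_time).total_seconds() / 60.0
        if dt < 0:
            raise ValueError("scan_time must not precede injection_time")
        return dt


@dataclass
class ActivityVolume:
    """A reconstructed 3-D activity-concentration volume (Bq/mL)."""

    voxels: np.ndarray
    spacing: Spacing
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _validate_grid(self.voxels, self.spacing)
        _validate_scalar(self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SUVImage:
    """A 3-D volume on the body-weight SUV scale (dimensionless)."""

    voxels: np.ndarray
    spacing: Spacing
    meta: AcquisitionMeta
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _validate_grid(self.voxels, self.spacing)
        _validate_scalar(self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LesionMask:
    """A binary 3-D mask marking the metabolic tumor volume."""

    voxels: np.ndarray
    spacing: Spacing
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _validate_grid(self.voxels, self.spacing)
        if not self.voxels.any():
            raise ValueError("lesion mask must be non-empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())


Volume = Union[ActivityVolume, SUVImage, LesionMask]


# --------------------------------------------------------------------------
# NIfTI round trip.  Internally arrays are (z, y, x); NIfTI stores (x, y, z)
# with a diagonal affine carrying the spacing and origin.
# --------------------------------------------------------------------------


def _affine(spacing_zyx: Spacing, origin_zyx: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_zyx[::-1]
    aff[:3, 3] = list(origin_zyx)[::-1]
    return aff


def write_volume(vol: Volume, path: Union[str, Path]) -> None:
    """Write a volume (activity, SUV or mask) to a NIfTI-1 file.

    Masks are stored as uint8 (bit-exact round trip); scalar volumes as
    float64 (exact within float representation).
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, LesionMask):
        data = vol.voxels.astype(np.uint8)
    else:
        data = vol.voxels.astype(np.float64)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_volume(path: Union[str, Path], format: str = "nifti") -> ActivityVolume:
    """Read a scalar volume as an :class:`ActivityVolume`.

    ``format`` is ``"nifti"`` for a single NIfTI file or ``"dicom_series"``
    for a directory of DICOM slices.  Axis order is normalized to
    ``(z, y, x)``; spacing is taken from the header.  Anisotropic voxels
    are allowed.
    """
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path: Union[str, Path]) -> ActivityVolume:
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises a zoo of classes
        raise VolumeFormatError(f"cannot parse {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D data, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    origin_xyz = img.affine[:3, 3]
    try:
        return ActivityVolume(
            voxels=np.transpose(data, (2, 1, 0)),
            spacing=tuple(float(z) for z in zooms[::-1]),
            origin=tuple(float(o) for o in origin_xyz[::-1]),
        )
    except ValueError as exc:
        raise VolumeFormatError(f"{path}: {exc}") from exc


def read_mask(path: Union[str, Path]) -> LesionMask:
    """Read a binary lesion mask from NIfTI (any nonzero voxel is in)."""
    vol = _read_nifti(path)
    try:
        return LesionMask(vol.voxels > 0, vol.spacing, vol.origin)
    except ValueError as exc:
        raise VolumeFormatError(f"{path}: {exc}") from exc


def _read_dicom_series(path: Union[str, Path]) -> ActivityVolume:
    import pydicom

    path = Path(path)
    if not path.is_dir():
        raise VolumeFormatError(f"DICOM series path must be a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima", ""})
    if not files:
        raise VolumeFormatError(f"no DICOM slices found in {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise VolumeFormatError(f"cannot parse {f} as DICOM: {exc}") from exc
        slices.append(ds)
    try:
        slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        rows_mm, cols_mm = (float(v) for v in slices[0].PixelSpacing)
        zs = [float(d.ImagePositionPatient[2]) for d in slices]
    except AttributeError as exc:
        raise VolumeFormatError(f"DICOM series missing field: {exc}") from exc
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.any(gaps <= 0):
            raise VolumeFormatError("DICOM slice positions are not strictly increasing")
        dz = float(np.mean(gaps))
    else:
        dz = float(getattr(slices[0], "SliceThickness", rows_mm))
    planes = []
    for d in slices:
        arr = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    vox = np.stack(planes, axis=0)  # (z, y, x)
    origin = (zs[0], float(slices[0].ImagePositionPatient[1]), float(slices[0].ImagePositionPatient[0]))
    try:
        return ActivityVolume(vox, spacing=(dz, rows_mm, cols_mm), origin=origin)
    except ValueError as exc:
        raise VolumeFormatError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# SUV conversion
# --------------------------------------------------------------------------


def decayed_activity(meta: AcquisitionMeta) -> float:
    """Injected activity decayed from injection to scan time (Bq)."""
    dt = meta.uptake_minutes()
    return meta.injected_activity_bq * 2.0 ** (-dt / meta.half_life_min)


def to_suv(
    vol: ActivityVolume,
    meta: AcquisitionMeta,
    decay_correct: bool = False,
) -> SUVImage:
    """Convert an activity volume (Bq/mL) to a body-weight SUV image.

    Each voxel becomes ``activity / injected_effective * body_weight`` where
    ``injected_effective`` is the injected activity decayed to scan time when
    ``decay_correct`` is on, and the raw injected activity otherwise.  With
    activity in Bq/mL, injected activity in Bq and weight in g the result is
    dimensionless on the conventional g/mL scale.
    """
    injected = decayed_activity(meta) if decay_correct else meta.injected_activity_bq
    suv = vol.voxels * (meta.body_weight_g / injected)
    return SUVImage(voxels=suv, spacing=vol.spacing, meta=meta, origin=vol.origin)
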