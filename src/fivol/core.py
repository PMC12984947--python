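"""Shared domain types and file I/O.

The measurement chain operates on three on-disk artifacts: a 3D grayscale
MRI volume (NIfTI-1), a binary anatomical region-of-interest mask drawn
over the supraspinatus contour (NIfTI-1, congruent grid), and tabular
reports (CSV for per-specimen rows, JSON for study-level statistics).
Intensities are kept in floating point and never rescaled beyond the
NIfTI header slope/intercept; all volumetrics downstream are computed in
voxel space times the header spacing, so orientation conventions do not
affect results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("fivol")

#: The three study arms: surgical repair after a chronic tear, untreated
#: chronic tear, and sham-operated control.
GROUPS = ("repair", "chronic_tear", "control")


class FivolError(Exception):
    """Base class for domain errors."""


class VolumeFormatError(FivolError):
    """Raised when an on-disk image cannot be used as a 3D scalar volume."""


class MaskMismatchError(FivolError):
    """Raised when a mask grid is not congruent with its reference volume."""


class EmptyRoiError(FivolError):
    """Raised when an operation requires at least one foreground ROI voxel."""


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing in millimetres.

    Parameters
    ----------
    data
        3D array of signal intensities (arbitrary scanner units), stored
        as float64 regardless of the on-disk integer type.
    spacing
        Per-axis voxel edge length in mm; all components must be > 0.
    meta
        Free-form acquisition metadata (TE/TR, field strength, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """Binary foreground mask delineating the anatomical contour."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) != 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return self.foreground_count == 0


@dataclass
class SpecimenRecord:
    """Identity and wet-lab covariates of one imaged shoulder."""

    specimen_id: str
    group: str
    body_weight_kg: Optional[float] = None
    muscle_weight_g: Optional[float] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class QuantReport:
    """Per-specimen quantification rows plus study-level statistics.

    ``per_specimen`` holds one row per specimen (never mixing specimens);
    ``statistics`` holds the group tables and agreement statistics as a
    JSON-serialisable mapping.
    """

    per_specimen: pd.DataFrame
    statistics: dict = field(default_factory=dict)


def _nifti_spacing(img: nib.spatialimages.SpatialImage) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)  # type: ignore[return-value]


def load_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume, preserving header spacing and scaled intensities.

    Intensities come from the header-scaled data (slope/intercept applied,
    nothing else); spacing comes from the header zooms.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    VolumeFormatError
        For non-3D payloads (a trailing singleton dimension is tolerated
        and squeezed) or non-positive spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path.name}: expected a 3D single-channel volume, got shape {data.shape}"
        )
    spacing = _nifti_spacing(img)
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(f"{path.name}: non-positive voxel spacing {spacing}")
    meta = {"source": str(path)}
    return ImageVolume(data=data, spacing=spacing, meta=meta)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path, reference: ImageVolume) -> RoiMask:
    """Read a binary ROI mask and check congruence with its volume.

    Nonzero voxels become foreground. An all-zero mask loads (downstream
    segmentation raises the explicit empty-ROI error).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.shape != reference.shape:
        raise MaskMismatchError(
            f"mask grid {data.shape} does not match volume grid {reference.shape}"
        )
    mask = RoiMask(mask=data)
    if mask.is_empty:
        logger.warning("mask %s has no foreground voxels", path.name)
    return mask


def save_mask(mask: RoiMask, spacing: tuple[float, float, float], path: str | Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_report(report: QuantReport, out_dir: str | Path, stem: str = "study") -> tuple[Path, Path]:
    """Emit a report as ``<stem>.csv`` (per-specimen) + ``<stem>.json`` (statistics).

    Returns the two paths written. Values round-trip at full precision
    (CSV is written with repr-level float formatting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    if report.per_specimen.empty:
        logger.warning("writing empty report (no specimen rows)")
    report.per_specimen.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(report.statistics, fh, indent=2, default=_json_default)
    return csv_path, json_path


def read_report(out_dir: str | Path, stem: str = "study") -> QuantReport:
    out_dir = Path(out_dir)
    per_specimen = pd.read_csv(out_dir / f"{stem}.csv", float_precision="round_trip")
    with open(out_dir / f"{stem}.json") as fh:
        statistics = json.load(fh)
    return QuantReport(per_specimen=per_specimen, statistics=statistics)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
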