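"""Threshold-paint segmentation of the ROI into muscle / fat / unclassified.

Every ROI voxel is classified by pure intensity windowing: muscle when the
value lies in the closed muscle window, fat when it is at or above the fat
floor, unclassified otherwise (this covers both the gray zone between the
windows and values below the muscle window). Voxels outside the ROI are
background. No morphological post-processing is applied — cleanup would
change the voxel counts that the volumetrics report.

Gray-zone voxels are retained and reported rather than dropped: partial
volume mixing at tissue interfaces lands averaged signals there, which is
the mechanism behind fat underestimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import EmptyRoiError, ImageVolume, MaskMismatchError, RoiMask

# Integer label codes used in memory and on disk.
BACKGROUND, MUSCLE, FAT, UNCLASSIFIED = 0, 1, 2, 3
LABEL_CODES = {
    "background": BACKGROUND,
    "muscle": MUSCLE,
    "fat": FAT,
    "unclassified": UNCLASSIFIED,
}


@dataclass(frozen=True)
class ThresholdPolicy:
    """Intensity windows for tissue classification.

    muscle_window is closed on both ends ("1000-3500" taken inclusive);
    fat is value >= fat_floor ("3600 or higher"). The open interval
    between them is the gray zone and may be empty.
    """

    muscle_window: tuple[float, float]
    fat_floor: float

    def __post_init__(self) -> None:
        lo, hi = self.muscle_window
        if not (lo <= hi < self.fat_floor):
            raise ValueError(
                f"require muscle lo <= hi < fat_floor, got [{lo}, {hi}] / {self.fat_floor}"
            )

    @property
    def gray_zone(self) -> tuple[float, float]:
        """Open interval between the muscle window and the fat floor."""
        return (self.muscle_window[1], self.fat_floor)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"muscle_window": list(self.muscle_window), "fat_floor": self.fat_floor},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdPolicy":
        d = json.loads(Path(path).read_text())
        return cls(muscle_window=tuple(d["muscle_window"]), fat_floor=float(d["fat_floor"]))


def default_policy() -> ThresholdPolicy:
    """The working windows: muscle [1000, 3500], fat >= 3600.

    These are the calibrated cutoff bracket rounded outward to leave an
    explicit gray zone (3500, 3600) for interface voxels. Valid for the
    7.0T protocol they were calibrated on; recalibrate for any other.
    """
    return ThresholdPolicy(muscle_window=(1000.0, 3500.0), fat_floor=3600.0)


@dataclass
class TissueLabelMap:
    """Per-voxel class labels with the spacing and policy that produced them."""

    labels: np.ndarray  # int8/int16 grid over LABEL_CODES values
    spacing: tuple[float, float, float]
    policy: ThresholdPolicy

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def count(self, code: int) -> int:
        return int((self.labels == code).sum())


def segment_tissues(
    volume: ImageVolume, roi: RoiMask, policy: ThresholdPolicy | None = None
) -> TissueLabelMap:
    """Classify every ROI voxel by the threshold policy.

    muscle iff value in muscle_window (closed); fat iff value >= fat_floor;
    otherwise unclassified. Outside the ROI -> background. Deterministic
    and independent of voxel spacing.
    """
    if policy is None:
        policy = default_policy()
    if volume.shape != roi.shape:
        raise MaskMismatchError(
            f"volume grid {volume.shape} does not match ROI grid {roi.shape}"
        )
    if roi.is_empty:
        raise EmptyRoiError("ROI has no foreground voxels")

    v = volume.data
    lo, hi = policy.muscle_window
    labels = np.full(v.shape, UNCLASSIFIED, dtype=np.int8)
    labels[(v >= lo) & (v <= hi)] = MUSCLE
    labels[v >= policy.fat_floor] = FAT
    labels[~roi.mask] = BACKGROUND
    return TissueLabelMap(labels=labels, spacing=volume.spacing, policy=policy)


def save_label_map(label_map: TissueLabelMap, path: str | Path) -> None:
    """Write labels as NIfTI plus a JSON sidecar documenting codes and policy."""
    path = Path(path)
    affine = np.diag(list(label_map.spacing) + [1.0])
    img = nib.Nifti1Image(label_map.labels.astype(np.uint8), affine)
    img.header.set_zooms(label_map.spacing)
    nib.save(img, str(path))
    sidecar = {
        "label_codes": LABEL_CODES,
        "policy": {
            "muscle_window": list(label_map.policy.muscle_window),
            "fat_floor": label_map.policy.fat_floor,
        },
    }
    sidecar_path = path.parent / (path.name.split(".")[0] + ".labels.json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))


def load_label_map(path: str | Path) -> TissueLabelMap:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata()).astype(np.int8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar_path = path.parent / (path.name.split(".")[0] + ".labels.json")
    if sidecar_path.exists():
        policy_d = json.loads(sidecar_path.read_text())["policy"]
        policy = ThresholdPolicy(
            muscle_window=tuple(policy_d["muscle_window"]),
            fat_floor=float(policy_d["fat_floor"]),
        )
    else:
        policy = default_policy()
    return TissueLabelMap(labels=labels, spacing=spacing, policy=policy)  # type: ignore[arg-type]
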