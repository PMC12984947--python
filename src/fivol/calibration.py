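"""ROC calibration of the muscle/fat signal-intensity cutoff.

Muscle and fat differ strongly in T1 signal, so a scalar intensity cutoff
separates them. The cutoff is calibrated from operator-labelled sample
points probed on the images: candidate cutoffs are the midpoints between
consecutive distinct sorted sample values (plus below-minimum and
above-maximum sentinels), each candidate is scored by Youden's
J = sensitivity + specificity - 1 with fat as the positive class
(a voxel is called fat when its value >= cutoff), and the J-maximising
candidate is returned. When the classes are fully separated this is the
midpoint of the gap between max(muscle) and min(fat), with J = 1.

Thresholds calibrated at one field strength do not transfer to another;
recalibrate per protocol.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import FivolError, ImageVolume

LABELS = ("muscle", "fat")


class CalibrationError(FivolError):
    pass


@dataclass(frozen=True)
class IntensitySample:
    """One labelled intensity probe: the value at a cursor position."""

    value: float
    label: str  # "muscle" or "fat", assigned by the sampler
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not np.isfinite(self.value):
            raise ValueError("sample value must be finite")


@dataclass
class ThresholdCalibration:
    """Result of ROC cutoff calibration.

    ``sensitivity`` is fat recall (fat called fat at the cutoff) and
    ``specificity`` is muscle recall. ``roc_points`` lists every candidate
    cutoff with its (sensitivity, specificity). When the classes are
    separable, ``gap`` is (max muscle, min fat): any cutoff inside it is
    equivalent, and ``cutoff`` is the gap midpoint.
    """

    cutoff: float
    sensitivity: float
    specificity: float
    muscle_observed_range: tuple[float, float]
    fat_observed_range: tuple[float, float]
    n_samples: int
    roc_points: list[tuple[float, float, float]]
    separable: bool
    gap: tuple[float, float] | None
    inseparable_flag: bool = False

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "muscle_observed_range": list(self.muscle_observed_range),
            "fat_observed_range": list(self.fat_observed_range),
            "n_samples": self.n_samples,
            "separable": self.separable,
            "gap": list(self.gap) if self.gap else None,
            "inseparable_flag": self.inseparable_flag,
            "roc_points": [list(p) for p in self.roc_points],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def sample_intensities(
    volume: ImageVolume,
    points: Sequence[tuple[int, int, int]],
    labels: Sequence[str],
) -> list[IntensitySample]:
    """Probe the volume at voxel indices, attaching operator labels.

    Values are taken untransformed from the volume. Negative indices are
    rejected (they are not wrap-around probes).
    """
    if len(points) != len(labels):
        raise CalibrationError(
            f"{len(points)} points but {len(labels)} labels"
        )
    samples = []
    for point, label in zip(points, labels):
        if len(point) != 3:
            raise CalibrationError(f"point {point} is not a 3D index")
        if any(i < 0 for i in point) or any(
            i >= n for i, n in zip(point, volume.shape)
        ):
            raise CalibrationError(f"point {point} outside grid {volume.shape}")
        samples.append(IntensitySample(value=float(volume.data[tuple(point)]), label=label))
    return samples


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values, plus sentinels
    one unit below the minimum and above the maximum (the degenerate
    all-fat / all-muscle cutoffs standing in for the +-infinity ends of
    the ROC curve)."""
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])


def calibrate_cutoff(samples: Iterable[IntensitySample]) -> ThresholdCalibration:
    """Find the intensity cutoff maximising Youden's J over the samples.

    Requires at least one sample of each class. When several candidates
    tie on J, the lower median of the tied candidates is returned (for
    separable classes the optimum is unique: the gap midpoint). A sample
    set where no cutoff beats J = 0 is flagged inseparable.
    """
    samples = list(samples)
    muscle = np.array([s.value for s in samples if s.label == "muscle"], dtype=float)
    fat = np.array([s.value for s in samples if s.label == "fat"], dtype=float)
    if muscle.size == 0 or fat.size == 0:
        raise CalibrationError("need at least one sample of each class")

    values = np.concatenate([muscle, fat])
    candidates = _candidate_cutoffs(values)
    # fat is positive: called fat when value >= cutoff
    sens = np.array([(fat >= t).mean() for t in candidates])
    spec = np.array([(muscle < t).mean() for t in candidates])
    j = sens + spec - 1.0

    best = np.flatnonzero(j == j.max())
    pick = best[(len(best) - 1) // 2]  # lower-median tie-break
    cutoff = float(candidates[pick])

    separable = bool(muscle.max() < fat.min())
    gap = (float(muscle.max()), float(fat.min())) if separable else None
    return ThresholdCalibration(
        cutoff=cutoff,
        sensitivity=float(sens[pick]),
        specificity=float(spec[pick]),
        muscle_observed_range=(float(muscle.min()), float(muscle.max())),
        fat_observed_range=(float(fat.min()), float(fat.max())),
        n_samples=len(samples),
        roc_points=[(float(t), float(se), float(sp)) for t, se, sp in zip(candidates, sens, spec)],
        separable=separable,
        gap=gap,
        inseparable_flag=bool(j.max() <= 0.0),
    )


def read_samples_csv(path: str | Path) -> list[IntensitySample]:
    """Read samples from CSV with columns specimen_id, x, y, z, label, value."""
    samples = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            samples.append(
                IntensitySample(
                    value=float(row["value"]),
                    label=row["label"],
                    specimen_id=row.get("specimen_id", ""),
                )
            )
    return samples


def write_samples_csv(
    samples: Sequence[IntensitySample],
    path: str | Path,
    points: Sequence[tuple[int, int, int]] | None = None,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "x", "y", "z", "label", "value"])
        for i, s in enumerate(samples):
            xyz = points[i] if points is not None else ("", "", "")
            writer.writerow([s.specimen_id, *xyz, s.label, repr(s.value)])
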