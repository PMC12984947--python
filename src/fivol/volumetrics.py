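"""Label statistics: compartment volumes and the fat-to-muscle proportion.

Volumes are pure voxel counts times the voxel volume (spacing product),
the same estimator a label-statistics module applies to a painted
segmentation. The headline metric is FTMP, the fat-to-muscle proportion:

    FTMP (%) = 100 * fat volume / muscle volume

"Total volume" is muscle + fat (the reporting convention of the method's
group tables); the full ROI volume, which additionally includes
gray-zone/unclassified voxels, is reported separately so that
partial-volume loss stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GROUPS, SpecimenRecord, logger
from .segmentation import FAT, MUSCLE, UNCLASSIFIED, TissueLabelMap


@dataclass
class VolumetricResult:
    """Compartment volumes (mm^3) and FTMP (%) for one specimen.

    Invariants: total = muscle + fat; roi = total + unclassified.
    ``ftmp`` is None (with ``ftmp_defined`` False) when there is no
    muscle compartment to divide by.
    """

    muscle_volume: float
    fat_volume: float
    unclassified_volume: float
    muscle_voxels: int
    fat_voxels: int
    unclassified_voxels: int

    @property
    def total_volume(self) -> float:
        return self.muscle_volume + self.fat_volume

    @property
    def roi_volume(self) -> float:
        return self.total_volume + self.unclassified_volume

    @property
    def ftmp_defined(self) -> bool:
        return self.muscle_volume > 0

    @property
    def ftmp(self) -> Optional[float]:
        """Fat-to-muscle proportion in percent; None when muscle is empty."""
        if not self.ftmp_defined:
            return None
        return 100.0 * self.fat_volume / self.muscle_volume


def compute_volumes(labels: TissueLabelMap) -> VolumetricResult:
    """Convert a tissue label map into compartment volumes and FTMP."""
    voxel_mm3 = float(np.prod(labels.spacing))
    n_muscle = labels.count(MUSCLE)
    n_fat = labels.count(FAT)
    n_unclassified = labels.count(UNCLASSIFIED)
    return VolumetricResult(
        muscle_volume=n_muscle * voxel_mm3,
        fat_volume=n_fat * voxel_mm3,
        unclassified_volume=n_unclassified * voxel_mm3,
        muscle_voxels=n_muscle,
        fat_voxels=n_fat,
        unclassified_voxels=n_unclassified,
    )


def results_frame(
    pairs: Sequence[tuple[SpecimenRecord, VolumetricResult]]
) -> pd.DataFrame:
    """One row per specimen with compartment volumes and FTMP."""
    rows = []
    for record, res in pairs:
        rows.append(
            {
                "specimen_id": record.specimen_id,
                "group": record.group,
                "muscle_mm3": res.muscle_volume,
                "fat_mm3": res.fat_volume,
                "unclassified_mm3": res.unclassified_volume,
                "total_mm3": res.total_volume,
                "roi_mm3": res.roi_volume,
                "ftmp_pct": res.ftmp if res.ftmp_defined else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_group(
    pairs: Sequence[tuple[SpecimenRecord, VolumetricResult]]
) -> pd.DataFrame:
    """Group mean +- SD of total, muscle, fat volumes and FTMP.

    The group FTMP is the mean of per-specimen FTMPs (mean of ratios, the
    convention consistent with the method's reported group tables), with
    sample (n-1) standard deviations. Single-specimen groups report SD 0
    with ``sd_degenerate`` flagged; empty groups are omitted with a
    warning. Specimens with undefined FTMP are excluded from the FTMP
    statistic only.
    """
    df = results_frame(pairs)
    out_rows = []
    for group in GROUPS:
        sub = df[df["group"] == group]
        if sub.empty:
            logger.warning("group %r has no specimens; omitted from summary", group)
            continue
        row: dict = {"group": group, "n": len(sub)}
        for col, name in [
            ("total_mm3", "total"),
            ("muscle_mm3", "muscle"),
            ("fat_mm3", "fat"),
            ("ftmp_pct", "ftmp"),
        ]:
            vals = sub[col].dropna()
            row[f"{name}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        row["sd_degenerate"] = len(sub) < 2
        out_rows.append(row)
    return pd.DataFrame(out_rows)
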