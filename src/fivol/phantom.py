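"""Synthetic phantoms with known tissue composition.

No study data are deposited, so validation runs on phantoms:

* 3D MRI-like volumes — an ellipsoidal ROI filled with "muscle" and "fat"
  voxels whose intensities are drawn from the observed pure-tissue signal
  ranges (muscle 1002-3448, fat 3600-9652 in scanner units at 7.0T), with
  a chosen true fat-to-muscle proportion, optional boundary
  partial-volume mixing and additive noise;
* cohorts of such phantoms whose per-group FTMP and muscle-volume
  distributions follow the three study arms (repair / chronic tear /
  control);
* 2D stained-section images — eosin-pink background with blue nuclei
  speckle and non-overlapping red lipid droplets covering a known area
  fraction, satisfying the default HSB lipid windows.

Partial-volume model: an interface voxel mixes one muscle and one fat
endmember linearly by subvoxel occupancy, with the occupancy bounded so
the mixed signal stays strictly below the pure-fat floor. A mixed voxel
bright enough to classify as fat is observationally identical to a fat
voxel, so only the sub-floor ones are tracked as "mixed"; this is exactly
the regime that produces the gray zone and the underestimation of fat.

Everything is seeded: identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .calibration import IntensitySample
from .core import FivolError, ImageVolume, RoiMask, SpecimenRecord
from .histology import SectionImage

MUSCLE_RANGE_DEFAULT = (1002.0, 3448.0)
FAT_RANGE_DEFAULT = (3600.0, 9652.0)

#: Per-group generating parameters: FTMP mean/SD (%) and muscle-volume
#: mean/SD (mm^3) of the three study arms.
COHORT_PRESETS = {
    "repair": {"ftmp": (1.8, 0.8), "muscle_mm3": (8520.7, 521.9)},
    "chronic_tear": {"ftmp": (2.8, 0.7), "muscle_mm3": (8101.4, 1183.4)},
    "control": {"ftmp": (0.5, 0.4), "muscle_mm3": (10043.8, 911.0)},
}

#: In-plane resolution from a 60x40 mm FOV at 256x238 matrix, 2 mm slices.
DEFAULT_SPACING = (0.234, 0.168, 2.0)

_MUSCLE_DENSITY_G_PER_MM3 = 1.08e-3
_WEIGHT_SCATTER_SD = 0.03  # lognormal; keeps weight-volume rank correlation strong


class PhantomError(FivolError):
    pass


@dataclass
class PhantomSpec:
    """Recipe for one synthetic specimen volume."""

    target_ftmp: float
    seed: int
    shape: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    roi_center: Optional[tuple[float, float, float]] = None
    roi_semiaxes: Optional[tuple[float, float, float]] = None
    fat_pattern: str = "dispersed"  # "dispersed" | "clustered"
    muscle_intensity_range: tuple[float, float] = MUSCLE_RANGE_DEFAULT
    fat_intensity_range: tuple[float, float] = FAT_RANGE_DEFAULT
    partial_volume_width: int = 0
    noise_sd: float = 0.0
    intensity_model: str = "uniform"  # "uniform" | "normal"

    def __post_init__(self) -> None:
        if self.target_ftmp < 0:
            raise PhantomError("target_ftmp must be >= 0")
        if self.muscle_intensity_range[1] >= self.fat_intensity_range[0]:
            raise PhantomError("muscle and fat intensity ranges must not overlap")
        if self.fat_pattern not in ("dispersed", "clustered"):
            raise PhantomError("fat_pattern must be 'dispersed' or 'clustered'")
        if self.intensity_model not in ("uniform", "normal"):
            raise PhantomError("intensity_model must be 'uniform' or 'normal'")
        if self.partial_volume_width < 0 or self.noise_sd < 0:
            raise PhantomError("partial_volume_width and noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Ground-truth composition ledger of a generated phantom."""

    muscle_voxels: int
    fat_voxels: int
    mixed_voxels: int
    section_truths: list[float] = field(default_factory=list)

    @property
    def true_ftmp(self) -> float:
        """Fat/muscle voxel ratio x 100, by pre-mixing composition."""
        return 100.0 * self.fat_voxels / self.muscle_voxels


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return d2 <= 1.0


def _draw_intensities(rng, lo: float, hi: float, n: int, model: str) -> np.ndarray:
    if model == "uniform":
        return rng.uniform(lo, hi, size=n)
    mid, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    return np.clip(rng.normal(mid, sd, size=n), lo, hi)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, RoiMask, PhantomTruth]:
    """Render one phantom volume with its ROI mask and composition ledger.

    Fat voxels are placed to hit ``target_ftmp`` as closely as integer
    counts allow (exactly, when the implied count is an integer):
    ``dispersed`` scatters isolated voxels, ``clustered`` unions random
    small spheres. Raises :class:`PhantomError` when the target is
    unreachable inside the ROI, stating the maximum achievable value.
    """
    rng = np.random.default_rng(spec.seed)
    center = spec.roi_center or tuple((s - 1) / 2.0 for s in spec.shape)
    semiaxes = spec.roi_semiaxes or tuple(0.4 * s for s in spec.shape)
    roi = _ellipsoid_mask(spec.shape, center, semiaxes)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise PhantomError("ROI ellipsoid contains no voxels")

    # f/(N-f)*100 = t  =>  f = N*t/(100+t)
    n_fat = int(round(n_roi * spec.target_ftmp / (100.0 + spec.target_ftmp)))
    if n_fat > n_roi - 1:
        max_ftmp = 100.0 * (n_roi - 1)
        raise PhantomError(
            f"target_ftmp {spec.target_ftmp} unreachable in a {n_roi}-voxel ROI; "
            f"max achievable is {max_ftmp:.1f}"
        )

    roi_idx = np.flatnonzero(roi.ravel())
    fat_flat = np.zeros(roi.size, dtype=bool)
    if n_fat > 0:
        if spec.fat_pattern == "dispersed":
            chosen = rng.choice(roi_idx, size=n_fat, replace=False)
            fat_flat[chosen] = True
        else:
            fat_mask = np.zeros(spec.shape, dtype=bool)
            while int(fat_mask.sum()) < n_fat:
                c_flat = rng.choice(roi_idx)
                cz = np.unravel_index(c_flat, spec.shape)
                r = int(rng.integers(1, 4))
                ball = _ellipsoid_mask(spec.shape, tuple(float(v) for v in cz), (r, r, max(1, r // 2) or 1))
                fat_mask |= ball & roi
            excess = int(fat_mask.sum()) - n_fat
            if excess > 0:
                on = np.flatnonzero(fat_mask.ravel())
                drop = rng.choice(on, size=excess, replace=False)
                fat_mask.ravel()[drop] = False
            fat_flat = fat_mask.ravel()
    fat = fat_flat.reshape(spec.shape)
    muscle = roi & ~fat

    m_lo, m_hi = spec.muscle_intensity_range
    f_lo, f_hi = spec.fat_intensity_range
    data = np.zeros(spec.shape, dtype=np.float64)
    data[muscle] = _draw_intensities(rng, m_lo, m_hi, int(muscle.sum()), spec.intensity_model)
    data[fat] = _draw_intensities(rng, f_lo, f_hi, int(fat.sum()), spec.intensity_model)

    n_mixed = 0
    mixed = np.zeros(spec.shape, dtype=bool)
    if spec.partial_volume_width > 0 and n_fat > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        near_fat = ndimage.binary_dilation(fat, struct, iterations=spec.partial_volume_width)
        near_muscle = ndimage.binary_dilation(muscle, struct, iterations=spec.partial_volume_width)
        mixed = ((muscle & near_fat) | (fat & near_muscle)) & roi
        n_mixed = int(mixed.sum())
        if n_mixed:
            m_end = _draw_intensities(rng, m_lo, m_hi, n_mixed, spec.intensity_model)
            f_end = _draw_intensities(rng, f_lo, f_hi, n_mixed, spec.intensity_model)
            # occupancy alpha in (0, alpha_max) keeps the mix below the fat floor
            alpha_max = (f_lo - m_end) / (f_end - m_end)
            alpha = rng.uniform(0.0, alpha_max)
            data[mixed] = m_end + alpha * (f_end - m_end)

    if spec.noise_sd > 0:
        # The printed per-tissue ranges bracket *measured* signal, so the
        # rendered intensities must stay inside them: noise jitters each
        # voxel within its class range (mixed voxels stay below the fat
        # floor), never across a class boundary.
        noise = rng.normal(0.0, spec.noise_sd, size=spec.shape)
        pure_muscle, pure_fat = muscle & ~mixed, fat & ~mixed
        data[pure_muscle] = np.clip(data[pure_muscle] + noise[pure_muscle], m_lo, m_hi)
        data[pure_fat] = np.clip(data[pure_fat] + noise[pure_fat], f_lo, f_hi)
        if n_mixed:
            sub_floor = np.nextafter(f_lo, 0.0)
            data[mixed] = np.clip(data[mixed] + noise[mixed], m_lo, sub_floor)

    volume = ImageVolume(
        data=data,
        spacing=spec.spacing,
        meta={"phantom_seed": spec.seed, "target_ftmp": spec.target_ftmp},
    )
    truth = PhantomTruth(
        muscle_voxels=n_roi - n_fat, fat_voxels=n_fat, mixed_voxels=n_mixed
    )
    return volume, RoiMask(mask=roi), truth


def _truncated_normal(rng, mean: float, sd: float, lower: float = 0.0) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    return lower


def spec_for_muscle_volume(
    muscle_mm3: float,
    target_ftmp: float,
    seed: int,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    **kwargs,
) -> PhantomSpec:
    """Build a spec whose ellipsoid ROI holds ~muscle_mm3 of muscle.

    The ellipsoid (2:1:1 aspect, long axis in-plane) is sized so its
    volume is muscle + fat at the requested FTMP.
    """
    roi_mm3 = muscle_mm3 * (1.0 + target_ftmp / 100.0)
    # (4/3) * pi * (2k) * k * k = roi_mm3
    k = (3.0 * roi_mm3 / (8.0 * np.pi)) ** (1.0 / 3.0)
    semi_mm = (2.0 * k, k, k)
    semiaxes = tuple(a / s for a, s in zip(semi_mm, spacing))
    shape = tuple(int(np.ceil(2 * a)) + 5 for a in semiaxes)
    return PhantomSpec(
        target_ftmp=target_ftmp,
        seed=seed,
        shape=shape,  # type: ignore[arg-type]
        spacing=spacing,
        roi_semiaxes=semiaxes,  # type: ignore[arg-type]
        **kwargs,
    )


def generate_cohort(
    preset: str, n: int, seed: int, **spec_kwargs
) -> list[tuple[PhantomSpec, SpecimenRecord]]:
    """Draw ``n`` specimen recipes for one study arm.

    Per-specimen true FTMP ~ Normal(group mean, group SD) truncated at 0
    and ROI size scaled to the group muscle-volume distribution; muscle
    weight is volume times a tissue density with small lognormal scatter,
    so weight-vs-volume correlation is built in. Deterministic under
    ``seed``.
    """
    if preset not in COHORT_PRESETS:
        raise PhantomError(f"preset must be one of {list(COHORT_PRESETS)}")
    if n < 1:
        raise PhantomError("n must be >= 1")
    params = COHORT_PRESETS[preset]
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ftmp = _truncated_normal(rng, *params["ftmp"])
        muscle_mm3 = _truncated_normal(rng, *params["muscle_mm3"], lower=1000.0)
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = spec_for_muscle_volume(muscle_mm3, ftmp, child_seed, **spec_kwargs)
        weight = _MUSCLE_DENSITY_G_PER_MM3 * muscle_mm3 * float(
            np.exp(rng.normal(0.0, _WEIGHT_SCATTER_SD))
        )
        record = SpecimenRecord(
            specimen_id=f"{preset}_{i + 1:02d}",
            group=preset,
            body_weight_kg=_truncated_normal(rng, 4.0, 0.3, lower=3.0),
            muscle_weight_g=weight,
        )
        out.append((spec, record))
    return out


# ---------------------------------------------------------------------------
# Synthetic stained sections

_EOSIN_BG = np.array([235, 185, 195])
_NUCLEUS = np.array([95, 85, 160])
_DROPLET = np.array([200, 40, 45])


def _disk_offsets(radius: int) -> np.ndarray:
    if radius == 0:
        return np.array([[0, 0]])
    r = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    keep = yy**2 + xx**2 <= radius**2
    return np.stack([yy[keep], xx[keep]], axis=1)


def generate_section(
    truth_fraction: float,
    shape: tuple[int, int] = (256, 256),
    droplet_radius_px: int = 4,
    seed: int = 0,
    nucleus_density: float = 0.01,
) -> tuple[SectionImage, np.ndarray]:
    """Render a stained-section image with a known lipid area fraction.

    Non-overlapping red droplets are painted until they cover exactly the
    pixel count implied by ``truth_fraction`` (disks first, then single
    pixels), on an eosin-pink background with blue nuclei speckle. Red
    pixels satisfy the default HSB lipid windows; background and nuclei
    do not. Returns the image and the boolean ground-truth lipid mask.
    """
    if not (0.0 <= truth_fraction <= 40.0):
        raise PhantomError(
            "truth_fraction must be in [0, 40] percent for non-overlap packing"
        )
    rng = np.random.default_rng(seed)
    h, w = shape
    n_total = h * w
    target = int(round(truth_fraction / 100.0 * n_total))

    lipid = np.zeros(shape, dtype=bool)
    painted = 0
    radius = int(droplet_radius_px)
    attempts = 0
    while painted < target:
        offs = _disk_offsets(radius)
        disk_px = len(offs)
        if disk_px > target - painted or attempts > 200 * max(1, target):
            if radius > 0:
                radius -= 1
                attempts = 0
                continue
            raise PhantomError("droplet packing infeasible at this fraction/shape")
        cy = int(rng.integers(radius, h - radius)) if h > 2 * radius else radius
        cx = int(rng.integers(radius, w - radius)) if w > 2 * radius else radius
        ys, xs = offs[:, 0] + cy, offs[:, 1] + cx
        attempts += 1
        if lipid[ys, xs].any():
            continue
        lipid[ys, xs] = True
        painted += disk_px

    img = np.empty((h, w, 3), dtype=np.int16)
    img[...] = _EOSIN_BG
    img += rng.integers(-6, 7, size=img.shape, dtype=np.int16)

    n_nuclei = int(round(nucleus_density * n_total))
    if n_nuclei:
        free = np.flatnonzero(~lipid.ravel())
        nuc = rng.choice(free, size=min(n_nuclei, len(free)), replace=False)
        nuc_yx = np.unravel_index(nuc, shape)
        img[nuc_yx] = _NUCLEUS + rng.integers(-6, 7, size=(len(nuc), 3), dtype=np.int16)

    n_lipid = int(lipid.sum())
    if n_lipid:
        img[lipid] = _DROPLET + rng.integers(-8, 9, size=(n_lipid, 3), dtype=np.int16)

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return SectionImage(pixels=pixels), lipid


# ---------------------------------------------------------------------------
# Calibration fixture

def generate_intensity_samples(
    seed: int = 0,
    n_specimens: int = 18,
    points_per_specimen: int = 5,
    muscle_range: tuple[float, float] = MUSCLE_RANGE_DEFAULT,
    fat_range: tuple[float, float] = FAT_RANGE_DEFAULT,
) -> list[IntensitySample]:
    """Labelled probe samples emulating the calibration protocol.

    ``n_specimens * points_per_specimen`` samples split as evenly as
    possible between muscle and fat (45/45 at the defaults), drawn as
    uniform integers within the observed pure-tissue ranges with all four
    range endpoints forced present.
    """
    rng = np.random.default_rng(seed)
    total = n_specimens * points_per_specimen
    n_muscle = total // 2
    labels = ["muscle"] * n_muscle + ["fat"] * (total - n_muscle)
    rng.shuffle(labels)

    samples: list[IntensitySample] = []
    values = {
        "muscle": rng.integers(int(muscle_range[0]), int(muscle_range[1]) + 1, size=total),
        "fat": rng.integers(int(fat_range[0]), int(fat_range[1]) + 1, size=total),
    }
    counters = {"muscle": 0, "fat": 0}
    endpoint_plan = {
        "muscle": [muscle_range[0], muscle_range[1]],
        "fat": [fat_range[0], fat_range[1]],
    }
    for i, label in enumerate(labels):
        k = counters[label]
        if k < len(endpoint_plan[label]):
            value = endpoint_plan[label][k]
        else:
            value = float(values[label][i])
        counters[label] += 1
        specimen = f"S{(i // points_per_specimen) + 1:02d}"
        samples.append(IntensitySample(value=float(value), label=label, specimen_id=specimen))
    return samples
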