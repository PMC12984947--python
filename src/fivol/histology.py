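"""Histomorphometry of Oil Red O / H&E stained sections.

Two independent 2D measurements per section image:

* **Fat area fraction** — pixels are flagged as lipid when their hue falls
  in a red window, with saturation and brightness above configurable
  floors, in HSB (= HSV) color space. Oil Red O is a red chromogen, so the
  default windows sit around 0 degrees on the hue circle.
* **Muscle area fraction** — the image is split into RGB channels and the
  green channel binarised (eosin absorbs green, so muscle fibers are the
  *dark* side); the default threshold is Otsu's, with a fixed threshold
  available.

Fractions are percentages of all analysed pixels; they need not sum to
100 because background (unstained) area exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .core import FivolError

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


class SectionFormatError(FivolError):
    pass


@dataclass
class SectionImage:
    """A 2D RGB section capture (8-bit per channel)."""

    pixels: np.ndarray  # H x W x 3 uint8
    magnification: str = "x200"
    section_id: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise SectionFormatError(
                f"expected an RGB image (H, W, 3), got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise SectionFormatError("empty image")
        self.pixels = self.pixels.astype(np.uint8)


@dataclass
class ColorThresholdConfig:
    """HSB lipid windows and green-channel muscle binarisation settings.

    Hue windows are degree intervals on [0, 360); a [335, 360] window
    together with [0, 25] covers the red wrap-around. The defaults are
    explicit so every report records exactly what was thresholded.
    """

    hue_windows: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 25.0), (335.0, 360.0)]
    )
    sat_min: float = 0.30
    bright_min: float = 0.20
    muscle_channel: str = "green"
    muscle_threshold_mode: str = "otsu"  # "otsu" | "fixed"
    muscle_fixed_threshold: int = 128

    def __post_init__(self) -> None:
        for lo, hi in self.hue_windows:
            if not (0 <= lo <= hi <= 360):
                raise ValueError(f"hue window [{lo}, {hi}] outside [0, 360]")
        if not (0 <= self.sat_min <= 1 and 0 <= self.bright_min <= 1):
            raise ValueError("sat_min and bright_min must be in [0, 1]")
        if self.muscle_channel not in _CHANNELS:
            raise ValueError(f"muscle_channel must be one of {list(_CHANNELS)}")
        if self.muscle_threshold_mode not in ("otsu", "fixed"):
            raise ValueError("muscle_threshold_mode must be 'otsu' or 'fixed'")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "hue_windows": [list(w) for w in self.hue_windows],
                    "sat_min": self.sat_min,
                    "bright_min": self.bright_min,
                    "muscle_channel": self.muscle_channel,
                    "muscle_threshold_mode": self.muscle_threshold_mode,
                    "muscle_fixed_threshold": self.muscle_fixed_threshold,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ColorThresholdConfig":
        d = json.loads(Path(path).read_text())
        d["hue_windows"] = [tuple(w) for w in d["hue_windows"]]
        return cls(**d)


@dataclass
class SectionQuantification:
    """Area fractions (percent of analysed pixels) for one section read."""

    fat_fraction: Optional[float] = None
    muscle_fraction: Optional[float] = None
    analyzed_pixels: int = 0
    no_contrast_flag: bool = False
    section_id: str = ""
    read: int = 1


@dataclass
class SpecimenHistology:
    """Per-specimen aggregate over all retained section reads."""

    sections: list[SectionQuantification]
    fat_fraction_mean: float
    muscle_fraction_mean: float


def lipid_mask_hsb(image: SectionImage, config: ColorThresholdConfig) -> np.ndarray:
    """Boolean lipid mask: hue in any window AND sat >= sat_min AND bright >= bright_min."""
    hsv = rgb2hsv(image.pixels)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    bright = hsv[..., 2]
    in_hue = np.zeros(hue_deg.shape, dtype=bool)
    for lo, hi in config.hue_windows:
        in_hue |= (hue_deg >= lo) & (hue_deg <= hi)
    return in_hue & (sat >= config.sat_min) & (bright >= config.bright_min)


def fat_fraction_hsb(
    image: SectionImage, config: ColorThresholdConfig | None = None
) -> SectionQuantification:
    """Percent of pixels flagged as Oil Red O lipid by HSB thresholding."""
    if config is None:
        config = ColorThresholdConfig()
    mask = lipid_mask_hsb(image, config)
    n = mask.size
    return SectionQuantification(
        fat_fraction=100.0 * mask.sum() / n,
        analyzed_pixels=n,
        section_id=image.section_id,
    )


def muscle_fraction_channel(
    image: SectionImage, config: ColorThresholdConfig | None = None
) -> SectionQuantification:
    """Percent of pixels at or below threshold in the configured channel.

    Eosin-stained fibers are dark in green, so muscle is the below-threshold
    side. A constant channel under Otsu has no contrast: the result is 0%
    with ``no_contrast_flag`` set.
    """
    if config is None:
        config = ColorThresholdConfig()
    channel = image.pixels[..., _CHANNELS[config.muscle_channel]]
    n = channel.size
    if config.muscle_threshold_mode == "otsu":
        if channel.min() == channel.max():
            return SectionQuantification(
                muscle_fraction=0.0,
                analyzed_pixels=n,
                no_contrast_flag=True,
                section_id=image.section_id,
            )
        thr = threshold_otsu(channel)
    else:
        thr = config.muscle_fixed_threshold
    return SectionQuantification(
        muscle_fraction=100.0 * (channel <= thr).sum() / n,
        analyzed_pixels=n,
        section_id=image.section_id,
    )


def quantify_section(
    image: SectionImage, config: ColorThresholdConfig | None = None, read: int = 1
) -> SectionQuantification:
    """Both fractions for one read of one section."""
    if config is None:
        config = ColorThresholdConfig()
    fat = fat_fraction_hsb(image, config)
    mus = muscle_fraction_channel(image, config)
    return SectionQuantification(
        fat_fraction=fat.fat_fraction,
        muscle_fraction=mus.muscle_fraction,
        analyzed_pixels=fat.analyzed_pixels,
        no_contrast_flag=mus.no_contrast_flag,
        section_id=image.section_id,
        read=read,
    )


def aggregate_specimen(
    sections: Sequence[SectionQuantification], reads_per_section: int = 2
) -> SpecimenHistology:
    """Arithmetic mean over all section reads; individual reads retained.

    The study protocol reads each of 10 sections twice at separated time
    points; the specimen value is the plain mean over all reads.
    """
    if not sections:
        raise FivolError("at least one section quantification required")
    fat_vals = [s.fat_fraction for s in sections if s.fat_fraction is not None]
    mus_vals = [s.muscle_fraction for s in sections if s.muscle_fraction is not None]
    return SpecimenHistology(
        sections=list(sections),
        fat_fraction_mean=float(np.mean(fat_vals)) if fat_vals else float("nan"),
        muscle_fraction_mean=float(np.mean(mus_vals)) if mus_vals else float("nan"),
    )


def load_section(path: str | Path, specimen_id: str = "", section_id: str = "") -> SectionImage:
    """Read a TIFF/PNG section capture as RGB."""
    with Image.open(path) as img:
        if img.mode in ("L", "I", "I;16", "F"):
            raise SectionFormatError(
                f"{Path(path).name} is grayscale; use the muscle channel pathway "
                "on RGB captures instead"
            )
        arr = np.asarray(img.convert("RGB"))
    return SectionImage(pixels=arr, specimen_id=specimen_id, section_id=section_id or Path(path).stem)


def save_section(image: SectionImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(str(path))
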