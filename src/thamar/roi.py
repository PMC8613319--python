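"""ROI-based image-quality measurement.

A standardized template of circular regions of interest — one per pellet
(L1..L9, R1..R9) plus one background ROI (BG) in artifact-free water — is
applied to a coronal slice.  Per ROI the mean HU, the noise (standard
deviation of HU within the ROI), SNR = mean/noise and
CNR = (pellet - background) / mean(pellet noise, background noise) are
reported.  CNR is signed: under severe artifacts a pellet can fall below the
water background, and the sign carries that information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .phantom import PhantomSpec, SliceImage

__all__ = [
    "ROI",
    "ROITemplate",
    "ROIMeasurement",
    "ROIError",
    "measure_rois",
    "snr",
    "cnr",
    "rose_flag",
    "default_template",
    "DEFAULT_ROI_DIAMETER_MM",
    "BACKGROUND_LABEL",
]

#: Default ROI diameter.  The physical 6.75 mm keeps the ROI well inside the
#: 10 mm pellets and thereby limits partial-volume contamination; at
#: FOV 330 mm / matrix 512 this is ~10.5 px (>= 80 pixels per ROI).
DEFAULT_ROI_DIAMETER_MM = 6.75

BACKGROUND_LABEL = "BG"

#: Background ROI centre (mm): homogeneous water below the femoral stems,
#: outside the streak corridors.
BACKGROUND_CENTER_MM = (0.0, -120.0)


class ROIError(ValueError):
    """An ROI that cannot be measured (off image or too few pixels)."""


@dataclass(frozen=True)
class ROI:
    label: str
    x_mm: float
    y_mm: float
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM


@dataclass(frozen=True)
class ROITemplate:
    """A set of circular ROIs in image-centre mm coordinates."""

    rois: tuple[ROI, ...]
    frame: str = "center_mm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        if any(r.diameter_mm <= 0 for r in self.rois):
            raise ValueError("ROI diameters must be positive")

    @property
    def background(self) -> ROI | None:
        for r in self.rois:
            if r.label == BACKGROUND_LABEL:
                return r
        return None

    def validate_standard(self) -> None:
        """Require the full study layout: 18 pellet ROIs plus exactly one BG."""
        n_bg = sum(1 for r in self.rois if r.label == BACKGROUND_LABEL)
        if n_bg != 1:
            raise ValueError("template must contain exactly one BG ROI")
        pellet = sorted(r.label for r in self.rois if r.label != BACKGROUND_LABEL)
        expected = sorted(f"{s}{i}" for s in "LR" for i in range(1, 10))
        if pellet != expected:
            raise ValueError("template must contain the 18 pellet ROIs L1..R9")

    @classmethod
    def from_csv(cls, path) -> "ROITemplate":
        table = pd.read_csv(path)
        rois = [
            ROI(str(r.label), float(r.x_mm), float(r.y_mm), float(r.diameter_mm))
            for r in table.itertuples()
        ]
        return cls(tuple(rois))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "label": r.label,
                    "x_mm": r.x_mm,
                    "y_mm": r.y_mm,
                    "diameter_mm": r.diameter_mm,
                }
                for r in self.rois
            ]
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ROIMeasurement:
    label: str
    mean_hu: float
    noise_hu: float
    snr: float
    cnr: float
    n_pixels: int


def default_template(
    spec: PhantomSpec, diameter_mm: float | None = None
) -> ROITemplate:
    """Standard template: one ROI per pellet centre plus the background ROI.

    ``diameter_mm=None`` uses the 6.75 mm default; pass
    ``15 * spec.pixel_spacing_mm`` for a 15-pixel ROI instead.
    """
    d = DEFAULT_ROI_DIAMETER_MM if diameter_mm is None else float(diameter_mm)
    rois = [ROI(p.pellet_id, p.x_mm, p.y_mm, d) for p in spec.pellet_layout]
    rois.append(ROI(BACKGROUND_LABEL, *BACKGROUND_CENTER_MM, d))
    return ROITemplate(tuple(rois))


def snr(mean_hu: float, noise_hu: float) -> float:
    """Signal-to-noise ratio: ROI mean divided by ROI noise.

    Zero noise yields NaN (an undefined-value signal), never infinity.
    """
    if noise_hu < 0:
        raise ValueError("noise must be non-negative")
    if noise_hu == 0:
        return math.nan
    return mean_hu / noise_hu


def cnr(
    pellet_mean: float, pellet_noise: float, bg_mean: float, bg_noise: float
) -> float:
    """Signed contrast-to-noise ratio vs the background ROI.

    ``(pellet - background) / ((pellet noise + background noise) / 2)``;
    NaN if both noises are zero.
    """
    if pellet_noise < 0 or bg_noise < 0:
        raise ValueError("noise must be non-negative")
    denom = 0.5 * (pellet_noise + bg_noise)
    if denom == 0:
        return math.nan
    return (pellet_mean - bg_mean) / denom


def rose_flag(cnr_value: float, threshold: float = 4.0) -> bool:
    """Rose detectability criterion: CNR must strictly exceed the threshold.

    The threshold is conventionally in the 3-5 range.
    """
    if not 3.0 <= threshold <= 5.0:
        raise ValueError("Rose threshold conventionally lies in [3, 5]")
    return bool(cnr_value > threshold)


def _roi_pixels(image: SliceImage, roi: ROI) -> np.ndarray:
    n = image.matrix_size
    dx, dy = image.pixel_spacing_mm
    half_x = n * dx / 2.0
    half_y = n * dy / 2.0
    r = roi.diameter_mm / 2.0
    if (
        roi.x_mm - r < -half_x
        or roi.x_mm + r > half_x
        or roi.y_mm - r < -half_y
        or roi.y_mm + r > half_y
    ):
        raise ROIError(f"ROI {roi.label!r} extends outside the image")
    x, y = image.grid_mm()
    # pixel-centre membership, strict inequality (half-open, centre-inclusive)
    member = (x - roi.x_mm) ** 2 + (y - roi.y_mm) ** 2 < r**2
    vals = image.pixels[member]
    if vals.size < 9:
        raise ROIError(
            f"ROI {roi.label!r} covers only {vals.size} pixels; "
            "pixel spacing too coarse for a reliable statistic"
        )
    return vals


def measure_rois(
    image: SliceImage,
    template: ROITemplate,
    sd_mode: str = "population",
) -> list[ROIMeasurement]:
    """Measure mean, noise, SNR and CNR for every ROI of the template.

    Noise is the population standard deviation by default (``sd_mode =
    "sample"`` switches to the n-1 estimator, matching ImageJ).  CNR of the
    background ROI against itself is reported as 0.
    """
    if sd_mode not in ("population", "sample"):
        raise ValueError("sd_mode must be 'population' or 'sample'")
    ddof = 0 if sd_mode == "population" else 1

    stats: dict[str, tuple[float, float, int]] = {}
    for roi in template.rois:
        vals = _roi_pixels(image, roi)
        mean = float(vals.mean())
        noise = float(vals.std(ddof=ddof))
        # constant fields must report exactly zero noise, not accumulation eps
        if noise < 1e-9 * max(1.0, abs(mean)):
            noise = 0.0
        stats[roi.label] = (mean, noise, int(vals.size))

    bg = template.background
    bg_stats = stats[bg.label] if bg is not None else None

    out: list[ROIMeasurement] = []
    for roi in template.rois:
        mean, noise, n_px = stats[roi.label]
        if bg_stats is not None:
            c = cnr(mean, noise, bg_stats[0], bg_stats[1])
        else:
            c = math.nan
        out.append(
            ROIMeasurement(
                label=roi.label,
                mean_hu=mean,
                noise_hu=noise,
                snr=snr(mean, noise),
                cnr=c,
                n_pixels=n_px,
            )
        )
    return out


def measurements_frame(measurements: Iterable[ROIMeasurement]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of ROI measurements."""
    return pd.DataFrame(
        [
            {
                "label": m.label,
                "mean_hu": m.mean_hu,
                "noise_hu": m.noise_hu,
                "snr": m.snr,
                "cnr": m.cnr,
                "n_pixels": m.n_pixels,
            }
            for m in measurements
        ]
    )
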