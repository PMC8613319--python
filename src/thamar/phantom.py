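"""Digital total-hip-arthroplasty (THA) phantom.

A PMMA shell filled with water carries 18 hydroxyapatite-surrogate pellets
(9 per side, placed at the acetabular DeLee/Charnley zones and the femoral
Gruen zones) and optionally one or two simplified hip prostheses
(polyethylene or metal cup, ceramic or metal head, metal stem).  The module
rasterizes one coronal slice of this phantom onto a square HU grid; the
result is the artifact-free ground truth that the simulated CT chain
(projection, corruption, reconstruction) subsequently degrades.

Coordinates are millimetres with the origin at the image centre, x to the
right and y upward; pixel (row, col) maps to
``x = (col - (N-1)/2) * dx`` and ``y = ((N-1)/2 - row) * dy``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "AIR_HU",
    "PELLET_HU",
    "DEFAULT_MATERIAL_HU",
    "PelletSite",
    "Severity",
    "PhantomSpec",
    "SliceImage",
    "GeometryError",
    "default_pellet_layout",
    "rasterize_phantom",
]

AIR_HU = -1000.0

#: Nominal pellet HU per reconstruction family: the all-pellet reference
#: means measured without prostheses (conventional 140 kVp vs 130 keV VMI;
#: the VMI value is lower because attenuation of the calcium surrogate
#: drops at high virtual energy).
PELLET_HU = {"conventional": 248.4, "vmi130": 150.4}

#: Nominal HU of phantom and implant materials.  Only water (exactly 0) and
#: the ordering of the metals (CoCrMo densest, hence worst artifacts) carry
#: meaning; individual metal values are far beyond the 12-bit clinical range
#: and act as artifact sources rather than measurands.
DEFAULT_MATERIAL_HU = {
    "water": 0.0,
    "pmma": 120.0,
    "UHMWPE": 80.0,
    "TiAlV": 8000.0,
    "ZTA": 10000.0,
    "CoCrMo": 12000.0,
}

#: Threshold above which a voxel counts as metal for sinogram metal-trace
#: purposes.  UHMWPE (80 HU) is deliberately below it: polyethylene cups do
#: not cause streaks.
METAL_HU_THRESHOLD = 2500.0

#: Attenuation scale of metals on 130 keV virtual monochromatic images.
#: High-keV VMI suppresses metal attenuation (the mechanism behind its
#: artifact reduction): implant HU drops to roughly 45% of the
#: polychromatic value, so far fewer rays are starved or hardened.
VMI_METAL_FACTOR = 0.45

PROSTHESIS_CONFIGS = ("none", "unilateral", "bilateral")

#: (cup, head, stem) materials per configuration and side.  The unilateral
#: prosthesis sits on the right; the bilateral setup adds a deliberately
#: artifact-aggravating all-CoCrMo cup/head on the left.
DEFAULT_COMPONENT_MATERIALS = {
    "unilateral": {"R": ("UHMWPE", "ZTA", "TiAlV")},
    "bilateral": {
        "R": ("UHMWPE", "ZTA", "CoCrMo"),
        "L": ("CoCrMo", "CoCrMo", "TiAlV"),
    },
}


class GeometryError(ValueError):
    """Raised when phantom elements overlap or fall outside the body."""


@dataclass(frozen=True)
class PelletSite:
    """One cylindrical pellet: side 'L'/'R', 1-based zone index, centre in mm."""

    side: str
    index: int
    x_mm: float
    y_mm: float

    @property
    def pellet_id(self) -> str:
        return f"{self.side}{self.index}"


@dataclass(frozen=True)
class Severity:
    """Artifact-severity parameters of the corruption model.

    beta
        Beam-hardening coefficient (1/mm^2): a ray whose metal path length is
        m has its line integral depressed by ``beta * m**2``.
    i0
        Incident photon count per detector bin; photon starvation is Poisson
        noise on ``i0 * exp(-p)``.  ``math.inf`` disables noise.
    gamma
        Bright-streak amplitude for the 130 keV VMI emulation (added line
        integral per mm of metal path on a subset of view angles).
    bh_path_cap_mm
        Saturation path length: beam hardening grows quadratically only up
        to this metal path and is flat beyond it, mirroring the physical
        exhaustion of the low-energy spectrum on long metal paths.
    """

    beta: float = 3.0e-3
    i0: float = 3.3e7
    gamma: float = 2.0e-2
    bh_path_cap_mm: float = 45.0

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")
        if not self.i0 > 0:
            raise ValueError("i0 must be positive")
        if not self.bh_path_cap_mm > 0:
            raise ValueError("bh_path_cap_mm must be positive")


def default_pellet_layout() -> list[PelletSite]:
    """Packaged default pellet coordinates, mirrored left/right.

    Pellets 1-2 flank the acetabular cup (DeLee/Charnley zones) and pellets
    3-9 surround the femoral stem (Gruen zones); the even-indexed femoral
    pellets lie medially, i.e. between the implants when both hips carry a
    prosthesis, which is where bilateral streaks concentrate.
    """
    with resources.files("thamar.data").joinpath("pellet_layout.csv").open() as fh:
        table = pd.read_csv(fh)
    return [
        PelletSite(str(r.side), int(r.index), float(r.x_mm), float(r.y_mm))
        for r in table.itertuples()
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, materials and artifact severity of one simulated acquisition."""

    field_of_view_mm: float = 330.0
    matrix_size: int = 512
    body_width_mm: float = 320.0
    body_depth_mm: float = 290.0
    body_corner_radius_mm: float = 40.0
    shell_thickness_mm: float = 10.0
    pellet_diameter_mm: float = 10.0
    pellet_layout: tuple[PelletSite, ...] = None  # type: ignore[assignment]
    prosthesis_config: str = "none"
    component_materials: dict[str, tuple[str, str, str]] = None  # type: ignore[assignment]
    material_hu_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MATERIAL_HU))
    severity: Severity = field(default_factory=Severity)
    n_angles: int = 720
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pellet_layout is None:
            object.__setattr__(self, "pellet_layout", tuple(default_pellet_layout()))
        else:
            object.__setattr__(self, "pellet_layout", tuple(self.pellet_layout))
        if self.prosthesis_config not in PROSTHESIS_CONFIGS:
            raise ValueError(f"unknown prosthesis_config {self.prosthesis_config!r}")
        if self.component_materials is None:
            object.__setattr__(
                self,
                "component_materials",
                {
                    side: mats
                    for side, mats in DEFAULT_COMPONENT_MATERIALS.get(
                        self.prosthesis_config, {}
                    ).items()
                },
            )
        if self.material_hu_map.get("water", 0.0) != 0.0:
            raise ValueError("material_hu_map must assign water = 0 HU")
        if self.matrix_size < 32:
            raise ValueError("matrix_size too small")

    @property
    def pixel_spacing_mm(self) -> float:
        return self.field_of_view_mm / self.matrix_size

    def with_config(self, prosthesis_config: str) -> "PhantomSpec":
        """Same phantom with a different prosthesis configuration."""
        return replace(
            self, prosthesis_config=prosthesis_config, component_materials=None
        )


@dataclass
class SliceImage:
    """A 2-D coronal HU image with pixel spacing and provenance."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    condition: tuple[str, str, str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("SliceImage requires a square 2-D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("SliceImage pixels must be finite")

    @property
    def matrix_size(self) -> int:
        return self.pixels.shape[0]

    def grid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-centre coordinate grids in mm."""
        n = self.matrix_size
        dx, dy = self.pixel_spacing_mm
        c = (n - 1) / 2.0
        cols = (np.arange(n) - c) * dx
        rows = (c - np.arange(n)) * dy
        return np.meshgrid(cols, rows)


# ---------------------------------------------------------------------------
# Signed-distance primitives (negative inside).  Antialiasing converts the
# signed distance to a pixel coverage fraction, so painted edges are soft
# only within ~1 px of each boundary.


def _sd_rounded_rect(x, y, half_w, half_h, radius):
    qx = np.abs(x) - (half_w - radius)
    qy = np.abs(y) - (half_h - radius)
    outside = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
    inside = np.minimum(np.maximum(qx, qy), 0.0)
    return outside + inside - radius


def _sd_disk(x, y, cx, cy, r):
    return np.hypot(x - cx, y - cy) - r


def _sd_box(x, y, cx, cy, half_w, half_h):
    qx = np.abs(x - cx) - half_w
    qy = np.abs(y - cy) - half_h
    outside = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
    inside = np.minimum(np.maximum(qx, qy), 0.0)
    return outside + inside


def _sd_half_ring(x, y, cx, cy, r_mid, half_width):
    """Upper half of an annulus: hemispherical acetabular cup in cross-section."""
    ring = np.abs(np.hypot(x - cx, y - cy) - r_mid) - half_width
    return np.maximum(ring, cy - y)


# Prosthesis component geometry (mm) for the side at x = sign * _HIP_X.
_HIP_X = 95.0
_CUP = dict(cy=80.0, r_mid=24.0, half_width=3.0)
_HEAD = dict(cy=76.0, r=16.0)
_STEM = dict(cy=20.0, half_w=6.0, half_h=27.5)


def _prosthesis_sdfs(spec: PhantomSpec) -> list[tuple[str, str, Callable]]:
    """(component-name, material, sdf(x, y)) for every installed component."""
    out: list[tuple[str, str, Callable]] = []
    for side, (cup_m, head_m, stem_m) in sorted(spec.component_materials.items()):
        sgn = 1.0 if side == "R" else -1.0
        cx = sgn * _HIP_X
        out.append(
            (
                f"{side}_cup",
                cup_m,
                lambda x, y, cx=cx: _sd_half_ring(
                    x, y, cx, _CUP["cy"], _CUP["r_mid"], _CUP["half_width"]
                ),
            )
        )
        out.append(
            (
                f"{side}_head",
                head_m,
                lambda x, y, cx=cx: _sd_disk(x, y, cx, _HEAD["cy"], _HEAD["r"]),
            )
        )
        out.append(
            (
                f"{side}_stem",
                stem_m,
                lambda x, y, cx=cx: _sd_box(
                    x, y, cx, _STEM["cy"], _STEM["half_w"], _STEM["half_h"]
                ),
            )
        )
    return out


def _prosthesis_clearance_mm(spec: PhantomSpec, x: float, y: float) -> float:
    """Distance from (x, y) to the nearest prosthesis surface (inf if none)."""
    best = math.inf
    xs = np.asarray([x])
    ys = np.asarray([y])
    for _name, _mat, sdf in _prosthesis_sdfs(spec):
        best = min(best, float(sdf(xs, ys)[0]))
    return best


def validate_geometry(spec: PhantomSpec) -> None:
    """Check the pellet layout against the body and prosthesis geometry."""
    r = spec.pellet_diameter_mm / 2.0
    half_w = spec.body_width_mm / 2.0
    half_h = spec.body_depth_mm / 2.0
    interior_margin = spec.shell_thickness_mm
    for i, p in enumerate(spec.pellet_layout):
        d_body = float(
            _sd_rounded_rect(
                np.asarray([p.x_mm]),
                np.asarray([p.y_mm]),
                half_w,
                half_h,
                spec.body_corner_radius_mm,
            )[0]
        )
        if d_body > -(r + interior_margin):
            raise GeometryError(
                f"pellet {p.pellet_id} does not fit inside the water bath"
            )
        if _prosthesis_clearance_mm(spec, p.x_mm, p.y_mm) < r:
            raise GeometryError(
                f"pellet {p.pellet_id} overlaps a prosthesis component"
            )
        for q in spec.pellet_layout[i + 1 :]:
            if math.hypot(p.x_mm - q.x_mm, p.y_mm - q.y_mm) < spec.pellet_diameter_mm:
                raise GeometryError(
                    f"pellets {p.pellet_id} and {q.pellet_id} overlap"
                )


def _paint(img: np.ndarray, sd: np.ndarray, hu: float, px: float) -> None:
    """Composite a shape onto the image with 1-px antialiased coverage."""
    cov = np.clip(0.5 - sd / px, 0.0, 1.0)
    np.copyto(img, img * (1.0 - cov) + hu * cov)


def rasterize_phantom(spec: PhantomSpec, reconstruction: str = "conventional") -> SliceImage:
    """Artifact-free ground-truth coronal slice for one reconstruction family.

    Water is exactly 0 HU, air exactly -1000 HU; pellets take the
    reconstruction family's nominal pellet HU; edges are antialiased within
    one pixel of each boundary only.
    """
    if reconstruction not in PELLET_HU:
        raise ValueError(f"unknown reconstruction family {reconstruction!r}")
    validate_geometry(spec)

    n = spec.matrix_size
    px = spec.pixel_spacing_mm
    img = np.full((n, n), AIR_HU)
    holder = SliceImage(img, (px, px))
    x, y = holder.grid_mm()

    hu = spec.material_hu_map
    half_w = spec.body_width_mm / 2.0
    half_h = spec.body_depth_mm / 2.0
    body_sd = _sd_rounded_rect(x, y, half_w, half_h, spec.body_corner_radius_mm)
    _paint(img, body_sd, hu["pmma"], px)

    t = spec.shell_thickness_mm
    interior_sd = _sd_rounded_rect(
        x, y, half_w - t, half_h - t, max(spec.body_corner_radius_mm - t, 1.0)
    )
    _paint(img, interior_sd, hu["water"], px)

    pellet_hu = PELLET_HU[reconstruction]
    r = spec.pellet_diameter_mm / 2.0
    for p in spec.pellet_layout:
        _paint(img, _sd_disk(x, y, p.x_mm, p.y_mm, r), pellet_hu, px)

    metal_scale = VMI_METAL_FACTOR if reconstruction == "vmi130" else 1.0
    for _name, material, sdf in _prosthesis_sdfs(spec):
        value = hu[material]
        if value > METAL_HU_THRESHOLD:
            value *= metal_scale
        _paint(img, sdf(x, y), value, px)

    return SliceImage(
        img,
        (px, px),
        condition=(spec.prosthesis_config, reconstruction, "truth"),
        provenance=f"rasterized ground truth, seed={spec.seed}",
    )


def metal_mask(image: SliceImage, threshold: float = METAL_HU_THRESHOLD) -> np.ndarray:
    """Boolean mask of metal voxels (streak sources) in an HU image."""
    return image.pixels > threshold


def water_mask(truth: SliceImage, margin_px: int = 3) -> np.ndarray:
    """Water voxels of a ground-truth slice, eroded away from all boundaries."""
    from scipy import ndimage

    core = np.abs(truth.pixels) < 0.5
    return ndimage.binary_erosion(core, iterations=margin_px)
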