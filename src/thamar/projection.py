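"""Parallel-beam projection and filtered back projection (FBP).

HU images are converted to linear attenuation via
``mu = MU_WATER_MM * (1 + HU / 1000)`` so that air projects to exactly zero,
forward projected with the Radon transform (scikit-image), and reconstructed
with ramp-filtered back projection.  The sinogram carries, alongside the
line integrals, the metal path length of every ray; downstream artifact
emulation (beam hardening, photon starvation, O-MAR inpainting, VMI bright
streaks) operates on that trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import iradon, radon

from .phantom import METAL_HU_THRESHOLD, SliceImage, metal_mask

__all__ = ["MU_WATER_MM", "Sinogram", "forward_project", "reconstruct_fbp"]

#: Linear attenuation of water (1/mm) at the effective beam energy.
MU_WATER_MM = 0.0192

#: Metal path length (mm) above which a ray belongs to the metal trace.
METAL_TRACE_MIN_MM = 0.5


def hu_to_mu(hu: np.ndarray) -> np.ndarray:
    return MU_WATER_MM * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    return (np.asarray(mu, dtype=float) / MU_WATER_MM - 1.0) * 1000.0


@dataclass
class Sinogram:
    """Line integrals over uniform view angles in [0, pi).

    values
        (n_angles, n_bins) dimensionless line integrals of mu (1/mm * mm).
    angles
        View angles in radians.
    metal_trace
        Boolean mask of rays whose path crosses metal.
    metal_pathlen_mm
        Metal path length per ray (mm); zero off the trace.
    """

    values: np.ndarray
    angles: np.ndarray
    metal_trace: np.ndarray
    metal_pathlen_mm: np.ndarray
    pixel_spacing_mm: float
    image_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")
        if self.metal_trace.shape != self.values.shape:
            raise ValueError("metal_trace shape must equal values shape")
        if self.values.shape[0] != self.angles.size:
            raise ValueError("one angle per sinogram row required")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "Sinogram":
        return replace(self, values=np.array(values, dtype=float))


def _padded_size(n: int) -> int:
    """Inscribed-circle padding; parity matches n so the symmetric pad keeps
    the image centre on the projector's rotation centre."""
    m = int(math.ceil(math.sqrt(2.0) * n)) + 1
    if (m - n) % 2:
        m += 1
    return m


def forward_project(
    image: SliceImage,
    n_angles: int = 720,
    n_bins: int | None = None,
    metal_threshold: float = METAL_HU_THRESHOLD,
) -> Sinogram:
    """Parallel-beam line integrals of the image's linear attenuation.

    The detector bin count defaults to the diagonal padding
    ``ceil(sqrt(2) * matrix_size) + 1`` (always >= matrix width); a larger
    ``n_bins`` widens the padding, a smaller one is rejected because rays
    would truncate the object.
    """
    if n_angles < 90:
        raise ValueError("n_angles must be >= 90 for a usable reconstruction")
    n = image.matrix_size
    min_bins = _padded_size(n)
    if n_bins is None:
        n_bins = min_bins
    elif n_bins < min_bins:
        raise ValueError(
            f"n_bins={n_bins} would truncate the object; need >= {min_bins}"
        )
    pad = n_bins - n
    lo, hi = pad // 2, pad - pad // 2
    spacing = float(image.pixel_spacing_mm[0])

    theta_deg = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    mu = hu_to_mu(image.pixels)
    mu_pad = np.pad(mu, ((lo, hi), (lo, hi)))
    values = radon(mu_pad, theta=theta_deg, circle=True).T * spacing

    mask = metal_mask(image, metal_threshold).astype(float)
    if mask.any():
        mask_pad = np.pad(mask, ((lo, hi), (lo, hi)))
        pathlen = radon(mask_pad, theta=theta_deg, circle=True).T * spacing
        pathlen = np.maximum(pathlen, 0.0)
    else:
        pathlen = np.zeros_like(values)
    trace = pathlen > METAL_TRACE_MIN_MM
    # grazing rays below the trace threshold are treated as metal-free so
    # that corruption and correction act on exactly the traced rays
    pathlen[~trace] = 0.0

    return Sinogram(
        values=values,
        angles=np.deg2rad(theta_deg),
        metal_trace=trace,
        metal_pathlen_mm=pathlen,
        pixel_spacing_mm=spacing,
        image_size=n,
    )


def reconstruct_fbp(sino: Sinogram, filter_name: str = "ramp") -> SliceImage:
    """Ramp-filtered back projection back to an HU image.

    Raises if the view angles do not span [0, pi): a missing angular wedge
    makes the inversion ill-posed.
    """
    n = sino.n_angles
    span = float(np.ptp(sino.angles))
    if n < 2 or span < math.pi * (1.0 - 2.0 / n):
        raise ValueError("sinogram angles must span [0, pi)")
    theta_deg = np.rad2deg(sino.angles)
    mu_pad = iradon(
        sino.values.T / sino.pixel_spacing_mm,
        theta=theta_deg,
        filter_name=filter_name,
        interpolation="linear",
        circle=True,
        output_size=sino.n_bins,
    )
    pad = sino.n_bins - sino.image_size
    lo = pad // 2
    mu = mu_pad[lo : lo + sino.image_size, lo : lo + sino.image_size]
    return SliceImage(
        mu_to_hu(mu),
        (sino.pixel_spacing_mm, sino.pixel_spacing_mm),
        provenance="FBP reconstruction",
    )
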