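"""Projection-domain artifact emulation and correction.

Three effects are layered onto clean sinograms:

* **Beam hardening** — rays crossing metal are depressed by ``beta * m**2``
  (m = metal path length), the quadratic being the lowest-order polychromatic
  bias; after FBP this produces the familiar dark streaks between and around
  implants.
* **Photon starvation** — detector counts are Poisson with mean
  ``i0 * exp(-p)`` and re-logged, so rays through much metal become
  noise-dominated and reconstruct as grainy streaks.
* **VMI bright streaks** — high-keV virtual monochromatic images largely
  escape beam hardening but introduce positive streaks near metal; emulated
  by adding ``gamma * m`` to the line integrals of a sparse subset of the
  former metal-trace view angles.

An orthopedic-MAR-style correction is emulated as classical sinogram
inpainting: bins of the substantially-metallic trace are replaced by linear
interpolation across the trace within each view.  Plain interpolation of raw
line integrals fails badly for large in-plane implants (the body's chord
profile is far from linear across a wide trace), so — as in normalized MAR —
the interpolation runs in a prior-normalized domain when a prior sinogram is
supplied: values are divided by the prior, inpainted, and re-multiplied.
The simulator uses the no-prosthesis reference projection of the same
phantom as that prior, standing in for the tissue-class prior a vendor
implementation builds internally.
"""

from __future__ import annotations

import warnings

import numpy as np

from .phantom import Severity, SliceImage
from .projection import Sinogram

__all__ = [
    "corrupt_sinogram",
    "expected_corruption",
    "apply_omar_emulation",
    "apply_vmi_emulation",
    "streak_artifact_index",
    "OMAR_MIN_PATH_MM",
    "VMI_BEAM_HARDENING_RATIO",
    "VMI_NOISE_SCALE",
    "VMI_STARVED_AMPLIFICATION",
]

#: Expected counts above which Poisson noise is negligible and the ray is
#: passed through deterministically (relative fluctuation < 1e-4).
_NOISELESS_COUNTS = 1.0e8

#: Residual beam hardening of 130 keV VMI relative to the polychromatic beam.
VMI_BEAM_HARDENING_RATIO = 0.1

#: Noise amplification of 130 keV VMI relative to the conventional
#: reconstruction of the same acquisition (reference noise 8.0 vs 6.9 HU).
VMI_NOISE_SCALE = 8.0 / 6.9

#: Fraction of metal-trace view angles that receive the bright-streak term.
VMI_STREAK_ANGLE_FRACTION = 0.06

#: Extra amplification of the transferred corruption on photon-starved rays.
#: Spectral decomposition of a dual-layer acquisition becomes ill-conditioned
#: where almost no quanta reach the detector, so the VMI inherits starved-ray
#: errors amplified rather than merely rescaled; this is what keeps severe
#: (between-implant) artifacts on high-keV VMI even though its beam
#: hardening is small.
VMI_STARVED_AMPLIFICATION = 3.0

#: A ray counts as starved for the amplification above when its expected
#: clean-beam detector counts fall below this value.
VMI_STARVED_COUNTS = 50.0


def corrupt_sinogram(
    sino: Sinogram,
    severity: Severity,
    rng: np.random.Generator | int | None = None,
) -> Sinogram:
    """Apply beam hardening and photon starvation to a clean sinogram.

    Deterministic given the generator state; rays whose expected counts
    exceed ~1e8 (including everything when ``i0 = inf``) skip the Poisson
    draw entirely.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m_eff = np.minimum(sino.metal_pathlen_mm, severity.bh_path_cap_mm)
    p = sino.values - severity.beta * m_eff**2
    if np.isfinite(severity.i0):
        with np.errstate(over="ignore"):
            lam = severity.i0 * np.exp(-p)
        noisy = lam < _NOISELESS_COUNTS
        counts = rng.poisson(np.where(noisy, lam, 0.0))
        # continuity-corrected re-log: nearly unbiased at moderate counts,
        # capped at log(2*i0) for fully starved rays
        p = np.where(noisy, -np.log((counts + 0.5) / severity.i0), p)
    return sino.copy_with(p)


#: Metal path length (mm) above which a ray is inpainted by the MAR
#: emulation.  Rays grazing less metal keep their (mildly biased) values, so
#: the correction is strong but not perfect — thin-path beam hardening
#: survives it, as residual streaks survive vendor MAR.
OMAR_MIN_PATH_MM = 16.0


def expected_corruption(sino: Sinogram, severity: Severity) -> Sinogram:
    """Noise-free limit of ``corrupt_sinogram``.

    Beam hardening in full, and the deterministic part of photon
    starvation: a fully starved ray reads the count floor, so its line
    integral saturates at ``log(2 * i0)`` regardless of the true
    attenuation.  This is the zero-variance skeleton that injected severity
    classes are derived from.
    """
    m_eff = np.minimum(sino.metal_pathlen_mm, severity.bh_path_cap_mm)
    p = sino.values - severity.beta * m_eff**2
    if np.isfinite(severity.i0):
        p = np.minimum(p, np.log(2.0 * severity.i0))
    return sino.copy_with(p)


def apply_omar_emulation(
    sino: Sinogram,
    prior: Sinogram | None = None,
    metal_projection: np.ndarray | None = None,
    min_path_mm: float = OMAR_MIN_PATH_MM,
) -> Sinogram:
    """Orthopedic-MAR emulation: inpaint heavily-metallic bins per view.

    Bins whose metal path exceeds ``min_path_mm`` are replaced by 1-D linear
    interpolation anchored on the metal-free bins of the same view —
    performed on prior-normalized values when ``prior`` is given (normalized
    MAR) — after which the implant's own projection (``metal_projection``,
    the clean metal-excess line integrals the simulator knows exactly,
    standing in for the metal estimate a vendor algorithm reinserts) is
    added back on those bins.  Lightly-metallic bins (path below the
    threshold) are neither replaced nor used as anchors, so their mild
    beam-hardening bias survives the correction, as residual streaks survive
    vendor MAR.  Untouched bins and fixed prior/metal estimates make the
    operation idempotent; with no metal in the trace the input is returned
    unchanged (MAR does not alter images without metal).
    """
    inpaint = sino.metal_pathlen_mm > min_path_mm
    if not inpaint.any():
        return sino.copy_with(sino.values)
    if prior is not None:
        if prior.values.shape != sino.values.shape:
            raise ValueError("prior sinogram shape mismatch")
        ref = np.maximum(prior.values, 1e-3)
    else:
        ref = np.ones_like(sino.values)
    if metal_projection is not None and metal_projection.shape != sino.values.shape:
        raise ValueError("metal_projection shape mismatch")
    norm = np.array(sino.values, dtype=float) / ref
    out = np.array(sino.values, dtype=float)
    bins = np.arange(sino.n_bins, dtype=float)
    for i in range(sino.n_angles):
        trace = inpaint[i]
        if not trace.any():
            continue
        keep = ~sino.metal_trace[i]
        if not keep.any():
            warnings.warn(
                f"metal trace covers the whole detector row at angle index {i}; "
                "filling with the prior (zero excess attenuation)",
                RuntimeWarning,
                stacklevel=2,
            )
            out[i] = ref[i]
            continue
        filled = np.interp(bins[trace], bins[keep], norm[i, keep])
        out[i, trace] = filled * ref[i, trace]
    if metal_projection is not None:
        out = np.where(inpaint, out + metal_projection, out)
    return sino.copy_with(out)


def apply_vmi_emulation(
    sino_clean_vmi: Sinogram,
    sino_clean_conv: Sinogram,
    sino_corrupted_conv: Sinogram,
    severity: Severity,
    *,
    bh_ratio: float = VMI_BEAM_HARDENING_RATIO,
    noise_scale: float = VMI_NOISE_SCALE,
    streak_angle_fraction: float = VMI_STREAK_ANGLE_FRACTION,
    starved_amplification: float = VMI_STARVED_AMPLIFICATION,
) -> Sinogram:
    """130 keV virtual-monochromatic reconstruction of one acquisition.

    A dual-layer scanner derives the VMI from the same detected quanta as
    the conventional reconstruction, so the stochastic corruption transfers
    rather than being redrawn: the conventional chain's noise-and-saturation
    residual (corrupted minus beam-hardened-clean) is carried over, scaled
    to the VMI noise level.  On top of that the VMI gets (i) its own, much
    weaker beam hardening ``beta * bh_ratio`` on the shared metal paths and
    (ii) the additive bright-streak term ``gamma * m`` on a sparse regular
    subset of metal-trace view angles.  Fully deterministic given the
    corrupted conventional sinogram.
    """
    if not 0.0 <= bh_ratio <= 1.0:
        raise ValueError("bh_ratio must lie in [0, 1]")
    if sino_clean_conv.values.shape != sino_clean_vmi.values.shape:
        raise ValueError("conventional/VMI sinogram shape mismatch")
    # shared acquisition geometry: use the conventional chain's metal path
    # lengths so its beam-hardening term cancels exactly in the residual
    m_eff = np.minimum(sino_clean_conv.metal_pathlen_mm, severity.bh_path_cap_mm)
    p_conv_bh = sino_clean_conv.values - severity.beta * m_eff**2
    residual = sino_corrupted_conv.values - p_conv_bh
    scale = np.full_like(residual, noise_scale)
    if np.isfinite(severity.i0) and starved_amplification > 1.0:
        with np.errstate(over="ignore"):
            starved = severity.i0 * np.exp(-p_conv_bh) < VMI_STARVED_COUNTS
        scale[starved] = noise_scale * starved_amplification
    p = (
        sino_clean_vmi.values
        - bh_ratio * severity.beta * m_eff**2
        + scale * residual
    )
    out = sino_clean_vmi.copy_with(p)
    if severity.gamma > 0 and out.metal_trace.any() and streak_angle_fraction > 0:
        step = max(int(round(1.0 / streak_angle_fraction)), 1)
        trace_angles = np.flatnonzero(out.metal_trace.any(axis=1))
        chosen = trace_angles[::step]
        values = np.array(out.values, dtype=float)
        values[chosen] += severity.gamma * out.metal_pathlen_mm[chosen]
        out = out.copy_with(values)
    return out


def streak_artifact_index(image: SliceImage, truth: SliceImage, mask: np.ndarray) -> float:
    """Mean absolute HU deviation from ground truth over the given water mask.

    Internal simulator QC metric: larger means stronger streaks/noise.
    """
    if image.pixels.shape != truth.pixels.shape:
        raise ValueError("image and truth shapes differ")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return float(np.mean(np.abs(image.pixels[mask] - truth.pixels[mask])))
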