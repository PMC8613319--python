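"""The full simulated study: 12 conditions, ground truth and measurements.

The study design crosses {no prosthesis, unilateral, bilateral} with
{conventional, 130 keV VMI} and {MAR off, MAR on}.  All four reconstructions
of one prosthesis configuration share a single simulated acquisition per
family (dual-layer acquisition: the VMI is derived from the same scan), so
MAR on/off differ only by sinogram inpainting and are bit-identical when no
metal is present.

Alongside the images the generator emits, per pellet-instance, the severity
class implied by the *noiseless* limit of the corruption model (beam
hardening only, infinite flux) — the ground truth that category recovery is
judged against: the deterministic artifact decides the class, noise can only
blur the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .artifacts import (
    apply_omar_emulation,
    apply_vmi_emulation,
    corrupt_sinogram,
    expected_corruption,
    streak_artifact_index,
)
from .categorize import DEFAULT_CUTOFF_HU, attach_categories, categorize
from .phantom import PhantomSpec, SliceImage, rasterize_phantom, water_mask
from .projection import forward_project, reconstruct_fbp
from .roi import ROITemplate, default_template, measure_rois

__all__ = ["StudyResult", "generate_study", "measure_study", "PROSTHESIS_CONFIGS"]

PROSTHESIS_CONFIGS = ("none", "unilateral", "bilateral")
RECON_KEYS = ("conventional", "conventional_omar", "vmi130", "vmi130_omar")


@dataclass
class StudyResult:
    """Images, ground truth and injected labels of one simulated study."""

    spec: PhantomSpec
    images: dict[tuple[str, str], SliceImage]  # (config, recon_key) -> image
    truths: dict[tuple[str, str], SliceImage]  # (config, family) -> ground truth
    injected_labels: pd.DataFrame  # pellet_id, side, index, config, injected_category
    template: ROITemplate

    def water_mask(self, config: str) -> np.ndarray:
        return water_mask(self.truths[(config, "conventional")])

    def streak_index(self, config: str, recon_key: str) -> float:
        family = "vmi130" if recon_key.startswith("vmi130") else "conventional"
        return streak_artifact_index(
            self.images[(config, recon_key)],
            self.truths[(config, family)],
            self.water_mask(config),
        )


def _condition(img: SliceImage, config: str, family: str, omar: bool, seed: int) -> SliceImage:
    img.condition = (config, family, "omar_on" if omar else "omar_off")
    img.provenance = f"simulated study seed={seed}"
    return img


def generate_study(
    seed: int = 0,
    spec: PhantomSpec | None = None,
    cutoff: float = DEFAULT_CUTOFF_HU,
) -> StudyResult:
    """Simulate all 12 study conditions, fully deterministic given the seed.

    RNG call order (documented contract): one child generator per prosthesis
    configuration in (none, unilateral, bilateral), consumed by that
    configuration's conventional acquisition; the VMI reconstruction derives
    deterministically from the same acquisition (dual-layer scanner), so it
    draws nothing.
    """
    if spec is None:
        spec = PhantomSpec(seed=seed)
    elif spec.seed != seed:
        spec = replace(spec, seed=seed)
    severity = spec.severity
    children = np.random.SeedSequence(seed).spawn(len(PROSTHESIS_CONFIGS))
    rngs = iter(np.random.default_rng(c) for c in children)

    images: dict[tuple[str, str], SliceImage] = {}
    truths: dict[tuple[str, str], SliceImage] = {}
    label_rows: list[dict] = []
    template = default_template(spec)
    # the no-prosthesis projections double as the MAR emulation's
    # normalization prior ("none" is generated first)
    priors: dict[str, object] = {}

    for config in PROSTHESIS_CONFIGS:
        spec_c = spec.with_config(config)
        rng_conv = next(rngs)

        truth_c = rasterize_phantom(spec_c, "conventional")
        truths[(config, "conventional")] = truth_c
        sino_c = forward_project(truth_c, spec.n_angles)
        if config == "none":
            priors["conventional"] = sino_c
        cor_c = corrupt_sinogram(sino_c, severity, rng_conv)
        images[(config, "conventional")] = _condition(
            reconstruct_fbp(cor_c), config, "conventional", False, seed
        )
        metal_c = sino_c.values - priors["conventional"].values
        images[(config, "conventional_omar")] = _condition(
            reconstruct_fbp(
                apply_omar_emulation(cor_c, priors["conventional"], metal_c)
            ),
            config, "conventional", True, seed,
        )

        truth_v = rasterize_phantom(spec_c, "vmi130")
        truths[(config, "vmi130")] = truth_v
        sino_v = forward_project(truth_v, spec.n_angles)
        if config == "none":
            priors["vmi130"] = sino_v
        cor_v = apply_vmi_emulation(sino_v, sino_c, cor_c, severity)
        images[(config, "vmi130")] = _condition(
            reconstruct_fbp(cor_v), config, "vmi130", False, seed
        )
        metal_v = sino_v.values - priors["vmi130"].values
        images[(config, "vmi130_omar")] = _condition(
            reconstruct_fbp(
                apply_omar_emulation(cor_v, priors["vmi130"], metal_v)
            ),
            config, "vmi130", True, seed,
        )

        # injected severity class: zero-variance limit of the categorization
        # image (conventional, MAR off): beam hardening plus the
        # deterministic starvation saturation, no Poisson draw
        if config == "none":
            inj = {p.pellet_id: "unaffected" for p in spec.pellet_layout}
        else:
            img0 = reconstruct_fbp(expected_corruption(sino_c, severity))
            inj = {
                m.label: categorize(m.mean_hu, cutoff)
                for m in measure_rois(img0, template)
                if m.label != "BG"
            }
        for p in spec.pellet_layout:
            label_rows.append(
                {
                    "pellet_id": p.pellet_id,
                    "side": p.side,
                    "index": p.index,
                    "config": config,
                    "injected_category": inj[p.pellet_id],
                }
            )

    return StudyResult(
        spec=spec,
        images=images,
        truths=truths,
        injected_labels=pd.DataFrame(label_rows),
        template=template,
    )


def measure_study(
    study: StudyResult,
    template: ROITemplate | None = None,
    cutoff: float = DEFAULT_CUTOFF_HU,
    sd_mode: str = "population",
) -> pd.DataFrame:
    """Apply the ROI template to all 12 images and attach categories.

    Returns long format: one row per (config, recon_key, ROI label) with
    mean_hu, noise_hu, snr, cnr, n_pixels, reconstruction family, the MAR
    flag and the instance category.
    """
    template = template or study.template
    rows = []
    for (config, recon_key), image in sorted(study.images.items()):
        family = "vmi130" if recon_key.startswith("vmi130") else "conventional"
        omar = recon_key.endswith("_omar")
        for m in measure_rois(image, template, sd_mode=sd_mode):
            rows.append(
                {
                    "config": config,
                    "reconstruction": family,
                    "omar": omar,
                    "recon_key": recon_key,
                    "label": m.label,
                    "mean_hu": m.mean_hu,
                    "noise_hu": m.noise_hu,
                    "snr": m.snr,
                    "cnr": m.cnr,
                    "n_pixels": m.n_pixels,
                }
            )
    df = pd.DataFrame(rows)
    return attach_categories(df, cutoff)
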