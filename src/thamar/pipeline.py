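"""End-to-end orchestration: simulate -> measure -> categorize -> tables.

Three modes share one entry point:

* ``simulate``  — run the full synthetic study from a phantom spec, write the
  12 condition images, the ground-truth labels, the long-format measurement
  CSV, category counts and both result tables.
* ``measure``   — apply an ROI template to existing slice files (NIfTI or
  DICOM) and write a measurement CSV.
* ``reanalyze`` — rebuild categories, tables and statistics from a
  per-pellet measurement CSV (e.g. hand-converted from a supplementary
  spreadsheet).

Every run writes a manifest (config hash, seed, version, output checksums);
a fixed config + seed reproduces every CSV byte for byte, and the tables of
a simulate run are regenerated from its own exported CSV so that
re-analysis of the export is an exact round trip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .categorize import DEFAULT_CUTOFF_HU, attach_categories, tabulate_categories
from .io import (
    read_measurements_csv,
    read_slice,
    write_measurements_csv,
    write_slice_dicom,
    write_slice_nifti,
)
from .metrics import (
    DEFAULT_COMPARISONS,
    METRICS,
    aggregate_comparison,
    build_tables,
)
from .phantom import PelletSite, PhantomSpec, Severity
from .roi import ROITemplate, default_template, measure_rois, measurements_frame
from .study import generate_study, measure_study

logger = logging.getLogger("thamar")

_CSV_FLOAT = "%.10g"

__all__ = ["RunConfig", "run", "tables_from_measurements"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    mode: str = "simulate"
    seed: int = 0
    out_dir: str = "thamar_run"
    phantom: dict = field(default_factory=dict)  # PhantomSpec field overrides
    template_path: str | None = None
    references: dict | None = None  # default: packaged reference values
    cutoff: float = DEFAULT_CUTOFF_HU
    comparisons: tuple = DEFAULT_COMPARISONS
    aggregation_mode: str = "ratio_of_means"
    sd_mode: str = "population"
    measurements_path: str | None = None  # reanalyze mode
    image_paths: tuple = ()  # measure mode
    write_dicom: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "measure", "reanalyze"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.comparisons = tuple(tuple(c) for c in self.comparisons)
        self.image_paths = tuple(self.image_paths)
        if self.mode == "reanalyze" and not self.measurements_path:
            raise ValueError("reanalyze mode requires measurements_path")
        if self.mode == "measure" and not self.image_paths:
            raise ValueError("measure mode requires image_paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def build_spec(self) -> PhantomSpec:
        overrides = dict(self.phantom)
        if "severity" in overrides and isinstance(overrides["severity"], dict):
            overrides["severity"] = Severity(**overrides["severity"])
        if "pellet_layout" in overrides:
            overrides["pellet_layout"] = tuple(
                PelletSite(**p) if isinstance(p, dict) else p
                for p in overrides["pellet_layout"]
            )
        return PhantomSpec(seed=self.seed, **overrides)

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def tables_from_measurements(
    measurements: pd.DataFrame,
    references: dict | None = None,
    cutoff: float = DEFAULT_CUTOFF_HU,
    aggregation_mode: str = "ratio_of_means",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Categorize a long-format measurement table and build both MAR tables."""
    df = measurements.copy()
    if "recon_key" not in df.columns:
        df["recon_key"] = df["reconstruction"] + df["omar"].map(
            {True: "_omar", False: ""}
        )
    if "category" not in df.columns:
        df = attach_categories(df, cutoff)
    return build_tables(df, references, aggregation_mode)


def _delta_v_audit(records: pd.DataFrame, config: RunConfig) -> dict:
    audit: dict = {}
    for recon, standard in config.comparisons:
        for category in ("mild", "severe"):
            for metric in METRICS:
                key = f"{recon}_vs_{standard}/{category}/{metric}"
                try:
                    cell = aggregate_comparison(
                        records, metric, category, recon, standard,
                        config.references, config.aggregation_mode,
                    )
                except ValueError:
                    audit[key] = None
                    continue
                audit[key] = {
                    "pellet_ids": list(cell.pellet_ids),
                    "delta_v_reconstruction": list(cell.delta_v_recon),
                    "delta_v_standard": list(cell.delta_v_standard),
                    "relative_mar_pct": _nan_none(cell.relative_mar_pct),
                    "p_value": _nan_none(cell.p_value),
                    "n": cell.n,
                }
    return audit


def _nan_none(x: float):
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x


def _analysis_outputs(
    out: Path, measurements: pd.DataFrame, config: RunConfig
) -> list[Path]:
    """Tables, counts and audit from a measurement table; returns paths."""
    df = measurements.copy()
    if "recon_key" not in df.columns:
        df["recon_key"] = df["reconstruction"] + df["omar"].map(
            {True: "_omar", False: ""}
        )
    if "category" not in df.columns:
        df = attach_categories(df, config.cutoff)

    instances = df[
        (df["label"] != "BG")
        & (df["config"] != "none")
        & (df["recon_key"] == "conventional")
    ][["config", "label", "category"]]
    counts = tabulate_categories(instances).reset_index()
    counts_path = out / "category_counts.csv"
    _write_csv(counts, counts_path)

    t3, t4 = build_tables(df, config.references, config.aggregation_mode)
    t3_path, t4_path = out / "table3.csv", out / "table4.csv"
    _write_csv(t3, t3_path)
    _write_csv(t4, t4_path)

    audit_path = out / "delta_v.json"
    audit_path.write_text(
        json.dumps(_delta_v_audit(df, config), indent=1, sort_keys=True)
    )
    return [counts_path, t3_path, t4_path, audit_path]


def run(config: RunConfig) -> dict:
    """Execute one run; returns (and writes) the manifest.

    A failing stage leaves a ``RUN.partial`` marker next to whatever outputs
    were already written, then re-raises.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial = out / "RUN.partial"
    partial.write_text("run in progress\n")
    t0 = time.time()
    outputs: list[Path] = []
    try:
        if config.mode == "simulate":
            outputs += _run_simulate(out, config)
        elif config.mode == "measure":
            outputs += _run_measure(out, config)
        else:
            measurements = read_measurements_csv(config.measurements_path)
            outputs += _analysis_outputs(out, measurements, config)
    except Exception:
        logger.exception("stage failed; partial outputs retained in %s", out)
        raise
    partial.unlink()

    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "version": __version__,
        "config_hash": config.config_hash(),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete: %d outputs in %.1fs", len(outputs), manifest["elapsed_s"])
    return manifest


def _run_simulate(out: Path, config: RunConfig) -> list[Path]:
    spec = config.build_spec()
    logger.info("simulating study (matrix %d, %d angles, seed %d)",
                spec.matrix_size, spec.n_angles, config.seed)
    study = generate_study(config.seed, spec, config.cutoff)
    template = (
        ROITemplate.from_csv(config.template_path)
        if config.template_path
        else study.template
    )

    outputs: list[Path] = []
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for (cfg, recon_key), image in sorted(study.images.items()):
        path = img_dir / f"{cfg}_{recon_key}.nii"
        write_slice_nifti(image, path)
        outputs.append(path)
        if config.write_dicom:
            dpath = img_dir / f"{cfg}_{recon_key}.dcm"
            write_slice_dicom(image, dpath)
            outputs.append(dpath)

    labels_path = out / "ground_truth_labels.csv"
    _write_csv(study.injected_labels, labels_path)
    outputs.append(labels_path)

    template_path = out / "roi_template.csv"
    template.to_csv(template_path)
    outputs.append(template_path)

    measurements = measure_study(study, template, config.cutoff, config.sd_mode)
    meas_path = out / "measurements.csv"
    write_measurements_csv(measurements, meas_path)
    outputs.append(meas_path)

    # tables are rebuilt from the exported CSV so that re-analysis of the
    # export is an exact round trip
    outputs += _analysis_outputs(out, read_measurements_csv(meas_path), config)
    return outputs


def _run_measure(out: Path, config: RunConfig) -> list[Path]:
    if not config.template_path:
        template = default_template(PhantomSpec(seed=config.seed))
    else:
        template = ROITemplate.from_csv(config.template_path)
    outputs = []
    for path in config.image_paths:
        image = read_slice(path)
        df = measurements_frame(measure_rois(image, template, config.sd_mode))
        dest = out / (Path(path).stem.split(".")[0] + "_measurements.csv")
        _write_csv(df, dest)
        outputs.append(dest)
    return outputs
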