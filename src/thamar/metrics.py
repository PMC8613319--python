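"""Normalized artifact metric and relative metal artifact reduction.

For a metric V (mean HU, CNR, SNR or noise) of one pellet-instance, the
artifact magnitude is the normalized absolute deviation from the
no-prosthesis reference of the same reconstruction family:

    dV = | 1 - V_with_prostheses / V_no_prostheses |

The reference V_no_prostheses is the all-pellet mean without prostheses
(per family: conventional vs 130 keV VMI), which makes dV comparable across
families despite their different HU scales.  Two reconstructions are then
compared per category by the relative metal artifact reduction

    relative MAR (%) = (1 - dV_reconstruction / dV_standard) * 100

where negative values mean the candidate reconstruction *aggravates* the
artifact relative to the standard.  Category-level percentages use the
ratio of category-mean dV by default (robust to near-zero per-pellet
standards); a mean-of-per-pellet-ratios mode is available.  A paired
Wilcoxon signed-rank p over the per-pellet dV pairs accompanies each cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import wilcoxon_signed_rank

__all__ = [
    "DEFAULT_REFERENCE_VALUES",
    "METRICS",
    "RECONSTRUCTION_KEYS",
    "MARComparison",
    "delta_v",
    "relative_mar",
    "aggregate_comparison",
    "build_tables",
    "reference_for",
]

METRICS = ("mean_hu", "cnr", "snr", "noise_hu")

#: Reconstruction keys in study order; *_omar denotes the MAR-corrected
#: variant of the same acquisition.
RECONSTRUCTION_KEYS = ("conventional", "conventional_omar", "vmi130", "vmi130_omar")

#: No-prosthesis reference values per reconstruction family: the all-pellet
#: means (and the background-matched noise) measured without implants.
#: MAR does not alter images without metal, so each family's values hold for
#: both its MAR states.
DEFAULT_REFERENCE_VALUES = {
    "conventional": {"mean_hu": 248.4, "cnr": 37.3, "snr": 36.5, "noise_hu": 6.9},
    "vmi130": {"mean_hu": 150.4, "cnr": 18.0, "snr": 19.3, "noise_hu": 8.0},
}

#: The five standard comparisons of the study design: three candidates vs the
#: plain conventional standard, two vs the MAR-corrected conventional one.
DEFAULT_COMPARISONS = (
    ("conventional_omar", "conventional"),
    ("vmi130", "conventional"),
    ("vmi130_omar", "conventional"),
    ("vmi130", "conventional_omar"),
    ("vmi130_omar", "conventional_omar"),
)


def reference_for(reconstruction: str, references: dict | None = None) -> dict:
    """Reference-value row for a reconstruction key (family lookup)."""
    references = DEFAULT_REFERENCE_VALUES if references is None else references
    family = "vmi130" if reconstruction.startswith("vmi130") else "conventional"
    return references[family]


def delta_v(v_with: float, v_reference: float) -> float:
    """Normalized absolute deviation |1 - V_with / V_reference|.

    A zero reference makes the normalization undefined; NaN is returned and
    a warning emitted so the pellet can be excluded upstream.
    """
    if v_reference == 0:
        warnings.warn(
            "delta_v undefined for zero reference value; returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    return abs(1.0 - v_with / v_reference)


def relative_mar(delta_recon: float, delta_standard: float) -> float:
    """Relative metal artifact reduction in percent.

    ``(1 - delta_recon / delta_standard) * 100``; negative values indicate
    aggravation.  NaN (with a warning) if the standard's artifact is zero.
    """
    if delta_standard == 0:
        warnings.warn(
            "relative MAR undefined when the standard reconstruction has "
            "zero artifact; returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    return (1.0 - delta_recon / delta_standard) * 100.0


@dataclass(frozen=True)
class MARComparison:
    """One (metric, category, reconstruction-vs-standard) table cell."""

    metric: str
    category: str
    reconstruction: str
    standard_reconstruction: str
    delta_v_recon: tuple[float, ...]
    delta_v_standard: tuple[float, ...]
    pellet_ids: tuple[str, ...]
    relative_mar_pct: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if len(self.delta_v_recon) != len(self.delta_v_standard):
            raise ValueError("paired delta-V lists must have equal length")
        if self.n < 1:
            raise ValueError("need at least one pellet pair")


def _metric_lookup(records: pd.DataFrame, reconstruction: str, metric: str) -> pd.Series:
    sub = records[records["recon_key"] == reconstruction]
    return sub.set_index(["config", "label"])[metric]


def aggregate_comparison(
    records: pd.DataFrame,
    metric: str,
    category: str,
    reconstruction: str,
    standard: str,
    references: dict | None = None,
    mode: str = "ratio_of_means",
) -> MARComparison:
    """Build one relative-MAR cell from long-format pellet records.

    ``records`` carries one row per (config, label, recon_key) with the four
    metric columns and a ``category`` column (from the conventional no-MAR
    image).  Pellet-instances of the requested category are pooled across
    prosthesis configurations; each contributes one paired (dV_standard,
    dV_reconstruction) observation.  Pellets whose dV is undefined (NaN
    metric or zero reference) are excluded with a warning.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError("mode must be 'ratio_of_means' or 'mean_of_ratios'")
    cat_rows = records[records["category"] == category]
    instances = sorted(set(zip(cat_rows["config"], cat_rows["label"])))
    if not instances:
        raise ValueError(f"no pellet-instances in category {category!r}")

    v_recon = _metric_lookup(records, reconstruction, metric)
    v_std = _metric_lookup(records, standard, metric)
    ref_r = reference_for(reconstruction, references)[metric]
    ref_s = reference_for(standard, references)[metric]

    ids, dvr, dvs = [], [], []
    for key in instances:
        try:
            vr = float(v_recon[key])
            vs = float(v_std[key])
        except KeyError as exc:
            raise ValueError(f"pellet pairing incomplete for {key}") from exc
        dr, ds = delta_v(vr, ref_r), delta_v(vs, ref_s)
        if math.isnan(dr) or math.isnan(ds):
            warnings.warn(
                f"excluding pellet {key} from {metric}/{category}: undefined delta-V",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        ids.append(f"{key[0]}:{key[1]}")
        dvr.append(dr)
        dvs.append(ds)
    if not dvr:
        raise ValueError(f"all pellets excluded for {metric}/{category}")

    if reconstruction == standard:
        rel, p = 0.0, 1.0
    else:
        if mode == "ratio_of_means":
            rel = relative_mar(float(np.mean(dvr)), float(np.mean(dvs)))
        else:
            per = [
                relative_mar(r, s) for r, s in zip(dvr, dvs) if s != 0
            ]
            rel = float(np.mean(per)) if per else math.nan
        diffs = np.asarray(dvs) - np.asarray(dvr)
        p = wilcoxon_signed_rank(diffs).p_value

    return MARComparison(
        metric=metric,
        category=category,
        reconstruction=reconstruction,
        standard_reconstruction=standard,
        delta_v_recon=tuple(dvr),
        delta_v_standard=tuple(dvs),
        pellet_ids=tuple(ids),
        relative_mar_pct=rel,
        p_value=p,
        n=len(dvr),
    )


def build_tables(
    records: pd.DataFrame,
    references: dict | None = None,
    mode: str = "ratio_of_means",
    categories: tuple[str, ...] = ("mild", "severe"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two headline result tables, in tidy form.

    Table A compares {conventional+MAR, VMI, VMI+MAR} against plain
    conventional imaging; table B compares {VMI, VMI+MAR} against
    conventional imaging with MAR.  One row per (reconstruction, category,
    metric) with the relative MAR percentage, the Wilcoxon p and n.  A
    category with no pellet-instances yields NaN cells flagged ``absent``
    rather than zeros.
    """
    tables = []
    for standard, recons in (
        ("conventional", ("conventional_omar", "vmi130", "vmi130_omar")),
        ("conventional_omar", ("vmi130", "vmi130_omar")),
    ):
        rows = []
        for recon in recons:
            for category in categories:
                for metric in METRICS:
                    try:
                        cell = aggregate_comparison(
                            records, metric, category, recon, standard,
                            references, mode,
                        )
                        rows.append(
                            {
                                "standard": standard,
                                "reconstruction": recon,
                                "category": category,
                                "metric": metric,
                                "relative_mar_pct": cell.relative_mar_pct,
                                "p_value": cell.p_value,
                                "n": cell.n,
                                "absent": False,
                            }
                        )
                    except ValueError:
                        rows.append(
                            {
                                "standard": standard,
                                "reconstruction": recon,
                                "category": category,
                                "metric": metric,
                                "relative_mar_pct": math.nan,
                                "p_value": math.nan,
                                "n": 0,
                                "absent": True,
                            }
                        )
        tables.append(pd.DataFrame(rows))
    return tables[0], tables[1]


def render_table(table: pd.DataFrame) -> str:
    """Human-readable pivot: '45% (p=0.006)' cells, categories x metrics."""
    def _cell(row) -> str:
        if row["absent"]:
            return "absent"
        return f"{row['relative_mar_pct']:.0f}% (p={row['p_value']:.3f})"

    df = table.copy()
    df["cell"] = df.apply(_cell, axis=1)
    pivot = df.pivot_table(
        index="reconstruction",
        columns=["category", "metric"],
        values="cell",
        aggfunc="first",
    )
    order = [
        (c, m)
        for c in ("mild", "severe")
        for m in METRICS
        if (c, m) in pivot.columns
    ]
    return pivot.reindex(columns=pd.MultiIndex.from_tuples(order)).to_string()
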