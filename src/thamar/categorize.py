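"""Pellet artifact-severity categorization.

Each pellet-instance (one physical pellet under one prosthesis
configuration) is assigned to {unaffected, mildly affected, severely
affected} from its mean HU on the conventional reconstruction *without*
MAR — the clinical reference image:

* mean < 0 HU            -> severe (the pellet has been pushed below water)
* 0 <= mean < cutoff     -> mild
* mean >= cutoff         -> unaffected

The published cutoff of 235 HU is the default; ``derive_cutoff`` rebuilds a
cutoff from reference statistics (mean - k*SD, floored to a 5 HU step) for
phantoms with other pellet densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CATEGORIES",
    "DEFAULT_CUTOFF_HU",
    "PelletRecord",
    "derive_cutoff",
    "categorize",
    "tabulate_categories",
    "attach_categories",
]

CATEGORIES = ("unaffected", "mild", "severe")
DEFAULT_CUTOFF_HU = 235.0

#: Reconstruction used to determine the category.
CATEGORIZATION_RECONSTRUCTION = "conventional"  # without MAR


@dataclass(frozen=True)
class PelletRecord:
    """One pellet-instance with its category and per-reconstruction metrics.

    ``metrics`` maps a reconstruction key (conventional, conventional_omar,
    vmi130, vmi130_omar) to {mean_hu, noise_hu, snr, cnr}.
    """

    pellet_id: str
    side: str
    index: int
    prosthesis_config: str
    category: str
    metrics: dict[str, dict[str, float]]


def derive_cutoff(
    reference_mean: float,
    reference_sd: float,
    k: float = 1.0,
    round_down_to: float | None = 5.0,
) -> float:
    """Cutoff = reference mean - k * reference SD, floored to a 5 HU step.

    The flooring makes round published cutoffs reachable; pass
    ``round_down_to=None`` for the raw value.
    """
    if reference_sd <= 0:
        raise ValueError("reference_sd must be positive")
    cutoff = reference_mean - k * reference_sd
    if round_down_to:
        cutoff = math.floor(cutoff / round_down_to) * round_down_to
    return float(cutoff)


def categorize(mean_hu: float, cutoff: float = DEFAULT_CUTOFF_HU) -> str:
    """Total categorization of one pellet mean HU.

    Exactly 0 HU falls in the mild class (the least severe adjacent class;
    the boundary itself has measure zero but the function must be total).
    """
    if not math.isfinite(mean_hu):
        raise ValueError("mean_hu must be finite")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mean_hu < 0:
        return "severe"
    if mean_hu < cutoff:
        return "mild"
    return "unaffected"


def attach_categories(
    measurements: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF_HU
) -> pd.DataFrame:
    """Attach a per-instance category column to long-format measurements.

    ``measurements`` has one row per (config, label, reconstruction, omar)
    with at least a ``mean_hu`` column; the category of every
    (config, label) instance is read off its conventional no-MAR row and
    broadcast to all of that instance's rows.  Background rows get category
    "background"; no-prosthesis (reference) rows get "reference".
    """
    required = {"config", "label", "reconstruction", "omar", "mean_hu"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    df = measurements.copy()
    base = df[
        (df["reconstruction"] == CATEGORIZATION_RECONSTRUCTION)
        & (~df["omar"].astype(bool))
        & (df["label"] != "BG")
        & (df["config"] != "none")
    ]
    cat = {
        (r.config, r.label): categorize(r.mean_hu, cutoff)
        for r in base.itertuples()
    }

    def _assign(row) -> str:
        if row["label"] == "BG":
            return "background"
        if row["config"] == "none":
            return "reference"
        key = (row["config"], row["label"])
        if key not in cat:
            raise ValueError(
                f"no conventional no-MAR row to categorize pellet {key}"
            )
        return cat[key]

    df["category"] = df.apply(_assign, axis=1)
    return df


def tabulate_categories(records: pd.DataFrame) -> pd.DataFrame:
    """Category counts per prosthesis configuration.

    ``records`` needs one row per pellet-instance with ``config`` and
    ``category`` columns (pass deduplicated rows, e.g. the conventional
    no-MAR subset).  Returns a table with one row per config and one column
    per category; an empty input yields an empty table.
    """
    if records.empty:
        return pd.DataFrame(columns=list(CATEGORIES))
    counts = (
        records.groupby("config")["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    counts.columns.name = None
    return counts
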