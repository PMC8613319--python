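"""Normalized artifact metric and relative MAR aggregation."""

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thamar.metrics import (
    DEFAULT_REFERENCE_VALUES,
    MARComparison,
    aggregate_comparison,
    build_tables,
    delta_v,
    relative_mar,
)

DATA = Path(__file__).parent / "data"


def test_delta_v_worked_values():
    assert delta_v(248.4, 248.4) == 0.0
    assert delta_v(100.0, 250.0) == pytest.approx(0.6)
    # values beyond the reference range exceed 1
    assert delta_v(-50.0, 250.0) == pytest.approx(1.2)


def test_delta_v_zero_reference_is_nan_with_warning():
    with pytest.warns(RuntimeWarning, match="zero reference"):
        assert math.isnan(delta_v(10.0, 0.0))


def test_relative_mar_worked_values():
    assert relative_mar(0.2, 0.2) == 0.0
    assert relative_mar(0.11, 0.20) == pytest.approx(45.0)
    # aggravation is a legal, negative outcome
    assert relative_mar(0.4, 0.1) == pytest.approx(-300.0)


def test_relative_mar_zero_standard_is_nan_with_warning():
    with pytest.warns(RuntimeWarning, match="zero artifact"):
        assert math.isnan(relative_mar(0.1, 0.0))


@given(st.floats(0.0, 5.0), st.floats(1e-3, 5.0))
@settings(max_examples=100, deadline=None)
def test_relative_mar_decreasing_in_delta_recon(dr, ds):
    assert relative_mar(dr, ds) <= relative_mar(dr * 0.99, ds) + 1e-9
    assert relative_mar(ds, ds) == pytest.approx(0.0, abs=1e-9)


@given(
    v=st.floats(-400, 400),
    ref=st.floats(10, 400),
    c=st.floats(1e-2, 1e2),
)
@settings(max_examples=100, deadline=None)
def test_delta_v_scale_invariance(v, ref, c):
    """Normalization is the point: rescaling V and its reference together
    changes nothing."""
    assert delta_v(c * v, c * ref) == pytest.approx(delta_v(v, ref), rel=1e-9, abs=1e-12)


def toy_records(v_std, v_recon, ref=100.0):
    rows = []
    for i, (vs, vr) in enumerate(zip(v_std, v_recon), start=1):
        for key, v in (("conventional", vs), ("conventional_omar", vr)):
            rows.append(
                {
                    "config": "unilateral",
                    "label": f"L{i}",
                    "recon_key": key,
                    "category": "mild",
                    "mean_hu": v,
                    "cnr": 1.0,
                    "snr": 1.0,
                    "noise_hu": 1.0,
                }
            )
    return pd.DataFrame(rows)


TOY_REFS = {
    "conventional": {"mean_hu": 100.0, "cnr": 1.0, "snr": 1.0, "noise_hu": 1.0},
    "vmi130": {"mean_hu": 100.0, "cnr": 1.0, "snr": 1.0, "noise_hu": 1.0},
}


def test_three_pellet_toy_gives_50pct():
    """dV_std = [.2,.4,.6] vs dV_recon = [.1,.2,.3]: ratio of means = 50%."""
    records = toy_records([80.0, 60.0, 40.0], [90.0, 80.0, 70.0])
    cell = aggregate_comparison(
        records, "mean_hu", "mild", "conventional_omar", "conventional", TOY_REFS
    )
    assert cell.relative_mar_pct == pytest.approx(50.0)
    assert cell.delta_v_standard == pytest.approx((0.2, 0.4, 0.6))
    assert cell.delta_v_recon == pytest.approx((0.1, 0.2, 0.3))
    assert cell.n == 3


def test_self_comparison_is_zero_with_p_one():
    records = toy_records([80.0, 60.0, 40.0], [90.0, 80.0, 70.0])
    cell = aggregate_comparison(
        records, "mean_hu", "mild", "conventional", "conventional", TOY_REFS
    )
    assert cell.relative_mar_pct == 0.0
    assert cell.p_value == 1.0


def test_mean_of_ratios_mode_differs_as_expected():
    records = toy_records([80.0, 60.0, 40.0], [90.0, 80.0, 70.0])
    cell = aggregate_comparison(
        records, "mean_hu", "mild", "conventional_omar", "conventional",
        TOY_REFS, mode="mean_of_ratios",
    )
    assert cell.relative_mar_pct == pytest.approx(50.0)  # all ratios are 0.5 here


def test_spreadsheet_oracle_fixture():
    """Five-pellet hand computation (synthetic per-pellet table).

    dV_std mean = 98.4/248.4, dV_recon mean = 28.4/248.4, so the relative
    reduction is (1 - 28.4/98.4)*100 = 71.1382...%; all five differences are
    positive, hence the exact two-sided signed-rank p is 2/32.
    """
    df = pd.read_csv(DATA / "per_pellet_toy.csv")
    df["recon_key"] = df["reconstruction"] + df["omar"].map({True: "_omar", False: ""})
    from thamar.categorize import attach_categories

    records = attach_categories(df)
    cell = aggregate_comparison(
        records, "mean_hu", "mild", "conventional_omar", "conventional"
    )
    assert cell.n == 5
    assert cell.relative_mar_pct == pytest.approx(100.0 * (1 - 28.4 / 98.4), abs=1e-9)
    assert cell.p_value == pytest.approx(2.0 / 32.0)


def test_empty_category_raises():
    records = toy_records([80.0], [90.0])
    with pytest.raises(ValueError, match="severe"):
        aggregate_comparison(
            records, "mean_hu", "severe", "conventional_omar", "conventional", TOY_REFS
        )


def test_incomplete_pairing_raises():
    records = toy_records([80.0, 60.0], [90.0, 70.0])
    records = records[
        ~((records.label == "L2") & (records.recon_key == "conventional_omar"))
    ]
    with pytest.raises(ValueError, match="pairing"):
        aggregate_comparison(
            records, "mean_hu", "mild", "conventional_omar", "conventional", TOY_REFS
        )


def test_build_tables_shapes_and_absent_cells():
    records = toy_records([80.0, 60.0, 40.0], [90.0, 80.0, 70.0])
    # only conventional keys exist: give the VMI keys too so tables build
    vmi = records.copy()
    vmi["recon_key"] = vmi["recon_key"].map(
        {"conventional": "vmi130", "conventional_omar": "vmi130_omar"}
    )
    all_records = pd.concat([records, vmi], ignore_index=True)
    t3, t4 = build_tables(all_records, TOY_REFS)
    assert len(t3) == 3 * 2 * 4 and len(t4) == 2 * 2 * 4
    # no severe pellets anywhere: severe cells flagged absent, not zero
    severe3 = t3[t3.category == "severe"]
    assert severe3.absent.all()
    assert severe3.relative_mar_pct.isna().all()
    mild3 = t3[(t3.category == "mild")]
    assert not mild3.absent.any()


def test_build_tables_on_study_reproduces_headline_pattern(measurements):
    """Default seeded study: every MAR-corrected row improves on its
    standard, and 130 keV VMI with MAR gives the strongest overall
    reduction — the study's headline conclusion."""
    t3, t4 = build_tables(measurements)
    t3v = t3.set_index(["reconstruction", "category", "metric"])
    # conventional+MAR and VMI+MAR reduce mean-HU artifacts in both classes
    for cat in ("mild", "severe"):
        assert t3v.loc[("conventional_omar", cat, "mean_hu"), "relative_mar_pct"] > 0
        assert t3v.loc[("vmi130_omar", cat, "mean_hu"), "relative_mar_pct"] > 0
    # VMI+MAR is the strongest reconstruction on average across all cells
    by_recon = t3.groupby("reconstruction")["relative_mar_pct"].mean()
    assert by_recon.idxmax() == "vmi130_omar"
    # mild-category improvements are statistically significant
    mild = t3[(t3.reconstruction == "vmi130_omar") & (t3.category == "mild")]
    assert (mild.p_value < 0.05).all()


def test_comparison_requires_paired_lengths():
    with pytest.raises(ValueError, match="equal length"):
        MARComparison(
            metric="mean_hu",
            category="mild",
            reconstruction="a",
            standard_reconstruction="b",
            delta_v_recon=(0.1,),
            delta_v_standard=(0.1, 0.2),
            pellet_ids=("x",),
            relative_mar_pct=0.0,
            p_value=1.0,
            n=1,
        )
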