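"""ROI statistics: membership rule, SNR/CNR definitions, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thamar.phantom import SliceImage
from thamar.roi import (
    ROI,
    ROIError,
    ROITemplate,
    cnr,
    default_template,
    measure_rois,
    rose_flag,
    snr,
)

from conftest import small_spec


def flat_image(value, n=64, spacing=1.0):
    return SliceImage(np.full((n, n), float(value)), (spacing, spacing))


def template_of(*rois):
    return ROITemplate(tuple(rois))


def test_constant_image_yields_zero_noise_everywhere():
    img = flat_image(248.4)
    tmpl = template_of(ROI("A", 0, 0, 10), ROI("B", 10, -10, 8), ROI("BG", -15, 10, 10))
    for m in measure_rois(img, tmpl):
        assert m.mean_hu == pytest.approx(248.4)
        assert m.noise_hu == 0.0
        assert math.isnan(m.snr)  # zero noise: undefined, not infinite


def test_checkerboard_oracle():
    """Exact enumeration on a 0/100 checkerboard: mean 50, population SD 50."""
    n = 64
    pix = np.indices((n, n)).sum(axis=0) % 2 * 100.0
    img = SliceImage(pix, (1.0, 1.0))
    tmpl = template_of(ROI("A", 0, 0, 14))  # ~150 px
    (m,) = measure_rois(img, tmpl)
    assert m.n_pixels >= 100
    assert m.mean_hu == pytest.approx(50.0, abs=5.0)
    assert m.noise_hu == pytest.approx(50.0, abs=2.0)


def test_membership_is_pixel_center_strict():
    """A ROI of diameter exactly 2 px spans a 2x2 block of pixel centres...

    shifted by one pixel pitch, the membership shifts identically.
    """
    img = SliceImage(np.arange(64 * 64, dtype=float).reshape(64, 64), (1.0, 1.0))
    a = measure_rois(img, template_of(ROI("A", 0.0, 0.0, 5.0)))[0]
    b = measure_rois(img, template_of(ROI("A", 1.0, 0.0, 5.0)))[0]
    assert a.n_pixels == b.n_pixels
    assert b.mean_hu == pytest.approx(a.mean_hu + 1.0)  # columns increase by 1


def test_roi_off_image_raises_with_label():
    img = flat_image(0.0)
    with pytest.raises(ROIError, match="edge"):
        measure_rois(img, template_of(ROI("edge", 31.0, 0.0, 10.0)))


def test_roi_too_small_raises():
    img = flat_image(0.0)
    with pytest.raises(ROIError, match="tiny"):
        measure_rois(img, template_of(ROI("tiny", 0.0, 0.0, 2.0)))


def test_sample_sd_option_close_to_population():
    rng = np.random.default_rng(0)
    img = SliceImage(rng.normal(0, 10, (64, 64)), (1.0, 1.0))
    tmpl = template_of(ROI("A", 0, 0, 20))
    pop = measure_rois(img, tmpl, sd_mode="population")[0]
    sam = measure_rois(img, tmpl, sd_mode="sample")[0]
    assert sam.noise_hu > pop.noise_hu
    assert sam.noise_hu == pytest.approx(pop.noise_hu, rel=0.01)


def test_snr_and_cnr_worked_values():
    assert snr(248.4, 6.9) == pytest.approx(36.0, abs=0.1)
    assert snr(0.0, 5.0) == 0.0
    assert cnr(248.4, 6.9, 0.0, 6.9) == pytest.approx(36.0, abs=0.1)
    assert cnr(100.0, 5.0, 100.0, 5.0) == 0.0
    # signed, not absolute: pellets below background carry a negative CNR
    assert cnr(-50.0, 5.0, 0.0, 5.0) < 0


def test_undefined_ratios_return_nan_not_inf():
    assert math.isnan(snr(100.0, 0.0))
    assert math.isnan(cnr(10.0, 0.0, 0.0, 0.0))


@given(
    mean=st.floats(-500, 500),
    noise=st.floats(0.1, 50),
    c=st.floats(1e-3, 1e3),
)
@settings(max_examples=100, deadline=None)
def test_snr_scale_invariance(mean, noise, c):
    assert snr(c * mean, c * noise) == pytest.approx(snr(mean, noise), rel=1e-12)


@given(
    pm=st.floats(-500, 500),
    pn=st.floats(0.1, 50),
    bm=st.floats(-500, 500),
    bn=st.floats(0.1, 50),
    offset=st.floats(-1000, 1000),
)
@settings(max_examples=100, deadline=None)
def test_cnr_translation_invariance(pm, pn, bm, bn, offset):
    assert cnr(pm + offset, pn, bm + offset, bn) == pytest.approx(
        cnr(pm, pn, bm, bn), rel=1e-9, abs=1e-9
    )


@pytest.mark.parametrize(
    "value, threshold, visible",
    [(36.0, 4.0, True), (2.9, 3.0, False), (4.0, 4.0, False)],
)
def test_rose_criterion_is_strict(value, threshold, visible):
    assert rose_flag(value, threshold) is visible


def test_rose_threshold_range_enforced():
    with pytest.raises(ValueError):
        rose_flag(10.0, threshold=2.0)


def test_default_template_is_standard(study_spec):
    tmpl = default_template(study_spec)
    tmpl.validate_standard()
    assert len(tmpl.rois) == 19
    assert tmpl.background is not None


def test_template_csv_round_trip(tmp_path, study_spec):
    tmpl = default_template(study_spec)
    path = tmp_path / "t.csv"
    tmpl.to_csv(path)
    back = ROITemplate.from_csv(path)
    assert back == tmpl


def test_reference_measurement_matches_published_band(study, measurements):
    """No-prosthesis conventional slice: the 18-pellet mean falls within the
    reference band 248.4 +/- 4.1 HU."""
    sub = measurements[
        (measurements.config == "none")
        & (measurements.recon_key == "conventional")
        & (measurements.label != "BG")
    ]
    assert len(sub) == 18
    assert abs(sub.mean_hu.mean() - 248.4) < 4.1
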