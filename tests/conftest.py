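"""Shared fixtures: a reduced-scale simulated study reused across the suite.

The study fixture runs the full 12-condition simulation once per session at
matrix 256 / 360 view angles — the scale the analysis scripts use — so the
qualitative image-level tests and the acceptance tests measure the same
object without re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from thamar.phantom import PhantomSpec, Severity, rasterize_phantom
from thamar.projection import forward_project
from thamar.study import generate_study, measure_study

STUDY_MATRIX = 256
STUDY_ANGLES = 360
STUDY_SEED = 1


def small_spec(**overrides) -> PhantomSpec:
    defaults = dict(matrix_size=STUDY_MATRIX, n_angles=STUDY_ANGLES)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def study_spec() -> PhantomSpec:
    return small_spec()


@pytest.fixture(scope="session")
def study(study_spec):
    return generate_study(seed=STUDY_SEED, spec=study_spec)


@pytest.fixture(scope="session")
def measurements(study):
    return measure_study(study)


@pytest.fixture(scope="session")
def none_truth_conv(study_spec):
    return rasterize_phantom(study_spec.with_config("none"), "conventional")


@pytest.fixture(scope="session")
def none_sino_conv(none_truth_conv):
    return forward_project(none_truth_conv, STUDY_ANGLES)


@pytest.fixture(scope="session")
def bilateral_truth_conv(study_spec):
    return rasterize_phantom(study_spec.with_config("bilateral"), "conventional")


@pytest.fixture(scope="session")
def bilateral_sino_conv(bilateral_truth_conv):
    return forward_project(bilateral_truth_conv, STUDY_ANGLES)
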