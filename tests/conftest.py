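"""Shared phantom fixtures: all synthetic, generated at test time."""

import numpy as np
import pytest

from hiemap.atlas import build_atlas, compute_z_map
from hiemap.synthetic import (
    LesionSpec,
    PhantomSpec,
    make_controls,
    make_patient,
    population_atlas,
)


@pytest.fixture(scope="session")
def small_spec():
    """Small phantom for fast tests."""
    return PhantomSpec(shape=(16, 16, 12), seed=7)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """13 controls + brain mask + parcellation on the small grid."""
    return make_controls(small_spec, 13)


@pytest.fixture(scope="session")
def small_atlas(small_cohort):
    controls, brain_mask, _ = small_cohort
    return build_atlas(controls, brain_mask)


@pytest.fixture(scope="session")
def lesioned_case(default_spec):
    """Noise-free patient with one spherical ischemic lesion (z = -3)."""
    lesion = LesionSpec(center=(16, 16, 12), radius_mm=4.0, z_offset=-3.0)
    return make_patient(default_spec, [lesion], seed=3, noise=False)


@pytest.fixture(scope="session")
def lesioned_zmap(default_spec, lesioned_case):
    atl = population_atlas(default_spec)
    _, brain_mask, _ = make_controls(default_spec, 2)
    return compute_z_map(lesioned_case.volume, atl, patient_mask=brain_mask)


@pytest.fixture(scope="session")
def default_geometry(default_spec):
    return make_controls(default_spec, 2)
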