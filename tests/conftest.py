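"""Shared fixtures: compact scenarios that keep unit tests fast."""

import numpy as np
import pytest

import callusim as cs


@pytest.fixture(scope="session")
def small_tibia_config():
    """Compact stabilized transverse tibia (same shape as the shipped
    scenario, small enough for second-scale solves)."""
    return cs.ScenarioConfig(
        bone_type="tibia", outer_diameter=20.0, cortical_thickness=4.0,
        canal_diameter=11.0, nail_diameter=10.0, segment_length=36.0,
        gap_width=2.0, fracture_kind="transverse", voxel_size=2.0)


@pytest.fixture(scope="session")
def small_tibia_model(small_tibia_config):
    return cs.build_scenario(small_tibia_config)


@pytest.fixture()
def small_tibia_state(small_tibia_model):
    return cs.initial_state(small_tibia_model)


@pytest.fixture(scope="session")
def rules():
    return cs.FuzzyRuleSet()


@pytest.fixture(scope="session")
def materials():
    return cs.MaterialTable()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)
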