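"""Shared fixtures: small maps, scenarios and simulated populations."""

from __future__ import annotations

import numpy as np
import pytest

from admixmate.forward_simulator import ScenarioConfig, run_scenario
from admixmate.mating_model import MatingParams, PriorConfig
from admixmate.synthetic_data import desk_scale_map, get_preset, toy_genetic_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_map():
    return desk_scale_map()


@pytest.fixture(scope="session")
def tiny_map():
    """Two short autosomes + X: fast generation turnover."""
    return toy_genetic_map([100.0, 80.0], include_x=True, x_length_cm=60.0)


@pytest.fixture(scope="session")
def single_autosome_map():
    return toy_genetic_map([100.0], include_x=False)


@pytest.fixture
def random_mating_params():
    return MatingParams.from_sb12((0.0, 0.0, 0.0), 0.0, 0.0)


@pytest.fixture
def moderate_params():
    return MatingParams.from_sb12((0.5, 0.5, 0.5), 0.2, -0.1)


@pytest.fixture
def tiny_scenario(tiny_map):
    return ScenarioConfig(
        genetic_map=tiny_map,
        founding_proportions=(0.3, 0.5, 0.2),
        population_size=60,
        generations=5,
    )


@pytest.fixture(scope="session")
def simulated_small():
    """One modest simulation reused by read-only tests."""
    gmap = desk_scale_map()
    config = ScenarioConfig(
        genetic_map=gmap,
        founding_proportions=get_preset("PEL").founding_proportions(),
        population_size=100,
        generations=10,
    )
    params = MatingParams.from_sb12((0.4, 0.4, 0.4), 0.1, -0.05)
    result = run_scenario(config, params, np.random.default_rng(777))
    return result


@pytest.fixture
def uniform_prior():
    return PriorConfig()
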