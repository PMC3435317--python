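"""Shared fixtures: synthetic movies and pipeline runs reused across tests.

The expensive fixtures (full-size movie generation + pipeline) are session
scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

import woundmap as wm


# At 4 µm/px the 18.5 µm reference patch is below the 8-pixel matcher
# minimum, so synthetic-movie analyses use a 32 µm (8 px) patch.
SYNTH_PATCH_UM = 32.0


@pytest.fixture(scope="session")
def synth_config() -> wm.RunConfig:
    return wm.RunConfig(patch_size_um=SYNTH_PATCH_UM)


@pytest.fixture(scope="session")
def untreated_run(synth_config):
    """Default untreated scenario, its movie/truth and a full pipeline run."""
    scenario = wm.SyntheticScenario(regime="untreated", rng_seed=1)
    movie, truth = wm.generate_movie(scenario)
    result = wm.run_experiment(movie, synth_config)
    return scenario, movie, truth, result


@pytest.fixture(scope="session")
def treated_run(synth_config):
    """Default treated (HGF/SF-like) scenario with movie/truth and run."""
    scenario = wm.SyntheticScenario(regime="treated", rng_seed=2)
    movie, truth = wm.generate_movie(scenario)
    result = wm.run_experiment(movie, synth_config)
    return scenario, movie, truth, result


@pytest.fixture(scope="session")
def small_scenario_kwargs() -> dict:
    """A compact geometry for fast generator-level tests."""
    return dict(
        height_px=64,
        width_px=128,
        pixel_size_um=4.0,
        n_frames=8,
        wound_width_um=160.0,
        edge_waviness_um=20.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
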