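"""Shared fixtures: small configurations and precomputed base runs.

Everything is generated programmatically; simulation fixtures use a coarse
timestep (5-day steps) and short horizons so the suite stays fast while the
closed-form checks remain exact.
"""

from __future__ import annotations

import numpy as np
import pytest

from initsens.config import EnvironmentSpec, load_chatham_fixture, make_toy_config
from initsens.simulator import run_simulation


@pytest.fixture(scope="session")
def chatham():
    return load_chatham_fixture()


@pytest.fixture(scope="session")
def toy_cfg():
    """Workhorse configuration: 4 age-structured groups + 2 pools, 5-day
    steps, 1980-2000 with a 5-year burn-in; fishing starts 1990."""
    return make_toy_config(
        4, 2, seed=11, timestep_hours=120.0,
        start_year=1980, end_year=2000, burn_in_years=5,
    )


@pytest.fixture(scope="session")
def base_run(toy_cfg):
    traj = run_simulation(toy_cfg, fishing_on=False, plan_id="base")
    assert traj.status == "ok"
    return traj


def constant_temperature(config, temperature_c: float):
    """Replace the environment with a spatially/seasonally constant field."""
    from dataclasses import replace

    env = config.environment
    flat = EnvironmentSpec(
        mean_temperature_c=temperature_c,
        seasonal_amplitude_c=0.0,
        box_offsets_c=tuple(0.0 for _ in env.box_offsets_c),
        spatial_distribution=env.spatial_distribution,
    )
    return replace(config, environment=flat)
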