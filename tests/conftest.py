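import numpy as np
import pytest

from swarmstall.model import default_flagellar_model
from swarmstall.swarm import (
    SwarmConfig,
    calibrate_saturation_speed,
    simulate_swarm,
    swarm_motility_model,
)


@pytest.fixture(scope="session")
def fitted_model():
    """The fitted three-state flagellar chain (rates 4, 4.76, 1.05 1/s)."""
    return default_flagellar_model()


@pytest.fixture(scope="session")
def motility_model():
    """Population-level motility chain with rare stalls."""
    return swarm_motility_model()


@pytest.fixture(scope="session")
def dense_tracks(motility_model):
    """A dense (rho = 0.3) coupled swarm, 60 s at 50 frames/s."""
    cfg = SwarmConfig(
        arena_width=60.0,
        arena_height=60.0,
        n_cells=None,
        surface_fraction=0.3,
        duration=60.0,
        frame_interval=0.02,
        seed=2,
    )
    cfg = calibrate_saturation_speed(cfg, motility_model, 20.0)
    return cfg, simulate_swarm(cfg, motility_model, seed=9)


@pytest.fixture(scope="session")
def uncoupled_tracks(fitted_model):
    """A small uncoupled swarm driven by the fitted flagellar chain."""
    cfg = SwarmConfig(
        arena_width=40.0,
        arena_height=40.0,
        n_cells=20,
        duration=120.0,
        frame_interval=0.02,
        coupling_enabled=False,
        seed=3,
    )
    return cfg, simulate_swarm(cfg, fitted_model, seed=21)
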