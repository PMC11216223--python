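"""Shared fixtures.

The expensive fixture is ``trained_policies``: three policy variants trained
under one matched, scaled-down budget (small start distances, short horizon,
nutrient-rich concentrations) at cell radius 2 um.  It is session-scoped and
only built when a test actually requests it.
"""

from __future__ import annotations

import numpy as np
import pytest

from chemonav import (
    CellParams,
    EpisodeConfig,
    FieldParams,
    NeuralPolicy,
    PolicySpec,
    init_params,
)
from chemonav.training import PPOConfig, train


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def field():
    return FieldParams(C0=16.0, lambda_decay=0.032)


@pytest.fixture
def cell():
    return CellParams(radius=2.0, n_sensors=5, speed=5.0, rot_diffusion=0.025)


@pytest.fixture
def episode_config():
    return EpisodeConfig()


# -- scaled-down study conditions -------------------------------------------
# Short episodes in the nutrient-rich regime: start distances 40-70 um from
# the source (straight-line travel 6-12 s), a 30 s horizon, and a fixed peak
# concentration of 100 x 16 um^-2 so the sensing signal-to-noise is high.

SCALED_FIELD = FieldParams(C0=1600.0, lambda_decay=0.032)
SCALED_EPISODE = EpisodeConfig(
    d0_range=(40.0, 70.0),
    delta=10.0,
    t_max=30.0,
    dt=0.2,
    conc_scale_range=(1600.0, 1600.0),
)
SCALED_CELL = CellParams(radius=2.0)
SCALED_SPEC = dict(n_sensors=5, hidden_size=32, mlp_widths=(32,))


def scaled_ppo(variant: str, total_updates: int = 200, seed: int = 3) -> PPOConfig:
    """Matched data budget (256 episodes x 200 updates) for every variant;
    optimizer settings are tuned per architecture class (transition
    minibatches for the feedforward net, episode minibatches for the
    recurrent ones)."""
    recurrent = variant != "spatial"
    return PPOConfig(
        discount=1.0,
        gae_lambda=0.95,
        epochs_per_update=4,
        learning_rate=2e-3 if recurrent else 1e-3,
        total_updates=total_updates,
        n_parallel_episodes=256,
        minibatch_size=64 if recurrent else 4096,
        seed=seed,
    )


@pytest.fixture(scope="session")
def trained_policies():
    """Train spatial, temporal and combined under the matched scaled budget.

    Returns ``{variant: (policy, training_log)}``.
    """
    out = {}
    for variant in ("spatial", "temporal", "combined"):
        spec = PolicySpec(variant, **SCALED_SPEC)
        params, log = train(
            spec, SCALED_EPISODE, SCALED_FIELD, SCALED_CELL, scaled_ppo(variant)
        )
        out[variant] = (NeuralPolicy(spec, params), log)
    return out


@pytest.fixture
def small_spec():
    return PolicySpec("combined", n_sensors=5, hidden_size=8, mlp_widths=(16,))


@pytest.fixture
def small_policy(small_spec, rng):
    return NeuralPolicy(small_spec, init_params(small_spec, rng))
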