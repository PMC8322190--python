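"""Shared fixtures: small, fast synthetic trials and state streams.

Unit tests use scaled-down trials (16 channels, 64 Hz generation) so the
whole suite stays quick; the acceptance tests use the generator defaults.
"""

import numpy as np
import pytest

from aadrl import (DQLConfig, GeneratorConfig, StateConfig, build_states,
                   make_switch_schedule, synthesize_trial)
from aadrl.preprocess import prepare_trial
from aadrl.states import StateSequence


@pytest.fixture(scope="session")
def small_gen_cfg():
    return GeneratorConfig(n_channels=16, fs=64.0, seed=0)


@pytest.fixture(scope="session")
def no_switch_trial(small_gen_cfg):
    schedule = make_switch_schedule(60.0, 60.0, "left")
    return synthesize_trial(schedule, small_gen_cfg, seed=1)


@pytest.fixture(scope="session")
def state_seq(no_switch_trial):
    return build_states(no_switch_trial, StateConfig(n_channel_groups=4))


@pytest.fixture(scope="session")
def switching_seq(small_gen_cfg):
    schedule = make_switch_schedule(15.0, 60.0, "left")
    trial = synthesize_trial(schedule, small_gen_cfg, seed=2)
    return build_states(trial, StateConfig(n_channel_groups=4))


@pytest.fixture
def toy_separable_seq():
    """Stream whose first feature's sign determines the label exactly."""
    rng = np.random.default_rng(0)
    T = 300
    y = (rng.random(T) < 0.5).astype(np.int8)
    F = np.column_stack([
        np.where(y == 0, 1.0, -1.0) + 0.05 * rng.standard_normal(T),
        0.05 * rng.standard_normal(T),
    ])
    return StateSequence(F, y, np.arange(T) * 125.0, 125.0)


@pytest.fixture
def small_dql_cfg():
    return DQLConfig(n_hidden=8, n_hidden_layers=1, max_inner_iters=10, seed=0)
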