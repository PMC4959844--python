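"""Shared simulation fixtures (session-scoped: each run happens once)."""

from __future__ import annotations

import numpy as np
import pytest

import larvacrawl as lc


@pytest.fixture(scope="session")
def params():
    return lc.default_params()


@pytest.fixture(scope="session")
def baseline_traj(params):
    """Full model, default parameters, pulse to E10, 500 tau_E."""
    return lc.simulate(params, lc.preset_protocol("fig2_baseline"))


@pytest.fixture(scope="session")
def baseline_metrics(baseline_traj):
    return lc.compute_metrics(baseline_traj, with_phases=True)


@pytest.fixture(scope="session")
def silenced_traj(params):
    """Proprioception silenced (w_Ep = w_Ip = 0), otherwise baseline."""
    return lc.simulate(params, lc.preset_protocol("fig4_no_proprio"))


@pytest.fixture(scope="session")
def silenced_metrics(silenced_traj):
    return lc.compute_metrics(silenced_traj)


@pytest.fixture(scope="session")
def stationary_traj(params):
    """No initiation pulse: the larva never moves."""
    proto = lc.Protocol(pulse=lc.Pulse(height=0.0), duration=50.0)
    return lc.simulate(params, proto)


def random_valid_state(params, rng, scale=0.05):
    """Random state satisfying the head-tail rod constraint exactly."""
    state = lc.rest_state(params)
    state.E = rng.uniform(0, 1, 10)
    state.I = rng.uniform(0, 1, 10)
    state.f = rng.uniform(0, params.f_max, 10)
    state.x[:-1] += rng.normal(0, scale, 10)
    state.x[-1] = state.x[0] - params.n_units * params.L
    state.v[:-1] = rng.normal(0, scale, 10)
    state.v[-1] = state.v[0]
    return state
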