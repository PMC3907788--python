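"""Shared fixtures.  Network trials are expensive, so one batch of control
and knock-out trials is simulated once per session and shared by every test
that inspects persistent-activity behaviour."""

from __future__ import annotations

import numpy as np
import pytest

from pfcmicro.cells import build_cell
from pfcmicro.network import (ManipulationSpec, NetworkSpec, apply_manipulation,
                              build_network)
from pfcmicro.protocols import StimulusSpec, run_induction_trial

N_SEEDS = 10


@pytest.fixture(scope="session")
def cells():
    return {ct: build_cell(ct) for ct in ("PYR", "FS", "RS", "IS")}


@pytest.fixture(scope="session")
def control_network():
    return build_network(NetworkSpec(seed=1))


@pytest.fixture(scope="session")
def stimulus():
    return StimulusSpec()


@pytest.fixture(scope="session")
def control_trials(control_network, stimulus):
    """(induced, SpikeTrainSet, TraceSet) for N_SEEDS control trials."""
    out = []
    for seed in range(1, N_SEEDS + 1):
        out.append(run_induction_trial(control_network, stimulus, seed=seed))
    return out


@pytest.fixture(scope="session")
def fs_ko_network(control_network):
    return apply_manipulation(control_network, ManipulationSpec(mode="fs_ko"))


@pytest.fixture(scope="session")
def fs_ko_trials(fs_ko_network, stimulus):
    out = []
    for seed in range(1, N_SEEDS + 1):
        out.append(run_induction_trial(fs_ko_network, stimulus, seed=seed,
                                       record_currents=False))
    return out


def poisson_train(rate_hz: float, duration_ms: float, rng) -> np.ndarray:
    """Homogeneous Poisson spike train helper for analysis-module tests."""
    n = rng.poisson(rate_hz * duration_ms * 1e-3)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))
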