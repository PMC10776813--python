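"""Shared fixtures: default parameter sets and cached campaign tables.

The sweep tables are expensive (seconds to tens of seconds each), so they are
computed once per session and shared between the module tests and the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import spindlesim as ss
from spindlesim import experiments as exp


@pytest.fixture(scope="session")
def config() -> exp.Config:
    return exp.default_config()


@pytest.fixture(scope="session")
def bag_params():
    return ss.FibreParams.bag()


@pytest.fixture(scope="session")
def chain_params():
    return ss.FibreParams.chain()


@pytest.fixture(scope="session")
def ramp_result(config):
    """Tuned-model ramp-and-hold (36% L0/s to 5.6% L0) through both fibres."""
    protocol = ss.ramp_hold(config.ramp_velocity, config.ramp_amplitude)
    return protocol, exp.simulate_spindle(protocol, config)


@pytest.fixture(scope="session")
def paired_result(config):
    """Tuned-model paired triangles (12% L0/s, 5.6% L0, ISI 0)."""
    protocol = ss.triangle_pair(12.0, 5.6, 5.6, isi=0.0)
    return protocol, exp.simulate_spindle(protocol, config)


@pytest.fixture(scope="session")
def isi_table(config):
    return exp.run_isi_sweep(config)


@pytest.fixture(scope="session")
def amplitude_table(config):
    return exp.run_amplitude_sweep(config)


@pytest.fixture(scope="session")
def sinusoid_table(config):
    return exp.run_sinusoid_sweep(config)


@pytest.fixture(scope="session")
def ladder_table(config):
    return exp.run_thin_filament_ladder(config)


@pytest.fixture(scope="session")
def chain_steady_activation(config):
    """Chain fibre held isometric at L0 and pCa 6.4 to steady state."""
    protocol = ss.ramp_hold(36.0, 0.0, total=2.0)
    trace = exp.run_fibre(protocol, config.chain, config.dt, config.pca, config.grid)
    return float(trace.actin_activated[-1])
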