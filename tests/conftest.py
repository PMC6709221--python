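"""Shared fixtures: small, fast synthetic study configurations."""

import numpy as np
import pytest

from hinet.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast subject: few regions/heartbeats, reduced sampling rate."""
    return SimulationConfig(
        n_regions=8,
        n_sensors=16,
        n_heartbeats=60,
        sampling_rate=250.0,
        mean_ibi=900.0,
        ibi_sd=60.0,
        seed=7,
    )


@pytest.fixture
def coupled_config(small_config):
    """Same, with one strongly induced theta edge (0, 1) at pi/2 lag."""
    import dataclasses

    return dataclasses.replace(
        small_config,
        coupled_edges=[(0, 1, np.pi / 2, 1.0)],
        burst_amplitude=3.0,
        noise_sd=1.0,
    )
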