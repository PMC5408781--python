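import numpy as np
import pytest

from latcirc.circuit_model import Circuit, ParameterSet, SimulationConfig, Topology


@pytest.fixture
def empty_circuit():
    """Two unregulated genes (only basal alpha behavior)."""
    return Circuit(Topology(((0, 0), (0, 0)), (0, 0)),
                   ParameterSet(((0, 0), (0, 0)), (0, 0), (-60.0, -60.0), 5.0))


@pytest.fixture
def silent_circuit():
    """Two genes with prohibitive activation thresholds: everything decays."""
    return Circuit(Topology(((0, 0), (0, 0)), (0, 0)),
                   ParameterSet(((0, 0), (0, 0)), (0, 0), (60.0, 60.0), 5.0))


@pytest.fixture
def mutual_repression_circuit():
    """Intercellular mutual repression of D: a robust lateral-inhibition core."""
    return Circuit(Topology(((0, 0), (0, 0)), (-1, 0)),
                   ParameterSet(((0, 0), (0, 0)), (-3.0, 0.0), (-10.0, 60.0), 10.0))


@pytest.fixture
def quiet_config():
    return SimulationConfig(noise_amplitude=0.0, max_steps=600, seed=1)


@pytest.fixture
def noisy_config():
    return SimulationConfig(noise_amplitude=0.01, max_steps=1200, seed=7)
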