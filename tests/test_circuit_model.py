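"""Unit and property tests of the multicellular and two-cell simulators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latcirc.circuit_model import (Circuit, ParameterSet, SimulationConfig,
                                   Topology, TwoCellState, circuit_from_dict,
                                   circuit_to_dict, load_circuit, net_input,
                                   noise_factors, regulation_rate, save_circuit,
                                   simulate_tissue, simulate_two_cell, step)


# ---------------------------------------------------------------------------
# Regulation function
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, alpha, beta, expected, tol", [
    (0.0, 0.0, 5.0, 0.5, 0.0),                      # sigmoid midpoint
    (0.0, -60.0, 5.0, 1.0, 1e-20),                  # constitutive expression
    (1.0, 15.0, 10.0, 1.0 / (1.0 + math.exp(5.0)), 1e-15),
])
def test_regulation_rate_reference_values(x, alpha, beta, expected, tol):
    assert regulation_rate(x, alpha, beta) == pytest.approx(expected, abs=tol)


@given(x=st.floats(-50, 50), alpha=st.floats(-60, 60),
       beta=st.sampled_from([5.0, 10.0]))
def test_regulation_rate_bounded_and_increasing(x, alpha, beta):
    y = regulation_rate(x, alpha, beta)
    assert 0.0 <= y <= 1.0
    assert regulation_rate(x + 0.5, alpha, beta) >= y


# ---------------------------------------------------------------------------
# Net input
# ---------------------------------------------------------------------------

def test_net_input_empty_topology_is_zero(empty_circuit):
    cfg = SimulationConfig(trigger_value=0.0)
    state = np.full((2, cfg.n_cells), 3.0)
    assert net_input(empty_circuit, state, 4, 0, cfg) == 0.0


def test_net_input_single_intra_link():
    circ = Circuit(Topology(((0, 1), (0, 0)), (0, 0)),
                   ParameterSet(((0, 2.0), (0, 0)), (0, 0), (0, 0), 5.0))
    cfg = SimulationConfig(trigger_value=0.0)
    state = np.zeros((2, cfg.n_cells))
    state[1, 10] = 3.0
    assert net_input(circ, state, 10, 0, cfg) == pytest.approx(6.0)


def test_net_input_trigger_and_context_targeting():
    circ = Circuit(Topology(((0, 0), (0, 0)), (0, 0)),
                   ParameterSet(((0, 0), (0, 0)), (0, 0), (0, 0), 5.0))
    cfg = SimulationConfig(trigger_value=1.0, trigger_gene=1,
                           context_value=0.5, context_gene=0)
    state = np.zeros((2, cfg.n_cells))
    assert net_input(circ, state, cfg.trigger_cell, 1, cfg) == pytest.approx(1.0)
    assert net_input(circ, state, 0, 0, cfg) == pytest.approx(0.5)
    assert net_input(circ, state, 3, 1, cfg) == 0.0


def test_net_input_mirror_boundary_doubles_edge_contribution():
    # mirror ghost copies the edge cell; with g[edge] == g[interior neighbor]
    # the inter contribution is exactly twice the interior-side one
    circ = Circuit(Topology(((0, 0), (0, 0)), (1, 0)),
                   ParameterSet(((0, 0), (0, 0)), (1.5, 0), (0, 0), 5.0))
    cfg = SimulationConfig(trigger_value=0.0, boundary="mirror")
    state = np.zeros((2, cfg.n_cells))
    state[0, 0] = 4.0
    state[0, 1] = 4.0
    # brute-force sum under the boundary rule: ghost(= cell 0) + cell 1
    assert net_input(circ, state, 0, 0, cfg) == pytest.approx(1.5 * 8.0)
    cfg_zero = cfg.replace(boundary="zero")
    assert net_input(circ, state, 0, 0, cfg_zero) == pytest.approx(1.5 * 4.0)


def test_net_input_rejects_bad_cell(empty_circuit):
    cfg = SimulationConfig()
    state = np.zeros((2, cfg.n_cells))
    with pytest.raises(IndexError):
        net_input(empty_circuit, state, cfg.n_cells, 0, cfg)


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def test_step_constitutive_monotone_approach_to_fixed_point(empty_circuit):
    # isolated constitutive gene: dg = phi - lambda*g with phi ~= 1, so the
    # fixed point is 1/lambda = 20 and the noise-free approach is monotone
    cfg = SimulationConfig(noise_amplitude=0.0, trigger_value=0.0)
    state = np.full((2, cfg.n_cells), 0.1)
    values = [state[0, 0]]
    for _ in range(400):
        state = step(state, empty_circuit, cfg)
        values.append(state[0, 0])
    values = np.array(values)
    assert np.all(np.diff(values) >= -1e-12)
    assert values[-1] == pytest.approx(20.0, abs=1e-4)


def test_step_silent_gene_geometric_decay(silent_circuit):
    cfg = SimulationConfig(noise_amplitude=0.0, trigger_value=0.0)
    state = np.full((2, cfg.n_cells), 8.0)
    new = step(state, silent_circuit, cfg)
    # production phi(60) is ~1e-26; decay dominates: factor (1 - lambda*dt)
    assert np.allclose(new, 8.0 * (1 - 0.05), atol=1e-9)


def test_step_noise_stays_within_envelope(empty_circuit):
    cfg = SimulationConfig(noise_amplitude=0.01, trigger_value=0.0)
    state = np.full((2, cfg.n_cells), 10.0)
    det = step(state, empty_circuit, cfg)
    nf = noise_factors(123, 1, cfg.n_cells, cfg.noise_amplitude)
    noisy = step(state, empty_circuit, cfg, noise=nf)
    assert np.all(np.abs(noisy - det) <= 0.01 * det + 1e-12)


# ---------------------------------------------------------------------------
# Tissue simulation invariants
# ---------------------------------------------------------------------------

def test_simulation_nonnegative_and_bounded(mutual_repression_circuit, noisy_config):
    trace = simulate_tissue(mutual_repression_circuit, noisy_config)
    assert trace.concentrations.min() >= 0.0
    assert trace.concentrations[200:].max() <= 25.0


def test_seed_determinism(mutual_repression_circuit, noisy_config):
    t1 = simulate_tissue(mutual_repression_circuit, noisy_config)
    t2 = simulate_tissue(mutual_repression_circuit, noisy_config)
    assert np.array_equal(t1.concentrations, t2.concentrations)
    t3 = simulate_tissue(mutual_repression_circuit,
                         noisy_config.replace(seed=noisy_config.seed + 1))
    assert not np.array_equal(t1.concentrations, t3.concentrations)


def test_isometry_equivariance_of_simulation(quiet_config):
    # an asymmetric circuit: relabeling genes everywhere swaps the gene axis
    circ = Circuit(Topology(((0, 1), (-1, 0)), (1, -1)),
                   ParameterSet(((0, 2.5), (-1.5, 0)), (3.0, -0.5),
                                (-5.0, 10.0), 5.0))
    cfg = quiet_config.replace(trigger_gene=0, context_gene=1, context_value=1.0)
    mirrored_cfg = cfg.replace(trigger_gene=1, context_gene=0)
    t = simulate_tissue(circ, cfg)
    tm = simulate_tissue(circ.mirror(), mirrored_cfg)
    assert np.array_equal(t.concentrations, tm.concentrations[:, ::-1, :])


def test_halving_dt_changes_final_state_less_than_one_percent(quiet_config):
    circ = Circuit(Topology(((1, 0), (0, 0)), (0, 1)),
                   ParameterSet(((2.0, 0), (0, 0)), (0, 1.0), (-10.0, 20.0), 5.0))
    cfg = quiet_config.replace(max_steps=2000)
    final_1 = simulate_tissue(circ, cfg).final
    cfg_half = cfg.replace(dt=0.5, max_steps=4000)
    final_2 = simulate_tissue(circ, cfg_half).final
    denom = np.maximum(np.abs(final_1), 1.0)
    assert np.max(np.abs(final_1 - final_2) / denom) < 0.01


# ---------------------------------------------------------------------------
# Two-cell model
# ---------------------------------------------------------------------------

def test_two_cell_exchange_symmetry():
    circ = Circuit(Topology(((0, 1), (1, 0)), (1, 1)),
                   ParameterSet(((0, 1.0), (2.0, 0)), (0.5, 0.5),
                                (5.0, 5.0), 5.0))
    traj = simulate_two_cell(circ, T=0.0, C=0.0,
                             init=TwoCellState(0.3, 0.2, 0.3, 0.2),
                             duration=500)
    assert np.allclose(traj[:, 0], traj[:, 2])
    assert np.allclose(traj[:, 1], traj[:, 3])
    assert traj.min() >= 0.0


def test_two_cell_trigger_breaks_symmetry():
    circ = Circuit(Topology(((0, 0), (0, 0)), (0, 0)),
                   ParameterSet(((0, 0), (0, 0)), (0, 0), (5.0, 5.0), 5.0))
    traj = simulate_two_cell(circ, T=1.0, C=0.0,
                             init=TwoCellState(0.1, 0.1, 0.1, 0.1),
                             duration=300, trigger_gene=1)
    assert traj[-1, 1] > traj[-1, 3]  # triggered gene higher in cell 1


# ---------------------------------------------------------------------------
# Types and serialization
# ---------------------------------------------------------------------------

def test_parameter_sign_validation():
    topo = Topology(((0, 1), (0, 0)), (0, 0))
    with pytest.raises(ValueError):
        Circuit(topo, ParameterSet(((0, -1.0), (0, 0)), (0, 0), (0, 0), 5.0))
    with pytest.raises(ValueError):
        Circuit(topo, ParameterSet(((0, 1.0), (0, 0.5)), (0, 0), (0, 0), 5.0))


def test_topology_canonicalization_roundtrip():
    topo = Topology(((0, 1), (-1, 0)), (1, -1), signaling=1)
    canon = topo.canonical()
    assert canon.signaling == 0
    assert canon.mirror().canonical() == canon
    assert Topology.decode(topo.encode()) == topo


def test_config_rejects_even_tissue_and_bad_noise():
    with pytest.raises(ValueError):
        SimulationConfig(n_cells=10)
    with pytest.raises(ValueError):
        SimulationConfig(noise_amplitude=0.2)


def test_circuit_serialization_roundtrip(tmp_path, mutual_repression_circuit):
    d = circuit_to_dict(mutual_repression_circuit)
    assert circuit_from_dict(d) == mutual_repression_circuit
    for suffix in (".json", ".yaml"):
        path = tmp_path / f"circ{suffix}"
        save_circuit(mutual_repression_circuit, path, SimulationConfig())
        loaded, cfg = load_circuit(path)
        assert loaded == mutual_repression_circuit
        assert cfg == SimulationConfig()


def test_trace_export_shape(empty_circuit, tmp_path):
    cfg = SimulationConfig(noise_amplitude=0.0, max_steps=5)
    trace = simulate_tissue(empty_circuit, cfg)
    frame = trace.to_frame()
    assert set(frame.columns) == {"step", "gene", "cell", "value"}
    assert len(frame) == 6 * 2 * cfg.n_cells
    trace.to_csv(tmp_path / "trace.csv")
    assert (tmp_path / "trace.csv").exists()


def test_noise_stream_is_counter_based():
    a = noise_factors(5, 17, 33, 0.01)
    b = noise_factors(np.array([4, 5, 6]), 17, 33, 0.01)
    assert np.array_equal(a, b[1])
    assert np.abs(a - 1.0).max() <= 0.01
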