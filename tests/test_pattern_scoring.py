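"""Tests of the induction/inhibition objective functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latcirc.circuit_model import (BatchParams, Circuit, ParameterSet,
                                   SimulationConfig, Topology, derive_seeds)
from latcirc.pattern_scoring import (ABSOLUTE_THRESHOLD, at_equilibrium, binarize,
                                     classify_circuit, classify_rows, classify_run,
                                     count_switches, expansion, verdict_name)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def test_binarize_absolute_uniform_high():
    pat = binarize(np.full(33, 20.0), "absolute")
    assert pat.labels.all() and pat.threshold == ABSOLUTE_THRESHOLD


def test_binarize_adaptive_alternating():
    profile = np.where(np.arange(33) % 2 == 0, 18.0, 0.5)
    pat = binarize(profile, "adaptive")
    assert np.array_equal(pat.labels, np.arange(33) % 2 == 0)


def test_binarize_adaptive_contrast_floor():
    rng = np.random.default_rng(0)
    flat = 0.1 + 0.01 * rng.random(33)
    assert not binarize(flat, "adaptive").labels.any()


def test_binarize_unknown_scheme():
    with pytest.raises(ValueError):
        binarize(np.zeros(5), "quantile")


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

def _expansion_oracle(labels):
    """Brute force: longest contiguous run of highs containing the center."""
    n = len(labels)
    c = n // 2
    best = 0
    for i in range(n):
        for j in range(i, n):
            if i <= c <= j and all(labels[i:j + 1]):
                best = max(best, j - i + 1)
    return best


def test_expansion_reference_patterns():
    n = 33
    assert expansion(np.ones(n, dtype=bool)) == n
    only_center = np.zeros(n, dtype=bool)
    only_center[n // 2] = True
    assert expansion(only_center) == 1
    center_plus_right = only_center.copy()
    center_plus_right[n // 2 + 1:n // 2 + 3] = True
    assert expansion(center_plus_right) == 3
    assert expansion(~only_center) == 0


@given(st.lists(st.booleans(), min_size=5, max_size=21).filter(lambda x: len(x) % 2))
def test_expansion_matches_bruteforce(bits):
    labels = np.array(bits, dtype=bool)
    assert expansion(labels) == _expansion_oracle(labels)


def test_expansion_monotone_under_contiguous_growth():
    n = 17
    labels = np.zeros(n, dtype=bool)
    labels[n // 2] = True
    prev = expansion(labels)
    for k in range(1, n // 2 + 1):
        labels[n // 2 + k] = True
        cur = expansion(labels)
        assert cur >= prev
        prev = cur


# ---------------------------------------------------------------------------
# Switch counting
# ---------------------------------------------------------------------------

def _switches_oracle(labels):
    return sum(1 for a, b in zip(labels[:-1], labels[1:]) if a and not b)


def test_switches_reference_patterns():
    n = 33
    alt_high = np.arange(n) % 2 == 0      # starts high
    alt_low = ~alt_high
    assert count_switches(alt_high) == 16
    assert count_switches(alt_low) == 16
    assert count_switches(np.ones(n, dtype=bool)) == 0
    assert count_switches(np.zeros(n, dtype=bool)) == 0


@given(st.lists(st.booleans(), min_size=2, max_size=33))
def test_switches_match_oracle_and_bound(bits):
    labels = np.array(bits, dtype=bool)
    got = count_switches(labels)
    assert got == _switches_oracle(bits)
    assert got <= len(bits) // 2


# ---------------------------------------------------------------------------
# Equilibrium detection
# ---------------------------------------------------------------------------

def _steady_trace(profile, n_steps=260):
    return np.tile(np.asarray(profile)[None, :, :], (n_steps, 1, 1))


def test_equilibrium_on_settled_profile():
    prof = np.stack([np.full(33, 20.0), np.full(33, 0.05)])
    eq, step_idx = at_equilibrium(_steady_trace(prof))
    assert eq and step_idx == 259


def test_no_equilibrium_during_oscillation():
    a = np.stack([np.full(33, 20.0), np.full(33, 0.05)])
    b = np.stack([np.full(33, 0.05), np.full(33, 20.0)])
    concs = np.array([a if t % 40 < 20 else b for t in range(300)])
    assert not at_equilibrium(concs)[0]


def test_no_equilibrium_while_still_rising():
    t = np.arange(300)[:, None, None]
    concs = 0.1 + 0.05 * t * np.ones((300, 2, 33))
    assert not at_equilibrium(concs)[0]


def test_short_trace_is_not_at_equilibrium():
    prof = np.stack([np.full(33, 20.0), np.full(33, 0.0)])
    assert not at_equilibrium(_steady_trace(prof, n_steps=150))[0]


# ---------------------------------------------------------------------------
# Run classification
# ---------------------------------------------------------------------------

def _trace_from_expansion_schedule(schedule, n=33, tail=260, high=20.0, low=0.05):
    """Concentrations whose absolute pattern follows an expansion schedule."""
    frames = []
    for width, repeats in schedule:
        labels = np.zeros(n, dtype=bool)
        if width:
            c = n // 2
            half = (width - 1) // 2
            labels[c - half:c - half + width] = True
        prof = np.where(labels, high, low)
        frame = np.stack([prof, np.full(n, low)])
        frames.extend([frame] * repeats)
    frames.extend([frames[-1]] * tail)
    return np.array(frames)


def test_classify_run_wavelike_growth_is_induction():
    schedule = [(0, 10), (1, 10), (3, 10), (7, 10), (15, 10), (25, 10), (33, 10)]
    concs = _trace_from_expansion_schedule(schedule)
    call = classify_run(concs)
    assert call.verdict == "induction"
    assert call.diagnostics["per_gene"][0]["expansion_increases"] >= 5


def test_classify_run_single_jump_is_none():
    concs = _trace_from_expansion_schedule([(0, 30), (33, 30)])
    call = classify_run(concs)
    assert call.verdict == "none"


def test_classify_run_alternating_equilibrium_is_inhibition():
    n = 33
    labels = np.arange(n) % 2 == 0
    prof = np.where(labels, 18.0, 0.4)
    concs = np.tile(np.stack([prof, np.full(n, 0.4)])[None], (300, 1, 1))
    call = classify_run(concs)
    assert call.verdict == "inhibition"
    assert call.diagnostics["per_gene"][0]["switches"] == 16


def test_classify_circuit_empty_is_none(empty_circuit, noisy_config):
    call = classify_circuit(empty_circuit, noisy_config.replace(max_steps=900))
    assert call.verdict == "none"
    assert len(call.diagnostics["per_run"]) == 4


def test_classify_circuit_mutual_repression_inhibits(mutual_repression_circuit):
    cfg = SimulationConfig(noise_amplitude=0.01, seed=11)
    call = classify_circuit(mutual_repression_circuit, cfg)
    assert call.verdict == "inhibition"


def test_classification_invariant_under_relabeling(mutual_repression_circuit):
    cfg = SimulationConfig(noise_amplitude=0.0, seed=3)
    call = classify_circuit(mutual_repression_circuit, cfg)
    mirrored = mutual_repression_circuit.mirror()
    call_m = classify_circuit(mirrored, cfg.replace(
        trigger_gene=1 - cfg.trigger_gene, context_gene=1 - cfg.context_gene))
    assert call.verdict == call_m.verdict


def test_verdict_stable_when_cap_raised(mutual_repression_circuit):
    cfg = SimulationConfig(noise_amplitude=0.01, seed=5, max_steps=2000)
    v1 = classify_circuit(mutual_repression_circuit, cfg).verdict
    v2 = classify_circuit(mutual_repression_circuit,
                          cfg.replace(max_steps=4000)).verdict
    assert v1 == v2


# ---------------------------------------------------------------------------
# Streaming classifier agrees with the trace-based one
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("circuit_fixture", ["empty_circuit", "silent_circuit",
                                             "mutual_repression_circuit"])
def test_streaming_matches_per_run_classification(circuit_fixture, request):
    circuit = request.getfixturevalue(circuit_fixture)
    cfg = SimulationConfig(noise_amplitude=0.01, seed=21)
    keys = derive_seeds(cfg.seed, 4)
    p = circuit.params
    reps = np.ones(4, dtype=int)
    bp = BatchParams(
        intra_w=np.array([p.intra_w] * 4), inter_w=np.array([p.inter_w] * 4),
        alpha=np.array([p.alpha] * 4), beta=np.array([p.beta] * 4),
        trigger_gene=np.zeros(4, dtype=int), context_gene=np.zeros(4, dtype=int),
        context_value=np.zeros(4), signaling=circuit.signaling)
    res = classify_rows(bp, cfg, keys)
    call = classify_circuit(circuit, cfg)
    streaming = [verdict_name(c) for c in res["verdict_code"]]
    assert streaming == call.diagnostics["per_run"]
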