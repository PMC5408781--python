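"""Objective functions for lateral induction and lateral inhibition.

A simulation is scored on binarized expression profiles.  Two binarization
schemes serve the two functions:

* ``absolute`` -- a cell is "high" when its concentration is at least 10,
  half of the maximal steady expression level ``1/decay = 20``.  Used for
  the *expansion* measure, because the induction end state is uniformly
  high (a relative threshold is meaningless there).
* ``adaptive`` -- a cell is "high" when it exceeds the midpoint of the
  profile's range, provided the range spans at least 2.0 concentration
  units (the contrast floor); otherwise all cells are low.  Used for the
  alternation (switch) count, because inhibition is about contrast between
  neighbors, not absolute level.  Inside the classifiers the adaptive
  scheme is applied to 100-step window-mean profiles: the per-step +/-1%
  multiplicative noise integrates (AR(1), decay 0.05) to ~1.9% of the
  expression level, so instantaneous profiles carry a cross-tissue spread
  of order 1.5 units that would make raw adaptive labels flicker, while
  window means fluctuate by only ~0.2 units.

*Lateral induction* is a dynamical verdict: the expansion (the contiguous
run of high cells containing the central, triggered cell) must strictly
exceed its running maximum on at least five distinct steps and finish equal
to the tissue size, at equilibrium.  *Lateral inhibition* is an end-state
verdict: the equilibrium pattern must alternate, counting at least
``min_switches`` high-to-low transitions (default 14, i.e. strictly more
than 13; a perfect alternating 33-cell pattern counts 16).  Equilibrium
requires the absolute patterns of both genes to be unchanged for 100
consecutive steps, window-mean drift per cell below a noise-aware
tolerance, and the adaptive window-mean patterns to agree across
consecutive windows.  A circuit-level verdict additionally requires four
independent noise runs to reach equilibrium and agree; when the two genes
of a run qualify for different functions, inhibition takes precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit_model import (BatchParams, Circuit, SimulationConfig, TissueTrace,
                            batch_initial_state, batch_step, derive_seeds,
                            noise_factors, simulate_tissue)

#: Absolute "high" threshold: half of the maximal steady level 1/decay = 20.
ABSOLUTE_THRESHOLD = 10.0
#: Minimum max-min range for the adaptive scheme to declare any cell high.
#: Chosen safely above the stationary noise spread of window-mean profiles.
CONTRAST_FLOOR = 2.0
#: Consecutive stable steps required for equilibrium.
EQUILIBRIUM_WINDOW = 100
#: Drift tolerance: windowed means may differ by up to this multiple of the
#: cell's own within-window standard deviation (stationary noise gives mean
#: differences of ~0.9 sigma; a linear trend gives ~3.4 sigma, so transients
#: still fail), with relative and absolute floors below.
DRIFT_STD_FACTOR = 2.5
DRIFT_TOL = 0.05
#: Absolute drift floor: 5% of the 0-20 dynamic range.  Sub-unit wander of
#: cells resting on the sigmoid shoulder carries no pattern information;
#: pattern-relevant transients are caught by the pattern-stability clauses.
DRIFT_ABS = 1.0
#: Number of distinct expansion increases required for induction.
MIN_EXPANSION_INCREASES = 5
#: Minimum steps between counted expansion increases.  A genuine inductive
#: wave advances about one cell per >= 10 steps; a uniform constitutive
#: rise crosses the threshold near-simultaneously everywhere, and without
#: this gap the noise-split crossing would mimic a propagating wave.
MIN_INCREASE_GAP = 5
#: High-to-low switches required for inhibition ("more than 13").
DEFAULT_MIN_SWITCHES = 14
#: Independent noise runs that must agree for a circuit-level verdict.
N_NOISE_RUNS = 4

VERDICT_NONE, VERDICT_INDUCTION, VERDICT_INHIBITION = "none", "induction", "inhibition"
_CODE = {0: VERDICT_NONE, 1: VERDICT_INDUCTION, 2: VERDICT_INHIBITION}


@dataclass(frozen=True)
class BinarizedPattern:
    """Per-cell high/low labels of one gene's profile at one time."""

    labels: np.ndarray
    scheme: str
    threshold: float

    @property
    def n_cells(self) -> int:
        return len(self.labels)


@dataclass
class PatternCall:
    """Verdict of a run or circuit with its scoring diagnostics."""

    verdict: str
    gene: int | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary pattern measures
# ---------------------------------------------------------------------------

def binarize(profile, scheme: str = "absolute") -> BinarizedPattern:
    """Label each cell high/low under the given scheme."""
    profile = np.asarray(profile, dtype=float)
    if scheme == "absolute":
        thr = ABSOLUTE_THRESHOLD
        labels = profile >= thr
    elif scheme == "adaptive":
        lo, hi = profile.min(), profile.max()
        if hi - lo < CONTRAST_FLOOR:
            thr = np.inf
            labels = np.zeros_like(profile, dtype=bool)
        else:
            thr = 0.5 * (lo + hi)
            labels = profile >= thr
    else:
        raise ValueError(f"unknown binarization scheme {scheme!r}")
    return BinarizedPattern(labels=labels, scheme=scheme, threshold=float(thr))


def expansion(pattern: BinarizedPattern | np.ndarray) -> int:
    """Length of the contiguous run of high cells containing the center.

    Zero when the central cell itself is low.
    """
    labels = pattern.labels if isinstance(pattern, BinarizedPattern) else np.asarray(pattern)
    return int(_expansion_bool(labels.astype(bool)[None, :])[0])


def _expansion_bool(labels: np.ndarray) -> np.ndarray:
    """Vectorized expansion for boolean arrays of shape (..., n_cells)."""
    n = labels.shape[-1]
    c = n // 2
    left = np.cumprod(labels[..., c::-1], axis=-1).sum(axis=-1)
    right = np.cumprod(labels[..., c:], axis=-1).sum(axis=-1)
    return left + right - labels[..., c]


def count_switches(pattern: BinarizedPattern | np.ndarray) -> int:
    """Number of adjacent pairs, read left to right, going high -> low."""
    labels = pattern.labels if isinstance(pattern, BinarizedPattern) else np.asarray(pattern)
    labels = labels.astype(bool)
    return int(np.sum(labels[:-1] & ~labels[1:]))


def _switches_bool(labels: np.ndarray) -> np.ndarray:
    return np.sum(labels[..., :-1] & ~labels[..., 1:], axis=-1)


def _adaptive_bool(values: np.ndarray) -> np.ndarray:
    """Vectorized adaptive binarization over the trailing cell axis."""
    lo = values.min(axis=-1, keepdims=True)
    hi = values.max(axis=-1, keepdims=True)
    mid = 0.5 * (lo + hi)
    return (values >= mid) & (hi - lo >= CONTRAST_FLOOR)


# ---------------------------------------------------------------------------
# Equilibrium detection
# ---------------------------------------------------------------------------

def _drift_ok(prev_mean: np.ndarray, cur_mean: np.ndarray,
              cur_std: np.ndarray) -> np.ndarray:
    """Windowed per-cell mean drift below a noise-aware tolerance.

    Each cell's tolerance scales with its own within-window standard
    deviation: cells resting on the steep shoulder of the sigmoid have
    large stationary fluctuations that are not drift.  Relative and
    absolute floors cover quiet cells.
    """
    delta = np.abs(cur_mean - prev_mean)
    tol = np.maximum(DRIFT_STD_FACTOR * cur_std,
                     np.maximum(DRIFT_TOL * np.abs(prev_mean), DRIFT_ABS))
    flat = delta <= tol
    if flat.ndim > 2:
        return flat.all(axis=(-2, -1))
    return bool(flat.all())


def at_equilibrium(trace: TissueTrace | np.ndarray,
                   window: int = EQUILIBRIUM_WINDOW) -> tuple[bool, int | None]:
    """Whether the trace has settled by its final step.

    True iff over the last ``window`` steps (i) the absolute-threshold
    patterns of both genes are unchanged, (ii) each cell's windowed mean
    drifted less than the tolerance relative to the preceding window, and
    (iii) the adaptive patterns of the two windows' mean profiles agree.
    Returns ``(flag, step)`` with the final step index when settled.
    """
    concs = trace.concentrations if isinstance(trace, TissueTrace) else np.asarray(trace)
    if len(concs) < 2 * window + 1:
        return False, None
    pats = concs[-(window + 1):] >= ABSOLUTE_THRESHOLD
    if not (pats == pats[0]).all():
        return False, None
    cur = concs[-window:].mean(axis=0)
    prev = concs[-2 * window:-window].mean(axis=0)
    if not _drift_ok(prev, cur, concs[-window:].std(axis=0)):
        return False, None
    if not (_adaptive_bool(cur) == _adaptive_bool(prev)).all():
        return False, None
    return True, len(concs) - 1


def equilibrium_stop_check(window: int = EQUILIBRIUM_WINDOW):
    """A ``stop_check`` callback for :func:`simulate_tissue`."""
    def check(concs: np.ndarray, step: int) -> bool:
        return at_equilibrium(concs, window)[0]
    return check


# ---------------------------------------------------------------------------
# Run- and circuit-level classification
# ---------------------------------------------------------------------------

def expansion_series(trace: TissueTrace | np.ndarray, gene: int) -> np.ndarray:
    """Expansion of one gene (absolute scheme) at every recorded step."""
    concs = trace.concentrations if isinstance(trace, TissueTrace) else np.asarray(trace)
    return _expansion_bool(concs[:, gene, :] >= ABSOLUTE_THRESHOLD)


def _count_increases(series: np.ndarray, min_gap: int = MIN_INCREASE_GAP) -> int:
    """Count steps where the series strictly exceeds its prior running max.

    Increases closer than ``min_gap`` steps to the previously counted one
    are not counted, so a near-simultaneous tissue-wide threshold crossing
    does not masquerade as a propagating wave.
    """
    if len(series) < 2:
        return 0
    runmax = np.maximum.accumulate(series)
    grew = np.flatnonzero(series[1:] > runmax[:-1]) + 1
    count, last = 0, -min_gap - 1
    for t in grew:
        if t - last >= min_gap:
            count += 1
            last = t
    return count


def classify_run(trace: TissueTrace | np.ndarray,
                 config: SimulationConfig | None = None,
                 min_switches: int = DEFAULT_MIN_SWITCHES) -> PatternCall:
    """Score one simulation as induction, inhibition or none.

    Both genes are evaluated; any gene qualifying suffices.  When the two
    genes qualify for different functions, inhibition takes precedence: a
    settled alternating pattern is the stronger evidence, while a uniform
    high field is exactly the end state the dynamical induction rule
    guards against.  End-state measures are taken on the mean profile of
    the final equilibrium window to suppress noise.
    """
    concs = trace.concentrations if isinstance(trace, TissueTrace) else np.asarray(trace)
    n_cells = concs.shape[-1]
    eq, eq_step = at_equilibrium(concs)
    w = min(EQUILIBRIUM_WINDOW, len(concs))
    final_mean = concs[-w:].mean(axis=0)
    diag = {"equilibrium": eq, "equilibrium_step": eq_step, "per_gene": {}}
    verdicts: dict[int, str] = {}
    for gene in (0, 1):
        series = _expansion_bool(concs[:, gene, :] >= ABSOLUTE_THRESHOLD)
        increases = _count_increases(series)
        final_exp = expansion(final_mean[gene] >= ABSOLUTE_THRESHOLD)
        switches = count_switches(_adaptive_bool(final_mean[gene][None, :])[0])
        diag["per_gene"][gene] = {"expansion_final": final_exp,
                                  "expansion_increases": increases,
                                  "switches": switches,
                                  "expansion_series_max": int(series.max())}
        if eq and final_exp == n_cells and increases >= MIN_EXPANSION_INCREASES:
            verdicts[gene] = VERDICT_INDUCTION
        elif eq and switches >= min_switches:
            verdicts[gene] = VERDICT_INHIBITION
    for wanted in (VERDICT_INHIBITION, VERDICT_INDUCTION):
        for gene, v in verdicts.items():
            if v == wanted:
                return PatternCall(verdict=wanted, gene=gene, diagnostics=diag)
    return PatternCall(verdict=VERDICT_NONE, gene=None, diagnostics=diag)


def classify_circuit(circuit: Circuit, config: SimulationConfig,
                     n_runs: int = N_NOISE_RUNS,
                     min_switches: int = DEFAULT_MIN_SWITCHES) -> PatternCall:
    """Circuit-level verdict over several independent noise runs.

    Each run uses a seed derived from ``config.seed``.  A non-none verdict
    is emitted only when every run reaches equilibrium and all runs agree.
    """
    seeds = derive_seeds(config.seed, n_runs)
    calls = []
    for s in seeds:
        cfg = config.replace(seed=int(s))
        trace = simulate_tissue(circuit, cfg,
                                stop_check=equilibrium_stop_check(),
                                check_every=EQUILIBRIUM_WINDOW // 2)
        calls.append(classify_run(trace, cfg, min_switches=min_switches))
    verdicts = {c.verdict for c in calls}
    diag = {"per_run": [c.verdict for c in calls],
            "per_run_diagnostics": [c.diagnostics for c in calls]}
    if len(verdicts) == 1 and VERDICT_NONE not in verdicts:
        rep = calls[0]
        return PatternCall(verdict=rep.verdict, gene=rep.gene, diagnostics=diag)
    return PatternCall(verdict=VERDICT_NONE, gene=None, diagnostics=diag)


# ---------------------------------------------------------------------------
# Vectorized streaming classifier (screening backend)
# ---------------------------------------------------------------------------

def classify_rows(bp: BatchParams, config: SimulationConfig,
                  noise_keys: np.ndarray,
                  min_switches: int = DEFAULT_MIN_SWITCHES) -> dict:
    """Classify every row of a parameter batch in one vectorized sweep.

    Matches :func:`simulate_tissue` + :func:`classify_run` per row with
    ``seed = noise_keys[row]`` (same noise stream), but streams: no trace is
    stored, equilibrium is checked on window boundaries, and rows that
    settle are retired from the computation.  Returns arrays:
    ``verdict_code`` (0 none / 1 induction / 2 inhibition), ``gene``,
    ``eq_step``, ``expansion_final``, ``increases``, ``switches``.
    """
    B = bp.size
    n = config.n_cells
    W = EQUILIBRIUM_WINDOW
    state = batch_initial_state(bp, config)
    noisy = config.noise_amplitude > 0

    active = np.arange(B)
    pats_prev = state >= ABSOLUTE_THRESHOLD
    last_change = np.zeros(B, dtype=int)
    runmax = _expansion_bool(pats_prev)
    increases = np.zeros((B, 2), dtype=int)
    last_inc = np.full((B, 2), -MIN_INCREASE_GAP - 1, dtype=int)
    block_sum = np.zeros((B, 2, n))
    block_sq = np.zeros((B, 2, n))
    prev_mean = None
    eq_step = np.full(B, -1, dtype=int)
    final_exp = np.zeros((B, 2), dtype=int)
    final_sw = np.zeros((B, 2), dtype=int)

    cur = bp
    keys = np.asarray(noise_keys)
    ext = bp.external_input(config)
    for t in range(1, config.max_steps + 1):
        nf = noise_factors(keys, t, n, config.noise_amplitude) if noisy else None
        state = batch_step(state, cur, config, ext, nf)

        pats = state >= ABSOLUTE_THRESHOLD
        changed = (pats != pats_prev).any(axis=(1, 2))
        last_change[active[changed]] = t
        pats_prev = pats

        exp = _expansion_bool(pats)
        grew = (exp > runmax) & (t - last_inc >= MIN_INCREASE_GAP)
        increases[active] += grew
        last_inc[grew] = t
        runmax = np.maximum(runmax, exp)

        block_sum += state
        block_sq += state * state
        if t % W == 0:
            cur_mean = block_sum / W
            cur_std = np.sqrt(np.maximum(block_sq / W - cur_mean ** 2, 0.0))
            block_sum = np.zeros_like(block_sum)
            block_sq = np.zeros_like(block_sq)
            if prev_mean is not None:
                ada_cur = _adaptive_bool(cur_mean)
                quiet = _drift_ok(prev_mean, cur_mean, cur_std) \
                    & (ada_cur == _adaptive_bool(prev_mean)).all(axis=(1, 2)) \
                    & (t - last_change[active] >= W)
                if quiet.any():
                    rows = active[quiet]
                    eq_step[rows] = t
                    final_exp[rows] = _expansion_bool(
                        cur_mean[quiet] >= ABSOLUTE_THRESHOLD)
                    final_sw[rows] = _switches_bool(ada_cur[quiet])
                    keep = ~quiet
                    active = active[keep]
                    if len(active) == 0:
                        break
                    state = state[keep]
                    pats_prev = pats_prev[keep]
                    runmax = runmax[keep]
                    last_inc = last_inc[keep]
                    block_sum = block_sum[keep]
                    block_sq = block_sq[keep]
                    cur_mean = cur_mean[keep]
                    ext = ext[keep]
                    keys = keys[keep]
                    cur = BatchParams(cur.intra_w[keep], cur.inter_w[keep],
                                      cur.alpha[keep], cur.beta[keep],
                                      cur.trigger_gene[keep], cur.context_gene[keep],
                                      cur.context_value[keep], cur.signaling)
            prev_mean = cur_mean

    eq = eq_step >= 0
    induction = eq[:, None] & (final_exp == n) & (increases >= MIN_EXPANSION_INCREASES)
    inhibition = eq[:, None] & (final_sw >= min_switches)
    code = np.zeros(B, dtype=int)
    gene = np.full(B, -1, dtype=int)
    for g in (1, 0):  # lower gene index wins ties; inhibition beats induction
        sel = induction[:, g]
        code[sel], gene[sel] = 1, g
    for g in (1, 0):
        sel = inhibition[:, g]
        code[sel], gene[sel] = 2, g
    return {"verdict_code": code, "gene": gene, "eq_step": eq_step,
            "expansion_final": final_exp, "increases": increases,
            "switches": final_sw}


def verdict_name(code: int) -> str:
    return _CODE[int(code)]
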