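"""Phase-space analysis of the reduced two-cell model.

The four-variable system (D_c1, A_c1, D_c2, A_c2) couples two cells through
their signaling genes.  Steady states are found by dense multi-start Newton
refinement, their stability read off the Jacobian eigenvalues; instantaneous
phase portraits freeze the two A concentrations at trajectory values and
analyze the two-variable D-subsystem whose nullclines and attractors explain
how lateral induction (bifurcation-driven attractor switching, or pursuit of
a moving attractor) and lateral inhibition (antagonistic bi-stability across
the diagonal) are implemented.  Bifurcation sweeps over the trigger or
context input track branches by nearest-neighbor continuation and classify
events heuristically from branch topology: saddle-node (a stable state and a
saddle annihilate), pitchfork (symmetric off-diagonal branch pair created or
destroyed around a diagonal state that changes stability), or other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .circuit_model import Circuit, SimulationConfig, TissueTrace, \
    noise_factors, step, two_cell_rhs
from .pattern_scoring import (ABSOLUTE_THRESHOLD, _adaptive_bool, count_switches,
                              expansion)

RESIDUAL_TOL = 1e-8
DEDUP_TOL = 1e-4
STABILITY_TOL = 1e-6
STATE_MAX = 20.0  # 1/decay: the maximal steady expression level


@dataclass
class SteadyState:
    """A fixed point of the (full or frozen) two-cell system."""

    state: np.ndarray
    stability: str                 # "stable" | "saddle" | "unstable"
    eigenvalues: np.ndarray
    residual: float
    role: str | None = None

    @property
    def D(self) -> np.ndarray:
        """The (D_c1, D_c2) coordinates (full 4-variable states only)."""
        return self.state[[0, 2]] if len(self.state) == 4 else self.state


@dataclass
class NullclineSet:
    """Zero-level curves of the frozen D-subsystem."""

    curves_d1: list[np.ndarray]    # polylines (k, 2) in (D_c1, D_c2) coords
    curves_d2: list[np.ndarray]
    crossings: list[SteadyState]
    frozen_A: tuple[float, float]


@dataclass
class BifurcationDiagram:
    parameter: str
    grid: np.ndarray
    states: list[list[SteadyState]]
    events: list[dict]

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(s.stability == "stable" for s in sl)
                         for sl in self.states])


@dataclass
class PursuitReport:
    verdict: str                   # "pursuit" | "attractor_switching" | "neither"
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Multi-start Newton root finding (batched)
# ---------------------------------------------------------------------------

def _newton_roots(rhs, starts: np.ndarray, n_iter: int = 60,
                  fd_h: float = 1e-7) -> np.ndarray:
    """Vectorized Newton with backtracking; returns converged points.

    The per-row backtracking line search matters here: fixed points sitting
    on the steep shoulder of the sigmoid have tiny undamped-Newton basins.
    """
    y = np.array(starts, dtype=float)
    dim = y.shape[1]
    eye = np.eye(dim)
    done = np.empty((0, dim))
    f = rhs(y)
    for _ in range(n_iter):
        res = np.abs(f).max(axis=1)
        conv = res < RESIDUAL_TOL / 10
        if conv.any():
            done = np.vstack([done, y[conv]])
            y, f, res = y[~conv], f[~conv], res[~conv]
            if len(y) == 0:
                break
        # forward-difference Jacobian, batched over starts
        J = np.empty(y.shape[:1] + (dim, dim))
        for j in range(dim):
            J[:, :, j] = (rhs(y + fd_h * eye[j]) - f) / fd_h
        try:
            delta = np.linalg.solve(J, f[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(J + 1e-12 * eye, f[..., None])[..., 0]
        delta[~np.isfinite(delta).all(axis=1)] = 0.0
        delta = np.clip(delta, -8.0, 8.0)
        s = np.ones(len(y))
        trial = np.clip(y - delta, -1.0, 2.5 * STATE_MAX)
        f_tr = rhs(trial)
        for _bt in range(6):
            worse = np.abs(f_tr).max(axis=1) > res
            if not worse.any():
                break
            s[worse] *= 0.5
            trial = np.clip(y - s[:, None] * delta, -1.0, 2.5 * STATE_MAX)
            f_tr = rhs(trial)
        y, f = trial, f_tr
    if len(y):
        res = np.abs(rhs(y)).max(axis=1)
        ok = np.isfinite(res) & (res < RESIDUAL_TOL)
        done = np.vstack([done, y[ok]])
    keep = done.min(axis=1) > -DEDUP_TOL if len(done) else np.zeros(0, bool)
    return np.clip(done[keep], 0.0, None)


#: Extra low-concentration grid values: thresholds of the sigmoid often sit
#: at concentrations of order 1, between the points of a coarse uniform grid.
_LOW_AXIS = np.array([0.4, 0.9, 1.5, 2.5, 4.0])

#: Segment fractions for the enrichment round, dense near the end points:
#: saddles between two attractors lie on or near the connecting segment,
#: often close to one end.
_SEG_FRACS = np.concatenate([np.linspace(0.02, 0.2, 7), [0.35, 0.5, 0.65],
                             np.linspace(0.8, 0.98, 7)])


def _start_axis(grid_points: int) -> np.ndarray:
    return np.unique(np.concatenate([np.linspace(0.0, STATE_MAX, grid_points),
                                     _LOW_AXIS]))


def _find_all_roots(rhs, dim: int, grid_points: int,
                    extra_starts: np.ndarray | None = None) -> np.ndarray:
    """Grid multi-start Newton plus one between-roots enrichment round."""
    axis = _start_axis(grid_points)
    starts = np.stack(np.meshgrid(*([axis] * dim), indexing="ij"),
                      axis=-1).reshape(-1, dim)
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([starts, np.asarray(extra_starts, float)])
    pts = _dedup(_newton_roots(rhs, starts))
    if len(pts) > 1:
        segs = []
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                a, b = pts[i], pts[j]
                segs.append(a[None, :] + _SEG_FRACS[:, None] * (b - a)[None, :])
        extra = np.vstack(segs)
        pts = _dedup(np.vstack([pts, _newton_roots(rhs, extra)]))
    return pts


def _dedup(points: np.ndarray, tol: float = DEDUP_TOL) -> np.ndarray:
    out: list[np.ndarray] = []
    for p in points:
        if not any(np.abs(p - q).max() < tol for q in out):
            out.append(p)
    return np.array(out) if out else np.empty((0, points.shape[1] if points.size else 4))


def _jacobian(rhs, y: np.ndarray, h: float = 1e-6) -> np.ndarray:
    dim = len(y)
    J = np.empty((dim, dim))
    for j in range(dim):
        e = np.zeros(dim)
        e[j] = h
        J[:, j] = (rhs(y + e) - rhs(y - e)) / (2 * h)
    return J


def _label_stability(eig: np.ndarray) -> str:
    re = eig.real
    if re.max() < -STABILITY_TOL:
        return "stable"
    if re.min() > STABILITY_TOL:
        return "unstable"
    return "saddle"


def _states_from_points(rhs, points: np.ndarray) -> list[SteadyState]:
    out = []
    for p in points:
        J = _jacobian(rhs, p)
        eig = np.linalg.eigvals(J)
        out.append(SteadyState(state=p, stability=_label_stability(eig),
                               eigenvalues=eig,
                               residual=float(np.abs(rhs(p)).max())))
    return sorted(out, key=lambda s: tuple(np.round(s.state, 6)))


def find_steady_states(circuit: Circuit, T: float, C: float,
                       trigger_gene: int = 0, context_gene: int = 0,
                       grid_points: int = 8,
                       extra_starts: np.ndarray | None = None) -> list[SteadyState]:
    """All fixed points of the noise-free four-variable two-cell model.

    Dense multi-start Newton refinement on a grid over ``[0, 1/decay]^4``
    (plus optional warm starts), deduplicated within ``DEDUP_TOL`` in the
    max norm; stability is labeled from the Jacobian eigenvalues
    (stable iff every real part < -1e-6).  Starts that fail to converge
    are dropped.
    """
    rhs = two_cell_rhs(circuit, T, C, trigger_gene, context_gene)
    pts = _find_all_roots(rhs, 4, grid_points, extra_starts)
    return _states_from_points(rhs, pts)


def frozen_d_rhs(circuit: Circuit, frozen_A: tuple[float, float], T: float,
                 C: float, trigger_gene: int = 0, context_gene: int = 0):
    """RHS of the 2-variable D-subsystem with both A concentrations frozen."""
    rhs4 = two_cell_rhs(circuit, T, C, trigger_gene, context_gene)
    a1, a2 = frozen_A

    def rhs(d):
        d = np.asarray(d, dtype=float)
        y = np.empty(d.shape[:-1] + (4,))
        y[..., 0] = d[..., 0]
        y[..., 1] = a1
        y[..., 2] = d[..., 1]
        y[..., 3] = a2
        f = rhs4(y)
        return f[..., [0, 2]]

    return rhs


def find_frozen_attractors(circuit: Circuit, frozen_A, T: float, C: float,
                           trigger_gene: int = 0, context_gene: int = 0,
                           grid_points: int = 14) -> list[SteadyState]:
    """Fixed points of the frozen D-subsystem (stability in that subsystem)."""
    rhs = frozen_d_rhs(circuit, frozen_A, T, C, trigger_gene, context_gene)
    pts = _find_all_roots(rhs, 2, grid_points)
    return _states_from_points(rhs, pts)


# ---------------------------------------------------------------------------
# Nullclines
# ---------------------------------------------------------------------------

def nullclines_2cell(circuit: Circuit, frozen_A, T: float, C: float,
                     grid: np.ndarray | None = None,
                     trigger_gene: int = 0, context_gene: int = 0) -> NullclineSet:
    """Zero contours of the two D-equations at frozen A values.

    Curves are extracted by marching squares on a dense grid; crossings are
    the frozen-subsystem fixed points.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.1 * STATE_MAX, 221)
    rhs = frozen_d_rhs(circuit, frozen_A, T, C, trigger_gene, context_gene)
    D1, D2 = np.meshgrid(grid, grid, indexing="ij")
    F = rhs(np.stack([D1, D2], axis=-1))

    def contours(values):
        polys = []
        for seg in measure.find_contours(values, 0.0):
            # index coordinates -> data coordinates
            idx = np.clip(seg, 0, len(grid) - 1)
            polys.append(np.stack([np.interp(idx[:, 0], np.arange(len(grid)), grid),
                                   np.interp(idx[:, 1], np.arange(len(grid)), grid)],
                                  axis=1))
        return polys

    crossings = find_frozen_attractors(circuit, frozen_A, T, C,
                                       trigger_gene, context_gene)
    return NullclineSet(curves_d1=contours(F[..., 0]),
                        curves_d2=contours(F[..., 1]),
                        crossings=crossings, frozen_A=tuple(frozen_A))


def turning_points(curve: np.ndarray, axis: int = 1) -> int:
    """Number of sign changes of the running slope along one coordinate.

    Used to characterize nullcline shape (an S has one turning point along
    its dependent coordinate, a cap-shape two).
    """
    v = np.diff(curve[:, axis])
    v = v[np.abs(v) > 1e-9]
    if len(v) < 2:
        return 0
    return int(np.sum(np.sign(v[1:]) != np.sign(v[:-1])))


# ---------------------------------------------------------------------------
# Bifurcation sweeps
# ---------------------------------------------------------------------------

def _is_swap_pair(a: np.ndarray, b: np.ndarray, tol: float = 1e-2) -> bool:
    """Whether two 4-states are exchange images (D/A swapped between cells)."""
    return bool(np.abs(a - b[[2, 3, 0, 1]]).max() < tol)


def _near_diagonal(s: np.ndarray, tol: float = 1e-2) -> bool:
    return bool(np.abs(s[[0, 1]] - s[[2, 3]]).max() < tol)


def sweep_bifurcations(circuit: Circuit, parameter: str, grid,
                       fixed_inputs: dict | None = None,
                       trigger_gene: int = 0, context_gene: int = 0,
                       grid_points: int = 6) -> BifurcationDiagram:
    """Track steady-state branches over a trigger or context sweep.

    ``parameter`` is ``"C"`` or ``"T"``; ``fixed_inputs`` supplies the other
    input's value (default 0).  Branches are continued by warm-starting each
    grid value with the previous fixed points; events between consecutive
    values are classified from the change in branch structure:

    * ``saddle-node`` -- a stable state and a saddle annihilate (or appear)
      as a close pair;
    * ``pitchfork`` -- an exchange-symmetric off-diagonal pair appears or
      disappears while a near-diagonal state flips stability (the
      subcritical case: two unstable branches collapse onto a stable
      diagonal state which destabilizes);
    * ``other`` -- anything the heuristics cannot identify (ambiguity is
      flagged, not guessed).
    """
    fixed = {"T": 0.0, "C": 0.0} | (fixed_inputs or {})
    grid = np.asarray(grid, dtype=float)
    if not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("sweep grid must be monotone")
    states: list[list[SteadyState]] = []
    prev_pts: np.ndarray | None = None
    for v in grid:
        T = v if parameter == "T" else fixed["T"]
        C = v if parameter == "C" else fixed["C"]
        sl = find_steady_states(circuit, T, C, trigger_gene, context_gene,
                                grid_points=grid_points, extra_starts=prev_pts)
        states.append(sl)
        prev_pts = np.array([s.state for s in sl]) if sl else None

    events = []
    for i in range(1, len(grid)):
        a, b = states[i - 1], states[i]
        ev = _classify_event(a, b)
        if ev is not None:
            ev["between"] = (float(grid[i - 1]), float(grid[i]))
            events.append(ev)
    return BifurcationDiagram(parameter=parameter, grid=grid, states=states,
                              events=events)


def _match_states(a: list[SteadyState], b: list[SteadyState],
                  tol: float = 2.0):
    """Greedy nearest-neighbor matching; returns (pairs, lost, gained)."""
    used = set()
    pairs = []
    for ia, sa in enumerate(a):
        best, bd = None, tol
        for ib, sb in enumerate(b):
            if ib in used:
                continue
            d = np.abs(sa.state - sb.state).max()
            if d < bd:
                best, bd = ib, d
        if best is not None:
            used.add(best)
            pairs.append((ia, best))
    lost = [ia for ia in range(len(a)) if ia not in {p[0] for p in pairs}]
    gained = [ib for ib in range(len(b)) if ib not in used]
    return pairs, lost, gained


def _proximity_pairs(states: list[SteadyState]) -> list[tuple]:
    """Greedy pairing of states by mutual distance (closest pairs first)."""
    idx = list(range(len(states)))
    dists = sorted(((np.abs(states[i].state - states[j].state).max(), i, j)
                    for i in idx for j in idx if i < j))
    used, pairs = set(), []
    for d, i, j in dists:
        if i not in used and j not in used:
            pairs.append((states[i], states[j], d))
            used.update((i, j))
    return pairs


def _swap_symmetric_pairs(states: list[SteadyState], tol: float = 1.0):
    """Distinct exchange-symmetric pairs of equal stability, with centroids."""
    out = []
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            si, sj = states[i].state, states[j].state
            if states[i].stability != states[j].stability:
                continue
            if np.abs(si - sj).max() < 10 * DEDUP_TOL:
                continue
            if _is_swap_pair(si, sj, tol):
                out.append((i, j, 0.5 * (si + sj)))
    return out


def _nearest_diagonal_state(states: list[SteadyState], centroid: np.ndarray,
                            exclude: tuple = (), radius: float = 6.0):
    """Closest near-diagonal state to a centroid, or None."""
    best, bd = None, radius
    for k, s in enumerate(states):
        if k in exclude or not _near_diagonal(s.state, tol=2.0):
            continue
        d = np.abs(s.state - centroid).max()
        if d < bd:
            best, bd = s, d
    return best


def _pitchfork_event(a: list[SteadyState], b: list[SteadyState],
                     detail: dict) -> dict | None:
    pairs_a = _swap_symmetric_pairs(a)
    pairs_b = _swap_symmetric_pairs(b)
    for pairs, side, other, other_pairs in ((pairs_a, a, b, pairs_b),
                                            (pairs_b, b, a, pairs_a)):
        for i, j, centroid in pairs:
            if any(np.abs(c2 - centroid).max() < 3.0 for _, _, c2 in other_pairs):
                continue  # pair persists on both sides: no event here
            s_here = _nearest_diagonal_state(side, centroid, exclude=(i, j))
            s_there = _nearest_diagonal_state(other, centroid)
            if s_here is None or s_there is None:
                continue
            if (s_here.stability == "stable") != (s_there.stability == "stable"):
                sub = side[i].stability != "stable"
                return {"type": "pitchfork",
                        "subtype": "subcritical" if sub else "supercritical",
                        "detail": detail}
    return None


def _classify_event(a: list[SteadyState], b: list[SteadyState]) -> dict | None:
    pairs, lost, gained = _match_states(a, b)
    delta = len(b) - len(a)
    changed = [(ia, ib) for ia, ib in pairs
               if a[ia].stability != b[ib].stability]
    if delta == 0 and not changed:
        return None

    def _describe(idxs, sl):
        return [{"state": sl[i].state.tolist(), "stability": sl[i].stability}
                for i in idxs]

    detail = {"lost": _describe(lost, a), "gained": _describe(gained, b),
              "stability_changes": [
                  {"from": a[ia].stability, "to": b[ib].stability,
                   "state": b[ib].state.tolist()} for ia, ib in changed]}

    # pitchfork: an exchange-symmetric pair of equal stability exists on one
    # side only, and the near-diagonal state at its centroid has the
    # opposite stability on the other side.  This is configuration-based
    # (not matching-based) because near the bifurcation the three colliding
    # states sit within the matching tolerance of each other.
    ev = _pitchfork_event(a, b, detail)
    if ev is not None:
        return ev
    # saddle-node: the disappearing (or appearing) states decompose into
    # close pairs, at least one of which joins a stable state and a saddle
    # (simultaneous folds on replicated branches give several such pairs)
    for idxs, side in ((lost, a), (gained, b)):
        if len(idxs) >= 2 and len(idxs) % 2 == 0:
            prs = _proximity_pairs([side[i] for i in idxs])
            if any({p[0].stability, p[1].stability} == {"stable", "saddle"}
                   for p in prs):
                return {"type": "saddle-node", "detail": detail}
    return {"type": "other", "detail": detail}


# ---------------------------------------------------------------------------
# Instantaneous attractors and pursuit
# ---------------------------------------------------------------------------

def instantaneous_attractors(circuit: Circuit, trajectory: np.ndarray,
                             sample_times, T: float, C: float,
                             trigger_gene: int = 0, context_gene: int = 0,
                             match_tol: float = 6.0) -> dict:
    """Attractor track of the frozen D-subsystem along a trajectory.

    At each sampled time the A concentrations are frozen at their
    trajectory values and the attractors (stable fixed points) of the
    two-variable D-subsystem are computed; attractor identities are aligned
    across times by nearest-neighbor matching.  Returns ``times``,
    ``attractors`` (list of (k, 2) arrays), ``counts``, and ``tracks``
    mapping identity -> {"times": [...], "positions": (m, 2) array}.
    """
    sample_times = np.asarray(sample_times, dtype=int)
    all_attr = []
    for t in sample_times:
        y = trajectory[t]
        att = [s.state for s in find_frozen_attractors(
            circuit, (y[1], y[3]), T, C, trigger_gene, context_gene)
            if s.stability == "stable"]
        all_attr.append(np.array(att) if att else np.empty((0, 2)))

    tracks: dict[int, dict] = {}
    next_id = 0
    prev_ids: list[int] = []
    prev_pos = np.empty((0, 2))
    for t, att in zip(sample_times, all_attr):
        ids = [-1] * len(att)
        used = set()
        for i, p in enumerate(att):
            if len(prev_pos):
                d = np.abs(prev_pos - p).max(axis=1)
                order = np.argsort(d)
                for j in order:
                    if d[j] < match_tol and prev_ids[j] not in used:
                        ids[i] = prev_ids[j]
                        used.add(prev_ids[j])
                        break
            if ids[i] < 0:
                ids[i] = next_id
                next_id += 1
            tr = tracks.setdefault(ids[i], {"times": [], "positions": []})
            tr["times"].append(int(t))
            tr["positions"].append(p)
        prev_ids, prev_pos = ids, att
    for tr in tracks.values():
        tr["positions"] = np.array(tr["positions"])
    return {"times": sample_times,
            "attractors": all_attr,
            "counts": np.array([len(a) for a in all_attr]),
            "tracks": tracks}


def detect_pursuit(trajectory: np.ndarray, track: dict,
                   displacement_min: float = 2.0,
                   distance_min: float = 1.0) -> PursuitReport:
    """Classify induction dynamics as pursuit, attractor switching or neither.

    The discriminator is *residence*.  In attractor switching the system
    initially rests on an attractor (the state starts within
    ``distance_min`` of one) which is later destroyed -- the instantaneous
    attractor count drops -- and the state jumps to another.  In pursuit
    the state is never at rest: it starts away from any attractor and
    chases a target (the nearest attractor at each sample) whose cumulative
    displacement exceeds ``displacement_min`` while the state trails it by
    at least ``distance_min`` over a sustained interval, finally catching
    it.  A trajectory that barely moves is ``neither``.  The target's
    displacement is measured positionally (nearest attractor per sample)
    because with steep regulation a pursued attractor can traverse most of
    the concentration range between two samples.
    """
    times = np.asarray(track["times"])
    counts = np.asarray(track["counts"])
    d_traj = trajectory[:, [0, 2]]
    total_move = float(np.abs(d_traj[times[-1]] - d_traj[times[0]]).max())
    diag = {"total_state_displacement": total_move,
            "attractor_counts": counts.tolist()}
    if total_move < distance_min:
        return PursuitReport("neither", diag)

    lag = np.full(len(times), np.inf)
    targets = np.full((len(times), 2), np.nan)
    for k, (t, att) in enumerate(zip(times, track["attractors"])):
        if len(att):
            d = np.abs(att - d_traj[t]).max(axis=1)
            j = int(np.argmin(d))
            lag[k] = d[j]
            targets[k] = att[j]
    valid = np.isfinite(targets[:, 0])
    tv = targets[valid]
    displacement = float(np.sum(np.abs(np.diff(tv, axis=0)).max(axis=1))) \
        if len(tv) > 1 else 0.0
    resident_start = bool(lag[0] < distance_min)
    annihilated = bool((np.diff(counts) < 0).any())
    sustained = int(np.sum(lag[np.isfinite(lag)] >= distance_min))
    converged = bool(np.isfinite(lag[-1]) and lag[-1] < distance_min)
    diag |= {"target_displacement": displacement,
             "max_lag": float(np.nanmax(np.where(np.isfinite(lag), lag, np.nan))),
             "sustained_lag_samples": sustained,
             "resident_at_start": resident_start,
             "count_decrease": annihilated,
             "converged": converged}

    if resident_start and annihilated:
        return PursuitReport("attractor_switching", diag)
    if (not resident_start and converged and sustained >= 2
            and displacement >= displacement_min):
        return PursuitReport("pursuit", diag)
    return PursuitReport("neither", diag)


# ---------------------------------------------------------------------------
# Time-dependent context ramp
# ---------------------------------------------------------------------------

def context_ramp(circuit: Circuit, C_schedule, config: SimulationConfig,
                 step_increment: float = 0.01, steps_per_increment: int = 50):
    """Full-tissue simulation under a time-varying context signal.

    ``C_schedule`` maps step -> C value (callable or array); None builds the
    default staircase raising C by ``step_increment`` every
    ``steps_per_increment`` steps from 0 to 1.  Returns ``(trace, profile,
    transition)`` where ``profile`` lists per-plateau pattern metrics
    (expansion, switch count, amplitude = mean high - mean low under the
    adaptive scheme) and ``transition`` is ``"abrupt"`` when the amplitude
    jumps by more than half its overall range between adjacent plateaus,
    else ``"smooth"``.
    """
    if C_schedule is None:
        n_plateau = int(round(1.0 / step_increment)) + 1
        sched = np.repeat(np.arange(n_plateau) * step_increment,
                          steps_per_increment)
    elif callable(C_schedule):
        sched = np.array([C_schedule(t) for t in range(config.max_steps)])
    else:
        sched = np.asarray(C_schedule, dtype=float)
    n_steps = len(sched)
    concs = np.empty((n_steps + 1, 2, config.n_cells))
    concs[0] = config.initial_value
    state = concs[0].copy()
    noisy = config.noise_amplitude > 0
    for t in range(1, n_steps + 1):
        cfg = config.replace(context_value=float(sched[t - 1]),
                             max_steps=n_steps)
        nf = noise_factors(config.seed, t, config.n_cells,
                           config.noise_amplitude) if noisy else None
        state = step(state, circuit, cfg, noise=nf)
        concs[t] = state
    trace = TissueTrace(concentrations=concs, times=np.arange(n_steps + 1),
                        config=config.replace(max_steps=n_steps))

    # plateau boundaries: last step at each constant C value
    change = np.flatnonzero(np.diff(sched) != 0)
    ends = np.concatenate([change, [n_steps - 1]])
    profile = []
    for e in ends:
        t = e + 1
        w = min(20, t)
        mean_prof = concs[t - w + 1:t + 1].mean(axis=0)
        row = {"step": int(t), "C": float(sched[e])}
        for gene in (0, 1):
            prof = mean_prof[gene]
            ada = _adaptive_bool(prof[None, :])[0]
            amp = float(prof[ada].mean() - prof[~ada].mean()) if ada.any() else 0.0
            row[f"expansion_g{gene}"] = expansion(prof >= ABSOLUTE_THRESHOLD)
            row[f"switches_g{gene}"] = count_switches(ada)
            row[f"amplitude_g{gene}"] = amp
        profile.append(row)

    transition = "smooth"
    jumps = {}
    for gene in (0, 1):
        amps = np.array([r[f"amplitude_g{gene}"] for r in profile])
        rng_ = amps.max() - amps.min()
        if rng_ > 0:
            jmp = np.abs(np.diff(amps)).max()
            jumps[gene] = float(jmp / rng_)
            if jmp > 0.5 * rng_:
                transition = "abrupt"
    return trace, profile, {"transition": transition, "max_jump_fraction": jumps}
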