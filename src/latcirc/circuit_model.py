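"""Core model of two-gene paracrine signaling circuits.

A circuit couples two genes in every cell of a one-dimensional tissue.  One
gene, the *signaling* gene D, regulates targets in the two neighboring cells
(juxtacrine signaling, inspired by Notch-Delta); the other gene A acts only
cell-autonomously.  Gene products follow

    dg_ij/dt = phi_i(net input) - lambda * g_ij            (+ noise)

where ``phi_i(x) = 1 / (1 + exp(alpha_i - beta * x))`` is a steep sigmoid
whose offset ``alpha_i`` sets each gene's basal behavior (``alpha = -60`` is
constitutive expression, large positive values demand strong activation) and
``beta`` its steepness.  The net input of gene *i* in cell *j* sums weighted
intra-cellular regulation, weighted input from the signaling gene of both
neighbors, a trigger signal T delivered to one gene of the central cell, and
a context signal C delivered to one gene of every cell.

Integration is explicit Euler with ``dt = 1`` so that the per-step
multiplicative noise (uniform +/- 1%) has the stated discrete semantics.
Boundaries are reflective: each edge cell's missing neighbor is a mirror
ghost copy of the edge cell itself (a ``"zero"`` alternative, in which the
absent neighbor contributes nothing, is configurable).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.special import expit

SCHEMA_VERSION = 1

#: Names of the six regulatory links.  ``("intra", i, j)`` is regulation of
#: gene *i* by gene *j* within a cell; ``("inter", i)`` is regulation of gene
#: *i* by the signaling gene of each neighboring cell.
LINK_KEYS: tuple[tuple, ...] = (
    ("intra", 0, 0), ("intra", 0, 1), ("intra", 1, 0), ("intra", 1, 1),
    ("inter", 0), ("inter", 1),
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Topology:
    """Signed interaction structure of a two-gene circuit.

    Parameters
    ----------
    intra
        2x2 matrix of signs; ``intra[i][j]`` is the sign (-1, 0, +1) of the
        regulation of target gene ``i`` by gene ``j`` within the same cell.
    inter
        Length-2 vector of signs; ``inter[i]`` is the sign of the regulation
        of target gene ``i`` by the signaling gene of each neighboring cell.
    signaling
        Index (0 or 1) of the signaling gene D.  Gene ``1 - signaling`` is
        the cell-autonomous gene A.
    """

    intra: tuple[tuple[int, int], tuple[int, int]]
    inter: tuple[int, int]
    signaling: int = 0

    def __post_init__(self):
        intra = tuple(tuple(int(v) for v in row) for row in self.intra)
        inter = tuple(int(v) for v in self.inter)
        object.__setattr__(self, "intra", intra)
        object.__setattr__(self, "inter", inter)
        if len(intra) != 2 or any(len(r) != 2 for r in intra) or len(inter) != 2:
            raise ValueError("topology must have a 2x2 intra matrix and length-2 inter vector")
        entries = [v for row in intra for v in row] + list(inter)
        if any(v not in (-1, 0, 1) for v in entries):
            raise ValueError("topology entries must be -1, 0 or +1")
        if self.signaling not in (0, 1):
            raise ValueError("signaling gene index must be 0 or 1")

    # -- link bookkeeping ---------------------------------------------------

    def entry(self, key: tuple) -> int:
        if key[0] == "intra":
            return self.intra[key[1]][key[2]]
        return self.inter[key[1]]

    @property
    def links(self) -> tuple[tuple, ...]:
        """Keys of the nonzero entries."""
        return tuple(k for k in LINK_KEYS if self.entry(k) != 0)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def sign_map(self) -> dict[tuple, int]:
        return {k: self.entry(k) for k in self.links}

    # -- isometry -----------------------------------------------------------

    def mirror(self) -> "Topology":
        """The isometric topology with the two gene labels exchanged.

        The signaling-role designation travels with its gene, so the mirror
        of a topology with ``signaling == 0`` has ``signaling == 1``.
        """
        intra = self.intra
        return Topology(
            intra=((intra[1][1], intra[1][0]), (intra[0][1], intra[0][0])),
            inter=(self.inter[1], self.inter[0]),
            signaling=1 - self.signaling,
        )

    def canonical(self) -> "Topology":
        """Canonical representative: the labeling with D as gene 0.

        Each isometry class of labeled topologies has exactly two members,
        one per choice of which label carries the signaling role; the class
        is uniquely represented by the member with ``signaling == 0``.
        """
        return self if self.signaling == 0 else self.mirror()

    def encode(self) -> str:
        """Compact string id, e.g. ``'s0:+0-0/0+'``."""
        sym = {-1: "-", 0: "0", 1: "+"}
        flat = "".join(sym[v] for row in self.intra for v in row)
        inter = "".join(sym[v] for v in self.inter)
        return f"s{self.signaling}:{flat}/{inter}"

    @classmethod
    def decode(cls, text: str) -> "Topology":
        sym = {"-": -1, "0": 0, "+": 1}
        head, body = text.split(":")
        flat, inter = body.split("/")
        vals = [sym[c] for c in flat]
        return cls(
            intra=((vals[0], vals[1]), (vals[2], vals[3])),
            inter=(sym[inter[0]], sym[inter[1]]),
            signaling=int(head[1]),
        )

    def with_link(self, key: tuple, sign: int) -> "Topology":
        """A copy with one entry replaced."""
        intra = [list(r) for r in self.intra]
        inter = list(self.inter)
        if key[0] == "intra":
            intra[key[1]][key[2]] = sign
        else:
            inter[key[1]] = sign
        return Topology(tuple(tuple(r) for r in intra), tuple(inter), self.signaling)


@dataclass(frozen=True)
class ParameterSet:
    """Interaction strengths realizing a topology.

    ``intra_w`` and ``inter_w`` mirror the topology layout with real weights
    whose signs must match the topology signs (zero exactly where the
    topology entry is zero).  ``alpha`` holds the per-gene sigmoid offsets
    and ``beta`` the shared steepness.
    """

    intra_w: tuple[tuple[float, float], tuple[float, float]]
    inter_w: tuple[float, float]
    alpha: tuple[float, float]
    beta: float

    def __post_init__(self):
        object.__setattr__(self, "intra_w",
                           tuple(tuple(float(v) for v in row) for row in self.intra_w))
        object.__setattr__(self, "inter_w", tuple(float(v) for v in self.inter_w))
        object.__setattr__(self, "alpha", tuple(float(v) for v in self.alpha))
        object.__setattr__(self, "beta", float(self.beta))
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def weight(self, key: tuple) -> float:
        if key[0] == "intra":
            return self.intra_w[key[1]][key[2]]
        return self.inter_w[key[1]]

    def validate_against(self, topology: Topology) -> None:
        """Raise if any weight sign disagrees with the topology sign."""
        for key in LINK_KEYS:
            sign = topology.entry(key)
            w = self.weight(key)
            if sign == 0 and w != 0.0:
                raise ValueError(f"nonzero weight on absent link {key}")
            if sign != 0 and np.sign(w) != sign:
                raise ValueError(f"weight sign mismatch on link {key}: {w} vs {sign}")

    def mirror(self) -> "ParameterSet":
        w = self.intra_w
        return ParameterSet(
            intra_w=((w[1][1], w[1][0]), (w[0][1], w[0][0])),
            inter_w=(self.inter_w[1], self.inter_w[0]),
            alpha=(self.alpha[1], self.alpha[0]),
            beta=self.beta,
        )


@dataclass(frozen=True)
class Circuit:
    """A topology together with one parameter set realizing it."""

    topology: Topology
    params: ParameterSet

    def __post_init__(self):
        self.params.validate_against(self.topology)

    def mirror(self) -> "Circuit":
        return Circuit(self.topology.mirror(), self.params.mirror())

    @property
    def signaling(self) -> int:
        return self.topology.signaling


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one multicellular simulation.

    The tissue has an odd number of cells so a unique central cell exists;
    the trigger T is delivered to ``trigger_gene`` of that cell and the
    context C to ``context_gene`` of every cell.
    """

    n_cells: int = 33
    dt: float = 1.0
    max_steps: int = 5000
    decay: float = 0.05
    noise_amplitude: float = 0.01
    trigger_value: float = 1.0
    trigger_gene: int = 0
    context_value: float = 0.0
    context_gene: int = 0
    initial_value: float = 0.1
    boundary: str = "mirror"
    neighbor_mode: str = "sum"
    seed: int = 0

    def __post_init__(self):
        if self.n_cells % 2 != 1:
            raise ValueError("n_cells must be odd")
        if self.decay <= 0:
            raise ValueError("decay must be positive")
        if not 0.0 <= self.noise_amplitude <= 0.05:
            raise ValueError("noise_amplitude must lie in [0, 0.05]")
        if self.boundary not in ("mirror", "zero"):
            raise ValueError("boundary must be 'mirror' or 'zero'")

    @property
    def trigger_cell(self) -> int:
        return self.n_cells // 2

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TissueTrace:
    """Concentration history of a tissue simulation.

    ``concentrations`` has shape ``(n_steps + 1, 2, n_cells)`` (time x gene x
    cell); the first snapshot is the uniform initial condition.
    """

    concentrations: np.ndarray
    times: np.ndarray
    config: SimulationConfig

    @property
    def final(self) -> np.ndarray:
        return self.concentrations[-1]

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    def to_frame(self):
        """Long-format DataFrame with columns step, gene, cell, value."""
        import pandas as pd

        t, g, c = self.concentrations.shape
        steps, genes, cells = np.meshgrid(self.times, np.arange(g), np.arange(c),
                                          indexing="ij")
        return pd.DataFrame({
            "step": steps.ravel(), "gene": genes.ravel(),
            "cell": cells.ravel(), "value": self.concentrations.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_npz(self, path) -> None:
        np.savez_compressed(path, concentrations=self.concentrations,
                            times=self.times,
                            config=json.dumps(config_to_dict(self.config)))


@dataclass(frozen=True)
class TwoCellState:
    """State of the reduced two-cell model, ordered (D_c1, A_c1, D_c2, A_c2)."""

    D_c1: float
    A_c1: float
    D_c2: float
    A_c2: float

    def __post_init__(self):
        if min(self.D_c1, self.A_c1, self.D_c2, self.A_c2) < 0:
            raise ValueError("concentrations must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.D_c1, self.A_c1, self.D_c2, self.A_c2], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "TwoCellState":
        return cls(*(float(v) for v in arr))


# ---------------------------------------------------------------------------
# Regulation function and net input
# ---------------------------------------------------------------------------

def regulation_rate(x, alpha, beta):
    """Sigmoid production rate ``1 / (1 + exp(alpha - beta * x))``.

    Strictly increasing in ``x`` and bounded in (0, 1).  Computed via the
    logistic function for overflow safety.  Accepts arrays.
    """
    return expit(np.asarray(beta) * np.asarray(x) - np.asarray(alpha))


def _neighbor_sum(g_sig: np.ndarray, boundary: str,
                  neighbor_mode: str = "sum") -> np.ndarray:
    """Signaling-gene input contributed by the two neighbors.

    ``g_sig`` has shape ``(..., n_cells)``.  Under the mirror boundary each
    edge cell's missing neighbor is a ghost copy of the edge cell itself;
    under the zero boundary the missing neighbor contributes nothing.  With
    ``neighbor_mode="mean"`` the two neighbor concentrations are averaged
    instead of summed, which makes the interior-cell input scale match the
    reduced two-cell model (one neighbor at weight w).
    """
    out = np.empty_like(g_sig)
    out[..., 1:-1] = g_sig[..., :-2] + g_sig[..., 2:]
    if boundary == "mirror":
        out[..., 0] = g_sig[..., 0] + g_sig[..., 1]
        out[..., -1] = g_sig[..., -2] + g_sig[..., -1]
    else:
        out[..., 0] = g_sig[..., 1]
        out[..., -1] = g_sig[..., -2]
    if neighbor_mode == "mean":
        out = out * 0.5
    elif neighbor_mode != "sum":
        raise ValueError("neighbor_mode must be 'sum' or 'mean'")
    return out


def external_input(config: SimulationConfig) -> np.ndarray:
    """Constant external input array of shape (2, n_cells): trigger + context."""
    ext = np.zeros((2, config.n_cells))
    ext[config.trigger_gene, config.trigger_cell] += config.trigger_value
    ext[config.context_gene, :] += config.context_value
    return ext


def net_input(circuit: Circuit, state: np.ndarray, cell: int, gene: int,
              config: SimulationConfig) -> float:
    """Net regulatory input of one gene in one cell.

    Sums intra-cellular regulation, inter-cellular regulation from the
    signaling gene of both neighbors (with the configured boundary rule),
    plus T if this is the trigger gene in the trigger cell and C if this is
    the context gene.
    """
    n = config.n_cells
    if not 0 <= cell < n:
        raise IndexError(f"cell index {cell} out of range for {n} cells")
    state = np.asarray(state, dtype=float)
    intra = np.asarray(circuit.params.intra_w)
    x = float(intra[gene] @ state[:, cell])
    neigh = _neighbor_sum(state[circuit.signaling], config.boundary,
                          config.neighbor_mode)[cell]
    x += circuit.params.inter_w[gene] * neigh
    if gene == config.trigger_gene and cell == config.trigger_cell:
        x += config.trigger_value
    if gene == config.context_gene:
        x += config.context_value
    return x


# ---------------------------------------------------------------------------
# Counter-based noise stream
#
# The +/-1% developmental noise is drawn from a counter-based hash stream so
# that the value for (seed, step, gene, cell) is a pure function of those
# indices: a trace re-run under its recorded seed is identical bit for bit
# whether it is simulated alone or as one row of a vectorized screening
# batch, and enlarging a screen keeps every earlier sample's noise unchanged
# (nested-seed monotonicity).  The mixer is the murmur3/splitmix 64-bit
# finalizer, ample for a +/-1% perturbation.
# ---------------------------------------------------------------------------

_MIX1 = np.uint64(0xFF51AFD7ED558CCD)
_MIX2 = np.uint64(0xC4CEB9FE1A85EC53)
_SHIFT = np.uint64(33)


def _mix64(x) -> np.ndarray:
    """Murmur3 64-bit finalizer (vectorized avalanche hash)."""
    with np.errstate(over="ignore"):
        x = np.asarray(x).astype(np.uint64)
        x = x ^ (x >> _SHIFT)
        x = x * _MIX1
        x = x ^ (x >> _SHIFT)
        x = x * _MIX2
        x = x ^ (x >> _SHIFT)
    return x


def noise_factors(keys, step_index: int, n_cells: int, amplitude: float) -> np.ndarray:
    """Multiplicative noise factors ``1 + u``, ``u ~ Uniform(-a, a)``.

    ``keys`` is a scalar seed or an array of per-sample seeds; the result has
    shape ``keys.shape + (2, n_cells)`` and is a deterministic function of
    (key, step, gene, cell).
    """
    keys = np.asarray(keys)
    scalar = keys.ndim == 0
    mk = _mix64(keys).reshape(-1, 1)
    nv = 2 * n_cells
    with np.errstate(over="ignore"):
        ctr = np.uint64(step_index) * np.uint64(nv) + np.arange(nv, dtype=np.uint64)
        h = _mix64(mk ^ _mix64(ctr))
    u = (h >> np.uint64(11)) * (2.0 ** -53)  # [0, 1)
    fac = 1.0 + amplitude * (2.0 * u - 1.0)
    fac = fac.reshape(keys.shape + (2, n_cells)) if not scalar else fac.reshape(2, n_cells)
    return fac


def derive_seeds(seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Deterministic family of child seeds (uint64) from one master seed."""
    with np.errstate(over="ignore"):
        base = _mix64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF) ^ _mix64(np.uint64(stream)))
        return _mix64(base ^ (np.arange(1, n + 1, dtype=np.uint64) * _MIX2))


# ---------------------------------------------------------------------------
# Stepping and simulation
# ---------------------------------------------------------------------------

def _net_input_all(state, intra_w, inter_w, signaling, ext, boundary,
                   neighbor_mode="sum"):
    """Net inputs for every gene and cell; broadcasts over a leading batch axis.

    ``state``: (..., 2, n); ``intra_w``: (..., 2, 2); ``inter_w``: (..., 2).
    """
    x = np.einsum("...ij,...jn->...in", intra_w, state)
    if np.ndim(signaling) == 0:
        g_sig = state[..., int(signaling), :]
    else:  # per-batch signaling index
        g_sig = np.take_along_axis(
            state, np.asarray(signaling)[:, None, None], axis=-2)[..., 0, :]
    x += inter_w[..., :, None] * \
        _neighbor_sum(g_sig, boundary, neighbor_mode)[..., None, :]
    return x + ext


def step(state: np.ndarray, circuit: Circuit, config: SimulationConfig,
         rng: np.random.Generator | None = None,
         noise: np.ndarray | None = None) -> np.ndarray:
    """One explicit-Euler update followed by multiplicative noise.

    ``g <- g + dt * (max(phi(x), 0) - decay * g)``, then ``g <- g * (1 + u)``
    with ``u ~ Uniform(-noise_amplitude, +noise_amplitude)`` drawn
    independently per gene and cell; the result is clamped at zero.  Noise
    factors may be supplied precomputed via ``noise`` (as
    :func:`simulate_tissue` does) or drawn from ``rng``; with neither, the
    update is deterministic.
    """
    state = np.asarray(state, dtype=float)
    params = circuit.params
    x = _net_input_all(state, np.asarray(params.intra_w), np.asarray(params.inter_w),
                       circuit.signaling, external_input(config), config.boundary,
                       config.neighbor_mode)
    production = np.maximum(regulation_rate(x, np.asarray(params.alpha)[:, None],
                                            params.beta), 0.0)
    new = state + config.dt * (production - config.decay * state)
    if noise is not None:
        new = new * noise
    elif rng is not None and config.noise_amplitude > 0:
        new = new * (1.0 + rng.uniform(-config.noise_amplitude,
                                       config.noise_amplitude, size=new.shape))
    return np.maximum(new, 0.0)


def simulate_tissue(circuit: Circuit, config: SimulationConfig,
                    stop_check: Callable[[np.ndarray, int], bool] | None = None,
                    check_every: int = 25) -> TissueTrace:
    """Integrate the multicellular model, recording every snapshot.

    Starts from the uniform initial condition, runs at most
    ``config.max_steps`` Euler steps and is bit-for-bit deterministic given
    ``config.seed`` (noise comes from the counter-based stream).
    ``stop_check(concentrations_so_far, step)`` may end the run early (used
    by the scoring module once its equilibrium detector fires).
    """
    circuit.params.validate_against(circuit.topology)
    noisy = config.noise_amplitude > 0
    n_keep = config.max_steps + 1
    concs = np.empty((n_keep, 2, config.n_cells))
    concs[0] = config.initial_value
    state = concs[0].copy()
    last = config.max_steps
    for t in range(1, config.max_steps + 1):
        nf = noise_factors(config.seed, t, config.n_cells,
                           config.noise_amplitude) if noisy else None
        state = step(state, circuit, config, noise=nf)
        concs[t] = state
        if stop_check is not None and t % check_every == 0 and stop_check(concs[:t + 1], t):
            last = t
            break
    return TissueTrace(concentrations=concs[:last + 1],
                       times=np.arange(last + 1), config=config)


def two_cell_rhs(circuit: Circuit, T: float, C: float,
                 trigger_gene: int = 0, context_gene: int = 0):
    """Right-hand side of the reduced two-cell ODE system.

    State order is (D_c1, A_c1, D_c2, A_c2).  Each cell's signaling input
    comes from the other cell's D; T enters the trigger gene of cell 1 only
    and C the context gene of both cells.  Returns ``f(y)`` accepting shape
    ``(4,)`` or batched ``(..., 4)``.
    """
    sig = circuit.signaling
    intra = np.asarray(circuit.params.intra_w)
    inter = np.asarray(circuit.params.inter_w)
    alpha = np.asarray(circuit.params.alpha)
    beta = circuit.params.beta
    lam = 0.05
    # gene order in the state vector: (D, A) per cell
    order = (sig, 1 - sig)
    inv = np.argsort(order)

    ext = np.zeros((2, 2))  # (cell, gene-in-natural-order)
    ext[0, trigger_gene] += T
    ext[:, context_gene] += C

    def rhs(y):
        y = np.asarray(y, dtype=float)
        cells = y.reshape(y.shape[:-1] + (2, 2))          # (..., cell, [D, A])
        nat = cells[..., inv]                             # natural gene order
        d_other = cells[..., ::-1, 0]                     # other cell's D
        x = np.einsum("ij,...cj->...ci", intra, nat)
        x += inter[None, :] * d_other[..., None]
        x = x + ext
        prod = regulation_rate(x, alpha[None, :], beta)
        dnat = prod - lam * nat
        return dnat[..., order].reshape(y.shape)

    rhs.decay = lam
    return rhs


def simulate_two_cell(circuit: Circuit, T: float, C: float,
                      init: TwoCellState | Sequence[float],
                      duration: float, dt: float = 1.0,
                      trigger_gene: int = 0, context_gene: int = 0) -> np.ndarray:
    """Noise-free trajectory of the two-cell model.

    Uses the same explicit-Euler discretization as the tissue model; returns
    an array of shape (n_steps + 1, 4) with rows (D_c1, A_c1, D_c2, A_c2),
    clamped to be nonnegative throughout.
    """
    rhs = two_cell_rhs(circuit, T, C, trigger_gene, context_gene)
    y = init.as_array() if isinstance(init, TwoCellState) else np.asarray(init, float)
    n = int(round(duration / dt))
    out = np.empty((n + 1, 4))
    out[0] = y
    for k in range(1, n + 1):
        y = np.maximum(y + dt * rhs(y), 0.0)
        out[k] = y
    return out


# ---------------------------------------------------------------------------
# Batched tissue kernel (used by the screening pipeline)
# ---------------------------------------------------------------------------

@dataclass
class BatchParams:
    """Array-of-structs parameter block for vectorized tissue simulation.

    All arrays share leading batch dimension B: ``intra_w`` (B, 2, 2),
    ``inter_w`` (B, 2), ``alpha`` (B, 2), ``beta`` (B,), plus per-sample
    trigger/context gene indices and context values.
    """

    intra_w: np.ndarray
    inter_w: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    trigger_gene: np.ndarray
    context_gene: np.ndarray
    context_value: np.ndarray
    signaling: int = 0

    @property
    def size(self) -> int:
        return len(self.beta)

    def external_input(self, config: SimulationConfig) -> np.ndarray:
        b = self.size
        ext = np.zeros((b, 2, config.n_cells))
        rows = np.arange(b)
        ext[rows, self.trigger_gene, config.trigger_cell] += config.trigger_value
        ext[rows, self.context_gene, :] += self.context_value[:, None]
        return ext


def batch_initial_state(bp: BatchParams, config: SimulationConfig) -> np.ndarray:
    return np.full((bp.size, 2, config.n_cells), config.initial_value)


def batch_step(state: np.ndarray, bp: BatchParams, config: SimulationConfig,
               ext: np.ndarray, noise: np.ndarray | None = None) -> np.ndarray:
    """Vectorized Euler + noise update over a batch of parameter sets."""
    x = _net_input_all(state, bp.intra_w, bp.inter_w, bp.signaling, ext,
                       config.boundary, config.neighbor_mode)
    production = expit(bp.beta[:, None, None] * x - bp.alpha[:, :, None])
    new = state + config.dt * (production - config.decay * state)
    if noise is not None:
        new = new * noise
    return np.maximum(new, 0.0)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["schema_version"] = SCHEMA_VERSION
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = {k: v for k, v in d.items() if k != "schema_version"}
    return SimulationConfig(**d)


def circuit_to_dict(circuit: Circuit) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "topology": {
            "intra": [list(r) for r in circuit.topology.intra],
            "inter": list(circuit.topology.inter),
            "signaling": circuit.topology.signaling,
        },
        "params": {
            "intra_w": [list(r) for r in circuit.params.intra_w],
            "inter_w": list(circuit.params.inter_w),
            "alpha": list(circuit.params.alpha),
            "beta": circuit.params.beta,
        },
    }


def circuit_from_dict(d: dict) -> Circuit:
    if d.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {d.get('schema_version')}")
    t, p = d["topology"], d["params"]
    return Circuit(
        Topology(tuple(tuple(r) for r in t["intra"]), tuple(t["inter"]),
                 t["signaling"]),
        ParameterSet(tuple(tuple(r) for r in p["intra_w"]), tuple(p["inter_w"]),
                     tuple(p["alpha"]), p["beta"]),
    )


def save_circuit(circuit: Circuit, path, config: SimulationConfig | None = None) -> None:
    """Write circuit (and optionally a config) to JSON or YAML by extension."""
    doc = circuit_to_dict(circuit)
    if config is not None:
        doc["config"] = config_to_dict(config)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(doc, fh)
        else:
            json.dump(doc, fh, indent=2)


def load_circuit(path) -> tuple[Circuit, SimulationConfig | None]:
    path = str(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
    cfg = config_from_dict(doc["config"]) if "config" in doc else None
    return circuit_from_dict(doc), cfg
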