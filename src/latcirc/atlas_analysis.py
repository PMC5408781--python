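"""Complexity-atlas construction and module decomposition.

The *complexity atlas* is a metagraph of successful circuit topologies:
nodes are canonical topologies annotated with their capability (induction,
inhibition, both, or strong bi-functionality), edges connect topologies
that differ by the gain or removal of exactly one regulatory interaction
(a sign flip is distance two, not an edge), and each node sits in a layer
equal to its number of links.  Minimal circuits appear at the tips of the
downward-tapering "stalactites" of the atlas.

Module decomposition asks whether a strong bi-functional topology contains
sign-consistent copies of a minimal induction circuit and a minimal
inhibition circuit: *hybrid* circuits contain one of each and are simple
overlays of two mono-functional designs; *emergent* circuits lack a module
for one function, which therefore only exists at the level of the full
circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .circuit_model import LINK_KEYS, Topology, derive_seeds
from .screen_pipeline import (BifunctionalHit, ScreenConfig, TopologyResult,
                              _classify_samples, verdict_name)

CAPABILITIES = ("induction", "inhibition", "both", "strong_bifunctional")


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

@dataclass
class ComplexityAtlas:
    """Metagraph of successful topologies.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are
    canonical topology ids with attributes ``capability``, ``layer`` (link
    count) and optionally ``klass`` (hybrid/emergent).
    """

    graph: nx.Graph

    def capability(self, node: str) -> str:
        return self.graph.nodes[node]["capability"]

    def layer(self, node: str) -> int:
        return self.graph.nodes[node]["layer"]

    def nodes_with(self, *capabilities: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["capability"] in capabilities]


def _single_link_neighbors(topo: Topology):
    """Canonical topologies reachable by removing or gaining one link."""
    for key in LINK_KEYS:
        sign = topo.entry(key)
        if sign != 0:
            yield topo.with_link(key, 0)
        else:
            yield topo.with_link(key, 1)
            yield topo.with_link(key, -1)


def build_atlas(screen_results: list[TopologyResult],
                strong_hits: list[BifunctionalHit] | None = None) -> ComplexityAtlas:
    """Atlas of the successful topologies of a screen.

    Nodes are topologies with at least one induction or inhibition hit;
    capability is ``both`` when a topology has hits of either kind and is
    upgraded to ``strong_bifunctional`` when it appears among the context
    screen's function-switching hits.
    """
    strong_ids = {h.topology_id for h in (strong_hits or [])}
    g = nx.Graph()
    for res in screen_results:
        caps = res.capabilities
        if not caps:
            continue
        node = res.topology.canonical().encode()
        cap = "both" if len(caps) == 2 else next(iter(caps))
        if node in strong_ids:
            cap = "strong_bifunctional"
        g.add_node(node, capability=cap, layer=res.topology.n_links,
                   n_induction=res.n_induction, n_inhibition=res.n_inhibition)
    for node in list(g.nodes):
        topo = Topology.decode(node)
        for nb in _single_link_neighbors(topo):
            nb_id = nb.encode()
            if nb_id in g and nb_id != node:
                g.add_edge(node, nb_id)
    return ComplexityAtlas(graph=g)


def stalactites(atlas: ComplexityAtlas, *capabilities: str) -> list[dict]:
    """Maximal connected subgraphs of a capability class.

    Each stalactite records its member nodes, its bottom layer and its
    minimal members (nodes with no in-class single-link-removal neighbor).
    """
    if not capabilities:
        capabilities = CAPABILITIES
    nodes = set(atlas.nodes_with(*capabilities))
    sub = atlas.graph.subgraph(nodes)
    out = []
    for idx, comp in enumerate(sorted(nx.connected_components(sub),
                                      key=lambda c: (min(atlas.layer(n) for n in c),
                                                     sorted(c)[0]))):
        layers = {n: atlas.layer(n) for n in comp}
        bottom = min(layers.values())
        minimal = [n for n in comp
                   if not any(layers.get(m, 99) < layers[n]
                              for m in sub.neighbors(n))]
        out.append({"component": idx, "nodes": sorted(comp),
                    "bottom_layer": bottom, "minimal": sorted(minimal)})
    return out


def layout_coordinates(atlas: ComplexityAtlas) -> dict[str, tuple[int, int]]:
    """(layer, component-index) coordinates for every node."""
    coords = {}
    for stal in stalactites(atlas):
        for n in stal["nodes"]:
            coords[n] = (atlas.layer(n), stal["component"])
    return coords


# ---------------------------------------------------------------------------
# Minimal topologies
# ---------------------------------------------------------------------------

def minimal_topologies(results: list[TopologyResult] | ComplexityAtlas,
                       function: str) -> list[Topology]:
    """Successful topologies with no successful single-link-removal subset.

    ``function`` is ``"induction"`` or ``"inhibition"``; success for the
    atlas form means any capability covering the function.
    """
    if isinstance(results, ComplexityAtlas):
        cover = {"induction": ("induction", "both", "strong_bifunctional"),
                 "inhibition": ("inhibition", "both", "strong_bifunctional")}
        good = set(results.nodes_with(*cover[function]))
    else:
        attr = {"induction": "n_induction", "inhibition": "n_inhibition"}[function]
        good = {r.topology.canonical().encode() for r in results
                if getattr(r, attr) > 0}
    out = []
    for node in sorted(good):
        topo = Topology.decode(node)
        subs = [topo.with_link(k, 0).encode() for k in topo.links]
        if not any(s in good for s in subs):
            out.append(topo)
    return out


# ---------------------------------------------------------------------------
# Module containment and union
# ---------------------------------------------------------------------------

def contains_module(topology: Topology, module: Topology) -> bool:
    """Whether every module link appears in the topology with the same sign.

    Both structures are compared in canonical form (signaling gene at
    index 0), so the signaling roles are aligned; extra links in the
    topology are allowed.
    """
    t = topology.canonical()
    m = module.canonical()
    return all(t.entry(k) == m.entry(k) for k in m.links)


@dataclass(frozen=True)
class Conflict:
    """Result of a union attempt in which some shared link disagrees in sign."""

    keys: tuple[tuple, ...]

    def __bool__(self):  # a conflict is falsy as a "topology"
        return False


def compatible_union(module_a: Topology, module_b: Topology) -> Topology | Conflict:
    """Entrywise union of two modules, or a :class:`Conflict`.

    The union exists iff no link carried by both modules has opposite
    signs; it is commutative and idempotent.
    """
    a = module_a.canonical()
    b = module_b.canonical()
    bad = tuple(k for k in LINK_KEYS
                if a.entry(k) * b.entry(k) == -1)
    if bad:
        return Conflict(keys=bad)
    merged = a
    for k in b.links:
        merged = merged.with_link(k, b.entry(k))
    return merged


# ---------------------------------------------------------------------------
# Hybrid candidates and classification
# ---------------------------------------------------------------------------

def enumerate_hybrid_candidates(library: dict[str, Topology]) -> dict:
    """All pairwise unions of the library's induction and inhibition modules.

    ``library`` maps names (``D0``..``D5``, ``H0``..``H5``) to topologies.
    Returns the conflict-free unions labeled ``A``, ``B``, ... in
    deterministic (induction-name, inhibition-name) order, plus the
    conflicting pairs.
    """
    d_names = sorted(n for n in library if n.upper().startswith("D"))
    h_names = sorted(n for n in library if n.upper().startswith("H"))
    candidates, conflicts = [], []
    for dn in d_names:
        for hn in h_names:
            res = compatible_union(library[dn], library[hn])
            if isinstance(res, Conflict):
                conflicts.append({"pair": (dn, hn), "conflict": res})
            else:
                candidates.append({"pair": (dn, hn), "topology": res})
    # deduplicate unions that coincide, keeping all contributing pairs
    merged: dict[str, dict] = {}
    for c in candidates:
        tid = c["topology"].encode()
        merged.setdefault(tid, {"topology": c["topology"], "pairs": []})
        merged[tid]["pairs"].append(c["pair"])
    labels = {}
    for label, tid in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", sorted(merged)):
        labels[label] = merged[tid] | {"id": tid}
    return {"n_pairs": len(d_names) * len(h_names),
            "n_conflicting_pairs": len(conflicts),
            "n_candidates": len(merged),
            "candidates": labels, "conflicts": conflicts}


def one_link_extensions(topology: Topology) -> list[Topology]:
    """All topologies formed by adding a single new link."""
    out = []
    for key in LINK_KEYS:
        if topology.entry(key) == 0:
            out.append(topology.with_link(key, 1))
            out.append(topology.with_link(key, -1))
    return out


@dataclass
class DecompositionReport:
    """Hybrid/emergent classification of a strong bi-functional topology."""

    topology_id: str
    induction_modules: list[str]
    inhibition_modules: list[str]
    klass: str                      # "hybrid" | "emergent"
    missing_function: str | None    # set for emergent circuits

    def to_dict(self) -> dict:
        return {"topology_id": self.topology_id,
                "induction_modules": self.induction_modules,
                "inhibition_modules": self.inhibition_modules,
                "class": self.klass, "missing_function": self.missing_function}


def classify_bifunctional(topology: Topology,
                          library: dict[str, Topology]) -> DecompositionReport:
    """Structural decomposition of a bi-functional topology.

    *Hybrid* iff the topology contains at least one minimal induction
    module and at least one minimal inhibition module from the library;
    otherwise *emergent*, recording which function lacks a module.
    """
    d_mods = sorted(n for n in library if n.upper().startswith("D")
                    and contains_module(topology, library[n]))
    h_mods = sorted(n for n in library if n.upper().startswith("H")
                    and contains_module(topology, library[n]))
    if d_mods and h_mods:
        klass, missing = "hybrid", None
    else:
        klass = "emergent"
        missing = "induction" if not d_mods else "inhibition"
    return DecompositionReport(topology_id=topology.canonical().encode(),
                               induction_modules=d_mods,
                               inhibition_modules=h_mods,
                               klass=klass, missing_function=missing)


# ---------------------------------------------------------------------------
# Robustness (simplified perturbation score)
# ---------------------------------------------------------------------------

def robustness_score(hit: BifunctionalHit, delta: float = 0.1, n: int = 100,
                     seed: int = 0, screen: ScreenConfig | None = None) -> float:
    """Fraction of parameter perturbations preserving strong bi-functionality.

    Each weight and each alpha is multiplied by an independent factor drawn
    uniformly from ``[1 - delta, 1 + delta]``; a perturbed circuit counts as
    retained when its verdicts at C = 0 and C = 1 (with the hit's recorded
    trigger/context genes) reproduce the hit's function map.  This is a
    simplified perturbation protocol, not a reproduction of any published
    robustness pipeline.
    """
    screen = screen or ScreenConfig()
    topo = hit.topology
    p = hit.params
    rng = np.random.default_rng(seed)
    fac = rng.uniform(1 - delta, 1 + delta, size=(n, 8))
    intra = np.asarray(p.intra_w)[None, :, :] * fac[:, :4].reshape(n, 2, 2)
    inter = np.asarray(p.inter_w)[None, :] * fac[:, 4:6]
    alpha = np.asarray(p.alpha)[None, :] * fac[:, 6:8]
    beta = np.full(n, p.beta)
    arrs = {"intra_w": intra, "inter_w": inter, "alpha": alpha, "beta": beta}
    ok = np.ones(n, dtype=bool)
    for cval in (0.0, 1.0):
        codes = _classify_samples(
            topo, arrs, screen,
            trigger_genes=np.full(n, hit.trigger_gene, dtype=int),
            context_genes=np.full(n, hit.context_gene, dtype=int),
            context_values=np.full(n, cval),
            noise_seed_base=derive_seeds(seed, 2)[int(cval)])
        want = hit.function_map[cval]
        ok &= np.array([verdict_name(c) == want for c in codes])
    return float(ok.mean())
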