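"""Molecular complex detection (MCODE) on compartment-labeled PPI graphs.

The algorithm scores each vertex by the product of the highest core number
of its (degree-filtered) closed neighborhood and the density of that
highest k-core — a local-density weight — then grows complexes outward from
high-weight seeds, admitting neighbors whose weight is within a
vertex-weight-percentage (VWP) tolerance of the seed's.  Optional
post-processing removes sparsely attached members (haircut, a 2-core) or
pulls in dense boundary vertices (fluff).  Complexes are scored by
density x size and ranked.

Tie-breaking, left open by the original description, is made total here so
runs are fully deterministic: seeds are ordered by (weight, degree,
symbol), complex ranks by (score, size, lexicographically smallest member).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx

from .ppi_network import density, highest_k_core

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCODEParams:
    """Tunables of the complex-detection algorithm (canonical defaults)."""

    degree_cutoff: int = 2
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density_threshold: float = 0.1
    max_depth: int = 100

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not 0 <= self.vwp < 1:
            raise ValueError("vwp must be in [0, 1)")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class ComplexResult:
    """A detected complex: members, seed, density x size score, rank."""

    members: frozenset
    seed: str
    score: float
    rank: int
    edge_count: int
    fluffed: frozenset = frozenset()

    @property
    def size(self) -> int:
        return len(self.members)

    def subgraph(self, graph: nx.Graph) -> nx.Graph:
        return graph.subgraph(self.members).copy()


def vertex_weight(graph: nx.Graph, v, degree_cutoff: int = 2) -> float:
    """Local-density weight of a vertex.

    The closed neighborhood N[v] is induced, restricted to vertices whose
    degree within it is at least ``degree_cutoff``, and the weight is
    k_max x density(highest k-core of the restriction).  Vertices whose
    filtered neighborhood has no edges weigh 0.
    """
    if v not in graph:
        raise KeyError(f"unknown node {v!r}")
    closed = set(graph[v]) | {v}
    nbhd = graph.subgraph(closed)
    kept = [u for u in nbhd if nbhd.degree(u) >= degree_cutoff]
    filtered = nbhd.subgraph(kept)
    if filtered.number_of_edges() == 0:
        return 0.0
    k_max, core = highest_k_core(filtered)
    return k_max * density(core)


def _seed_order(graph: nx.Graph, weights: dict) -> list:
    return sorted(graph.nodes, key=lambda v: (-weights[v], -graph.degree(v), str(v)))


def _grow(graph, seed, weights, threshold, max_depth, assigned) -> set:
    """Breadth-first expansion from a seed under the weight threshold.

    A node is examined at most once per complex and admitted on its first
    qualifying encounter; nodes already assigned to an earlier complex are
    never admitted.
    """
    members = {seed}
    checked = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < max_depth:
        nxt = []
        for u in frontier:
            for nb in sorted(graph[u], key=str):
                if nb in checked or nb in assigned:
                    continue
                checked.add(nb)
                if weights[nb] >= threshold:
                    members.add(nb)
                    nxt.append(nb)
        frontier = nxt
        depth += 1
    return members


def _haircut(graph: nx.Graph, members: set) -> set:
    """Iteratively shed degree-1 members (the 2-core of the complex)."""
    sub = graph.subgraph(members)
    core = nx.k_core(sub, 2)
    return set(core.nodes)


def _fluff(graph: nx.Graph, members: set, threshold: float) -> set:
    """Boundary vertices whose closed-neighborhood density exceeds threshold."""
    added = set()
    for u in sorted(members, key=str):
        for nb in graph[u]:
            if nb in members or nb in added:
                continue
            closed = set(graph[nb]) | {nb}
            if density(graph.subgraph(closed)) > threshold:
                added.add(nb)
    return added


def find_complexes(graph: nx.Graph, params: MCODEParams | None = None) -> list:
    """Detect, post-process, score, and rank molecular complexes.

    Complexes are grown from seeds in decreasing vertex-weight order; a
    vertex belongs to at most one grown complex (fluff additions may
    overlap and are reported in ``ComplexResult.fluffed``).  Only complexes
    with at least two members and one edge are returned, sorted by score
    descending with total tie-breaking.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    params = params or MCODEParams()
    weights = {v: vertex_weight(graph, v, params.degree_cutoff) for v in graph.nodes}
    threshold_of = lambda seed: (1.0 - params.vwp) * weights[seed]
    assigned: set = set()
    raw: list[tuple] = []
    for seed in _seed_order(graph, weights):
        if seed in assigned or weights[seed] <= 0:
            continue
        members = _grow(graph, seed, weights, threshold_of(seed),
                        params.max_depth, assigned)
        assigned |= members
        if params.haircut:
            members = _haircut(graph, members)
        if len(members) < 2:
            continue
        fluffed = frozenset()
        if params.fluff:
            fluffed = frozenset(_fluff(graph, members, params.fluff_density_threshold))
            members = members | fluffed
        sub = graph.subgraph(members)
        if sub.number_of_edges() == 0:
            continue
        score = density(sub) * len(members)
        raw.append((frozenset(members), seed, score, sub.number_of_edges(), fluffed))

    raw.sort(key=lambda r: (-r[2], -len(r[0]), min(r[0], key=str)))
    results = [
        ComplexResult(members=m, seed=s, score=sc, rank=i + 1,
                      edge_count=e, fluffed=f)
        for i, (m, s, sc, e, f) in enumerate(raw)
    ]
    overlap = sum(len(r.fluffed & q.members) for r in results for q in results if r is not q)
    logger.info("find_complexes: %d complexes (%d overlapping fluff additions)",
                len(results), overlap)
    return results


def top_k(results: list, k: int) -> list:
    """First min(k, len) complexes in ranked order, ranks re-assigned 1..k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [replace(r, rank=i + 1) for i, r in enumerate(results[:k])]


def complexes_to_frame(results: list):
    import pandas as pd

    rows = [
        {
            "rank": r.rank,
            "score": r.score,
            "n_members": r.size,
            "n_edges": r.edge_count,
            "seed": r.seed,
            "members": ";".join(sorted(r.members)),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["rank", "score", "n_members", "n_edges", "seed", "members"])


def write_complexes_tsv(results: list, path) -> None:
    complexes_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_gmt(results: list, path, prefix: str = "complex") -> None:
    """One line per complex: name, score description, members."""
    with open(path, "w") as fh:
        for r in results:
            fh.write("\t".join([f"{prefix}_{r.rank}", f"score={r.score:.6g}",
                                *sorted(r.members)]) + "\n")
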