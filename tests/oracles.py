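"""Independent brute-force oracles used to validate the graph algorithms.

Everything here is deliberately naive — subset enumeration, Floyd-Warshall,
exhaustive triple enumeration — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def edges_of(graph):
    return {frozenset(e) for e in graph.edges}


def brute_density(nodes, edge_set):
    n = len(nodes)
    if n < 2:
        return 0.0
    nodeset = set(nodes)
    e = sum(1 for edge in edge_set if edge <= nodeset)
    return 2.0 * e / (n * (n - 1))


def brute_k_core(graph, k):
    """Union of all vertex subsets inducing minimum degree >= k (n <= ~16)."""
    nodes = list(graph.nodes)
    edge_set = edges_of(graph)
    best: set = set()
    for r in range(len(nodes), 0, -1):
        for subset in combinations(nodes, r):
            s = set(subset)
            ok = all(
                sum(1 for u in s if u != v and frozenset((u, v)) in edge_set) >= k
                for v in s
            )
            if ok:
                best |= s
        if best:
            # the k-core is the union of all qualifying subsets; any
            # maximal qualifying subset already contains the rest
            break
    return best


def brute_highest_core(nodes, edge_set):
    """(k_max, core node set) by descending exhaustive search."""
    nodes = list(nodes)
    if not nodes:
        return 0, set()
    for k in range(len(nodes) - 1, 0, -1):
        union: set = set()
        for r in range(k + 1, len(nodes) + 1):
            for subset in combinations(nodes, r):
                s = set(subset)
                if all(
                    sum(1 for u in s if u != v and frozenset((u, v)) in edge_set) >= k
                    for v in s
                ):
                    union |= s
        if union:
            return k, union
    return 0, set(nodes)


def brute_vertex_weight(graph, v, degree_cutoff=2):
    """Closed-neighborhood core weight via exhaustive core search."""
    closed = set(graph[v]) | {v}
    edge_set = {e for e in edges_of(graph) if e <= closed}
    deg_in = {
        u: sum(1 for w in closed if w != u and frozenset((u, w)) in edge_set)
        for u in closed
    }
    kept = {u for u in closed if deg_in[u] >= degree_cutoff}
    kept_edges = {e for e in edge_set if e <= kept}
    if not kept_edges:
        return 0.0
    k_max, core = brute_highest_core(kept, kept_edges)
    return k_max * brute_density(core, kept_edges)


def floyd_warshall(graph):
    """All-pairs hop distances by the classic triple loop."""
    nodes = list(graph.nodes)
    dist = {u: {v: (0 if u == v else math.inf) for v in nodes} for u in nodes}
    for a, b in graph.edges:
        dist[a][b] = dist[b][a] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if math.isinf(dik):
                continue
            for j in nodes:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def brute_bridge_length(graph, c, er_nodes, mito_nodes):
    """min over (e, m) of d(e, c) + d(c, m), by exhaustive triple enumeration."""
    dist = floyd_warshall(graph)
    best = math.inf
    for e in er_nodes:
        for m in mito_nodes:
            best = min(best, dist[e][c] + dist[c][m])
    return best
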