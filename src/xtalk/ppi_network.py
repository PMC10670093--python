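"""Compartment-labeled protein-protein interaction graphs.

Thin, well-specified wrappers around :mod:`networkx` that fix the
conventions the rest of the pipeline relies on: graphs are simple and
undirected, every node carries a ``compartment`` attribute copied from the
catalog at build time, edges outside the catalog are dropped (closed-world
assumption), and edge confidence is carried but never used by downstream
stages (paths are hop-based, density unweighted).
"""

from __future__ import annotations

import logging
import math
from collections import deque
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .organelle_catalog import ProteinCatalog

logger = logging.getLogger(__name__)


def build_graph(
    edge_table: pd.DataFrame,
    catalog: ProteinCatalog,
    min_confidence: float | None = None,
    include_isolated: bool = False,
) -> nx.Graph:
    """Build the interaction graph from an edge table restricted to a catalog.

    ``edge_table`` needs columns ``protein_a`` and ``protein_b`` and may
    carry a ``confidence`` column in [0, 1].  Edges with an endpoint outside
    the catalog are dropped and counted; self-loops and duplicates are
    removed.  By default only proteins that retain at least one interaction
    become nodes; ``include_isolated=True`` adds the full catalog.
    """
    required = {"protein_a", "protein_b"}
    if not required.issubset(edge_table.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    primary = catalog.primary_map()
    has_conf = "confidence" in edge_table.columns
    g = nx.Graph()
    n_outside = n_lowconf = n_self = n_malformed = 0
    for i, row in enumerate(edge_table.itertuples(index=False)):
        a, b = row.protein_a, row.protein_b
        if pd.isna(a) or pd.isna(b) or not str(a) or not str(b):
            raise ValueError(f"malformed edge row {i}: ({a!r}, {b!r})")
        a, b = str(a), str(b)
        if a == b:
            n_self += 1
            continue
        if a not in primary or b not in primary:
            n_outside += 1
            continue
        conf = None
        if has_conf:
            conf = float(row.confidence)
            if min_confidence is not None and conf < min_confidence:
                n_lowconf += 1
                continue
        if conf is None:
            g.add_edge(a, b)
        else:
            g.add_edge(a, b, confidence=conf)
    if include_isolated:
        g.add_nodes_from(primary)
    nx.set_node_attributes(
        g, {v: primary[v] for v in g.nodes}, name="compartment"
    )
    logger.info(
        "build_graph: %d nodes / %d edges (%d outside catalog, %d below "
        "confidence %s, %d self-loops dropped)",
        g.number_of_nodes(), g.number_of_edges(), n_outside, n_lowconf,
        min_confidence, n_self,
    )
    return g


def annotate_compartments(graph: nx.Graph, catalog: ProteinCatalog) -> nx.Graph:
    """Attach primary-compartment node attributes from the catalog in place."""
    primary = catalog.primary_map()
    unknown = [v for v in graph.nodes if v not in primary]
    if unknown:
        raise ValueError(f"graph nodes missing from catalog: {sorted(unknown)[:5]} ...")
    nx.set_node_attributes(graph, {v: primary[v] for v in graph.nodes}, "compartment")
    return graph


def density(graph: nx.Graph) -> float:
    """Simple-graph density 2e / (n(n-1)); a single node has density 0."""
    n = graph.number_of_nodes()
    if n < 1:
        raise ValueError("density needs at least one node")
    if n == 1:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph in which every vertex has degree >= k (may be empty)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return graph.copy()
    return nx.k_core(graph, k)


def highest_k_core(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """The non-empty core with maximal k, as (k_max, core subgraph)."""
    if graph.number_of_nodes() == 0:
        return 0, graph.copy()
    core_numbers = nx.core_number(graph)
    k_max = max(core_numbers.values())
    nodes = [v for v, c in core_numbers.items() if c >= k_max]
    return k_max, graph.subgraph(nodes).copy()


def bfs_distances(graph: nx.Graph, sources: Iterable) -> dict:
    """Unweighted hop distance from a source set to every node.

    Multi-source breadth-first search; unreachable nodes map to ``inf``.
    """
    sources = list(sources)
    unknown = [s for s in sources if s not in graph]
    if unknown:
        raise ValueError(f"unknown source nodes: {sorted(unknown)}")
    dist = {v: math.inf for v in graph.nodes}
    queue = deque()
    for s in sources:
        dist[s] = 0
        queue.append(s)
    while queue:
        u = queue.popleft()
        for w in graph[u]:
            if math.isinf(dist[w]):
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def compartment_nodes(graph: nx.Graph, compartment: str) -> set:
    """Nodes whose primary compartment equals ``compartment``."""
    return {v for v, c in graph.nodes(data="compartment") if c == compartment}


def write_edge_tsv(graph: nx.Graph, path) -> None:
    rows = [
        {"protein_a": min(a, b), "protein_b": max(a, b),
         "confidence": d.get("confidence", "")}
        for a, b, d in graph.edges(data=True)
    ]
    rows.sort(key=lambda r: (r["protein_a"], r["protein_b"]))
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"]).to_csv(
        path, sep="\t", index=False
    )


def write_sif(graph: nx.Graph, path) -> None:
    """Simple interaction format: one "A pp B" line per edge."""
    lines = sorted(f"{min(a, b)}\tpp\t{max(a, b)}" for a, b in graph.edges)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_edge_table(path) -> pd.DataFrame:
    """Read an edge list from TSV (protein_a/protein_b[/confidence]) or SIF."""
    path = str(path)
    if path.endswith(".sif"):
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 3:
                    raise ValueError(f"malformed SIF line: {line.rstrip()!r}")
                rows.append({"protein_a": parts[0], "protein_b": parts[2]})
        return pd.DataFrame(rows, columns=["protein_a", "protein_b"])
    return pd.read_csv(path, sep="\t")
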