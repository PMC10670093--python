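"""Packaged synthetic fixtures with known ground truth.

Three ready-made constructions used throughout the tests and the worked
examples:

* :func:`reference_screen_fixture` — a full-scale bundle (catalog, network,
  expression studies, Ct table) shaped like a published organelle screen:
  a 2941-protein catalog (243 ER / 1399 mitochondria / 1299 cytosol),
  three dense complexes of 84, 66 and 44 members over a sparse background,
  with the 44-member complex tri-compartmental (37 mito / 6 cytosol / 1 ER)
  and carrying the named relay motif DDO-(IDE, UBA52)-SEC61A1: the
  cytosolic linker DDO touches the ER only through the two mitochondrial
  intermediates.
* :func:`planted_linker_fixture` — a single sparse tri-compartment cluster
  (18 mito / 6 cytosol / 1 ER, the 44-member composition at reduced scale)
  with the relay motif planted over a p=0.02 background, for linker
  recovery tests.
* :func:`planted_complex_fixture` — two dense planted complexes in an
  Erdos-Renyi background, for complex-detection recovery tests.

Everything is generated from one integer seed; identical seeds give
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .mcode_clustering import MCODEParams
from .organelle_catalog import CatalogRecord, ProteinCatalog
from .synthetic_data import (
    ComplexSpec,
    SyntheticTruth,
    _gnp_edges,
    generate_catalog,
    generate_ct_table,
    generate_expression,
    generate_network,
)

#: Motif protein names of the end-to-end fixture.
LINKER = "DDO"
MITO_INTERMEDIATES = ("IDE", "UBA52")
ER_ENDPOINT = "SEC61A1"

#: MCODE settings the end-to-end fixture is meant to be clustered with.
#: Fluff is enabled because the relay motif's linker and ER endpoint attach
#: to the complex through only two edges each: they are dense-neighborhood
#: boundary vertices, exactly the case the fluff stage exists for.
REFERENCE_SCREEN_MCODE = MCODEParams(fluff=True)


@dataclass
class FixtureBundle:
    catalog: ProteinCatalog
    graph: nx.Graph
    studies: list
    ct_table: pd.DataFrame
    truth: SyntheticTruth
    control_group: str = "control"


def _rename(catalog: ProteinCatalog, mapping: dict) -> ProteinCatalog:
    records = {}
    for sym, rec in catalog.records.items():
        new = mapping.get(sym, sym)
        records[new] = CatalogRecord(new, rec.support, rec.primary)
    return ProteinCatalog(records, n_rejected=catalog.n_rejected)


def reference_screen_fixture(seed: int = 0) -> FixtureBundle:
    """Full synthetic screen bundle with the named tri-compartment complex.

    The three planted complexes reproduce the 84-, 66- and 44-member shape
    of the reference screen in strictly decreasing density-x-size score:
    the first two are dense circulant graphs (3444 and 1848 internal
    edges), the third has a complete 37-member mitochondrial core with a
    sparse tri-compartment boundary.  Complexes and the sparse background
    are disjoint components so complex boundaries are exact.
    Expression covers all catalog genes in three case/control studies of
    114, 94 and 69 samples (277 total) with a 15% planted DEG set at a
    log2 shift of 1.5; the Ct table has three 25-sample groups with planted
    folds 0.5 (istradefylline), 0.9 (amantadine) and 1.0 (control).
    """
    ss = np.random.SeedSequence([seed, 0x5EED])
    (c_members, c_edges, c_expr, c_ct) = ss.spawn(4)
    rng = np.random.default_rng(c_members)
    erng = np.random.default_rng(c_edges)

    catalog = generate_catalog(2941, seed=seed)
    primary = catalog.primary_map()
    pools = {c: sorted(s for s, p in primary.items() if p == c)
             for c in ("ER", "mitochondria", "cytosol")}

    def take(comp: str, k: int) -> list:
        pool = pools[comp]
        idx = sorted(rng.choice(len(pool), size=k, replace=False))
        chosen = [pool[i] for i in idx]
        pools[comp] = [s for i, s in enumerate(pool) if i not in set(idx)]
        return chosen

    a_members = take("mitochondria", 84)
    b_members = take("mitochondria", 60) + take("cytosol", 6)
    c_mito = take("mitochondria", 37)
    c_cyto = take("cytosol", 6)
    c_er = take("ER", 1)
    background = take("mitochondria", 60) + take("cytosol", 60) + take("ER", 30)

    mapping = {c_cyto[0]: LINKER, c_mito[0]: MITO_INTERMEDIATES[0],
               c_mito[1]: MITO_INTERMEDIATES[1], c_er[0]: ER_ENDPOINT}
    catalog = _rename(catalog, mapping)
    relabel = lambda syms: [mapping.get(s, s) for s in syms]
    c_mito, c_cyto, c_er = relabel(c_mito), relabel(c_cyto), relabel(c_er)
    background = relabel(background)

    def circulant_edges(nodes, k):
        # vertex-transitive dense complex: every member has identical degree
        # and identical MCODE weight, so growth always recovers it whole
        nodes = sorted(nodes)
        n = len(nodes)
        for i in range(n):
            for off in range(1, k + 1):
                yield nodes[i], nodes[(i + off) % n]

    g = nx.Graph()
    g.add_nodes_from(sorted(catalog.symbols))
    g.add_edges_from(circulant_edges(a_members, 41))
    g.add_edges_from(circulant_edges(b_members, 28))
    # tri-compartment complex: a complete mitochondrial core, so every core
    # member (including the two relay intermediates) carries the same
    # vertex weight and the growth stage recovers the core as one complex;
    # the sparsely attached cytosolic members, the linker and the ER
    # endpoint are boundary vertices that the fluff stage pulls in
    g.add_edges_from(
        (a, b) for i, a in enumerate(sorted(c_mito))
        for b in sorted(c_mito)[i + 1:]
    )
    # ... cytosolic members wired to the core but not to the motif's
    # intermediates, so the planted linker's ER route is uniquely shortest
    mito_other = sorted(set(c_mito) - set(MITO_INTERMEDIATES))
    for cy in sorted(set(c_cyto) - {LINKER}):
        picks = erng.random(len(mito_other)) < 0.3
        neighbors = [m for m, keep in zip(mito_other, picks) if keep]
        if len(neighbors) < 2:  # keep every cytosolic member well-attached
            extra = [m for m in mito_other if m not in neighbors]
            neighbors += list(erng.choice(extra, size=2 - len(neighbors), replace=False))
        g.add_edges_from((cy, m) for m in neighbors)
    # the relay motif itself: linker and ER endpoint attach only through
    # the two mitochondrial intermediates
    g.add_edges_from((LINKER, m) for m in MITO_INTERMEDIATES)
    g.add_edges_from((ER_ENDPOINT, m) for m in MITO_INTERMEDIATES)
    g.add_edges_from(_gnp_edges(sorted(background), 0.03, erng))
    primary = catalog.primary_map()
    for v in g.nodes:
        g.nodes[v]["compartment"] = primary[v]

    studies, expr_truth = generate_expression(
        catalog,
        n_studies=3,
        n_per_group=[(57, 57), (47, 47), (35, 34)],
        deg_fraction=0.15,
        delta=1.5,
        noise_sd=1.0,
        seed=int(np.random.default_rng(c_expr).integers(2**31)),
    )
    ct_table = generate_ct_table(
        ["istradefylline", "amantadine", "control"],
        n_per_group=25,
        true_fold_changes={"istradefylline": 0.5, "amantadine": 0.9},
        ct_noise_sd=0.25,
        seed=int(np.random.default_rng(c_ct).integers(2**31)),
    )
    truth = SyntheticTruth(
        seed=seed,
        planted_complexes=[frozenset(a_members), frozenset(b_members),
                           frozenset(c_mito + c_cyto + c_er)],
        planted_linker=LINKER,
        motif={"linker": LINKER, "mito": MITO_INTERMEDIATES, "er": ER_ENDPOINT},
        planted_deg_set=expr_truth.planted_deg_set,
        delta=1.5,
        p_bg=0.03,
        p_in=[0.995, 0.86, 0.55],
    )
    return FixtureBundle(catalog, g, studies, ct_table, truth)


def planted_linker_fixture(
    seed: int = 0,
    n_mito: int = 18,
    n_cyto: int = 6,
    n_er: int = 1,
    p_bg: float = 0.02,
) -> tuple[ProteinCatalog, nx.Graph, SyntheticTruth]:
    """One sparse tri-compartment cluster with the relay motif planted.

    The cluster's internal background edges are drawn at ``p_bg``; the
    motif guarantees the planted cytosolic linker a finite bridge while
    competing cytosolic members must rely on background edges alone.
    """
    n = n_mito + n_cyto + n_er
    catalog = generate_catalog(
        n,
        proportions={"ER": n_er / n, "mitochondria": n_mito / n, "cytosol": n_cyto / n},
        seed=seed,
    )
    spec = ComplexSpec(
        size=n, p_in=p_bg,
        mix={"ER": n_er, "mitochondria": n_mito, "cytosol": n_cyto},
    )
    graph, truth = generate_network(
        catalog, [spec], p_bg=0.0, linker_motif=True, seed=seed
    )
    return catalog, graph, truth


def planted_complex_fixture(
    seed: int = 0,
    n: int = 200,
    complex_size: int = 20,
    n_complexes: int = 2,
    p_in: float = 0.9,
    p_bg: float = 0.02,
) -> tuple[ProteinCatalog, nx.Graph, SyntheticTruth]:
    """Dense planted complexes in a sparse Erdos-Renyi background."""
    catalog = generate_catalog(
        n, proportions={"ER": 0.1, "mitochondria": 0.45, "cytosol": 0.45}, seed=seed
    )
    specs = [ComplexSpec(size=complex_size, p_in=p_in) for _ in range(n_complexes)]
    graph, truth = generate_network(catalog, specs, p_bg=p_bg, seed=seed)
    return catalog, graph, truth
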