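"""Seeded generators for catalogs, networks, expression studies, Ct tables.

Every generator emulates the statistical structure the pipeline stages
assume, with ground truth returned alongside the data so recovery can be
tested:

* **Catalogs** mirror a curated organelle inventory — by default the
  243 ER / 1399 mitochondria / 1299 cytosol split of a 2941-protein
  three-compartment collection — with an optional fraction of
  multi-localized proteins.
* **Networks** are planted-partition graphs: dense complexes (edge
  probability ``p_in``) over a sparse Erdos-Renyi background (``p_bg``),
  optionally carrying a four-node cytosol-mito-mito-ER relay motif (one
  cytosolic node attached to two mitochondrial nodes, each attached to the
  same ER node) whose cytosolic vertex is the planted linker.
* **Expression studies** are case/control Normal matrices on a log2-like
  additive scale: a mean shift of ``delta`` equals a log2 fold change of
  ``delta``, with one planted DEG set shared across studies.
* **Ct tables** shift the target gene by -log2(fold) per group against a
  constant reference gene.

All randomness flows from one explicit seed through
:class:`numpy.random.SeedSequence` spawns, so identical calls are
byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .meta_expression import ExpressionStudy
from .organelle_catalog import COMPARTMENTS, CatalogRecord, ProteinCatalog

SOURCE = "synthetic"

#: Compartment proportions of the reference three-compartment inventory.
DEFAULT_PROPORTIONS = {
    "ER": 243 / 2941,
    "mitochondria": 1399 / 2941,
    "cytosol": 1299 / 2941,
}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for recovery tests."""

    seed: int
    planted_complexes: list = field(default_factory=list)  # list of frozensets
    planted_linker: str | None = None
    motif: dict | None = None  # {"linker", "mito": (m1, m2), "er"}
    planted_deg_set: frozenset = frozenset()
    delta: float | None = None
    p_bg: float | None = None
    p_in: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_complexes": [sorted(c) for c in self.planted_complexes],
            "planted_linker": self.planted_linker,
            "motif": (
                {"linker": self.motif["linker"], "mito": list(self.motif["mito"]),
                 "er": self.motif["er"]}
                if self.motif else None
            ),
            "planted_deg_set": sorted(self.planted_deg_set),
            "delta": self.delta,
            "p_bg": self.p_bg,
            "p_in": list(self.p_in),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass(frozen=True)
class ComplexSpec:
    """A planted complex: size, compartment mix (counts), edge probability."""

    size: int
    p_in: float
    mix: Mapping[str, int] | None = None  # compartment -> member count

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("complex size must be >= 2")
        if not 0 <= self.p_in <= 1:
            raise ValueError("p_in must lie in [0, 1]")
        if self.mix is not None and sum(self.mix.values()) != self.size:
            raise ValueError("compartment mix must sum to the complex size")


def _largest_remainder(n: int, proportions: Mapping[str, float]) -> dict:
    quotas = {c: n * f for c, f in proportions.items()}
    counts = {c: math.floor(q) for c, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(proportions, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def generate_catalog(
    n_proteins: int,
    proportions: Mapping[str, float] | None = None,
    multilocal_rate: float = 0.0,
    seed: int = 0,
) -> ProteinCatalog:
    """Synthetic compartment-labeled catalog with P000001-style symbols.

    Compartment counts follow ``proportions`` after largest-remainder
    rounding; a ``multilocal_rate`` fraction of proteins (rounded) get a
    second compartment drawn uniformly from the other two.  The first
    (rounded-proportion) compartment is recorded as the primary.
    """
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    if not 0 <= multilocal_rate < 1:
        raise ValueError("multilocal_rate must lie in [0, 1)")
    proportions = dict(proportions or DEFAULT_PROPORTIONS)
    unknown = set(proportions) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"unknown compartments in proportions: {sorted(unknown)}")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {total!r})")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = _largest_remainder(n_proteins, proportions)
    symbols = [f"P{i + 1:06d}" for i in range(n_proteins)]
    primary: list[str] = []
    for comp in COMPARTMENTS:
        primary.extend([comp] * counts.get(comp, 0))
    n_multi = int(round(multilocal_rate * n_proteins))
    multi_idx = set(rng.choice(n_proteins, size=n_multi, replace=False)) if n_multi else set()
    records = {}
    for i, (sym, comp) in enumerate(zip(symbols, primary)):
        support = {comp: frozenset({SOURCE})}
        if i in multi_idx:
            others = [c for c in COMPARTMENTS if c != comp]
            second = others[int(rng.integers(len(others)))]
            support[second] = frozenset({SOURCE})
        records[sym] = CatalogRecord(sym, support, primary=comp)
    return ProteinCatalog(records)


def _gnp_edges(nodes: Sequence[str], p: float, rng: np.random.Generator):
    """Edges of G(|nodes|, p) over the given node labels, deterministically."""
    n = len(nodes)
    if p <= 0 or n < 2:
        return
    mask_seed = int(rng.integers(2**31))
    g = nx.fast_gnp_random_graph(n, p, seed=mask_seed)
    for i, j in g.edges:
        yield nodes[i], nodes[j]


def generate_network(
    catalog: ProteinCatalog,
    complex_specs: Sequence[ComplexSpec] = (),
    p_bg: float = 0.0,
    linker_motif: bool = False,
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition interaction graph over a catalog.

    Background edges are drawn independently with probability ``p_bg`` over
    all pairs with at least one non-planted endpoint; each planted complex
    draws its internal edges with its own ``p_in``, and no background edge
    joins two planted members, so within-complex density is exactly
    ``p_in`` and the planted communities stay well-defined as ground truth
    (a random bridge between two planted complexes would merge them into
    one true community and make recovery ill-posed).  With
    ``linker_motif`` the relay motif is injected into the
    first complex whose compartment mix supports it (>= 1 cytosol, >= 2
    mitochondria, >= 1 ER); any direct edge between the motif's cytosolic
    node and an ER member of that complex is removed so the planted linker
    reaches the ER in exactly two hops.  The graph is simple, undirected,
    and contains every catalog protein (isolated nodes included).
    """
    if not 0 <= p_bg <= 1:
        raise ValueError("p_bg must lie in [0, 1]")
    if sum(s.size for s in complex_specs) > len(catalog):
        raise ValueError("complex sizes exceed catalog size")
    ss = np.random.SeedSequence(seed)
    rng_members, rng_bg, rng_complex, rng_motif = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    primary = catalog.primary_map()
    pools = {c: sorted(s for s, comp in primary.items() if comp == c)
             for c in COMPARTMENTS}
    free = {c: list(pool) for c, pool in pools.items()}

    def take(comp: str, k: int) -> list:
        pool = free[comp]
        if k > len(pool):
            raise ValueError(f"not enough free {comp} proteins for complex (need {k})")
        idx = sorted(rng_members.choice(len(pool), size=k, replace=False))
        chosen = [pool[i] for i in idx]
        free[comp] = [s for i, s in enumerate(pool) if i not in set(idx)]
        return chosen

    members_per_complex: list[dict] = []
    for spec in complex_specs:
        if spec.mix is not None:
            chosen = {c: take(c, k) for c, k in spec.mix.items() if k}
        else:
            flat = sorted(s for pool in free.values() for s in pool)
            idx = sorted(rng_members.choice(len(flat), size=spec.size, replace=False))
            picked = [flat[i] for i in idx]
            for c in COMPARTMENTS:
                free[c] = [s for s in free[c] if s not in set(picked)]
            chosen = {}
            for s in picked:
                chosen.setdefault(primary[s], []).append(s)
        members_per_complex.append(chosen)

    planted: set = set()
    for chosen in members_per_complex:
        for grp in chosen.values():
            planted.update(grp)
    g = nx.Graph()
    g.add_nodes_from(sorted(primary))
    g.add_edges_from(
        (a, b) for a, b in _gnp_edges(sorted(primary), p_bg, rng_bg)
        if not (a in planted and b in planted)
    )
    for spec, chosen in zip(complex_specs, members_per_complex):
        flat = sorted(s for grp in chosen.values() for s in grp)
        g.add_edges_from(_gnp_edges(flat, spec.p_in, rng_complex))

    truth = SyntheticTruth(
        seed=seed,
        planted_complexes=[
            frozenset(s for grp in chosen.values() for s in grp)
            for chosen in members_per_complex
        ],
        p_bg=p_bg,
        p_in=[spec.p_in for spec in complex_specs],
    )

    if linker_motif:
        host = None
        for chosen in members_per_complex:
            if (len(chosen.get("cytosol", [])) >= 1
                    and len(chosen.get("mitochondria", [])) >= 2
                    and len(chosen.get("ER", [])) >= 1):
                host = chosen
                break
        if host is None:
            raise ValueError(
                "linker_motif needs a complex mix with >= 1 cytosol, "
                ">= 2 mitochondria and >= 1 ER member"
            )
        c = host["cytosol"][int(rng_motif.integers(len(host["cytosol"])))]
        m_idx = rng_motif.choice(len(host["mitochondria"]), size=2, replace=False)
        m1, m2 = (host["mitochondria"][i] for i in sorted(m_idx))
        e = host["ER"][int(rng_motif.integers(len(host["ER"])))]
        for er_node in host["ER"]:
            if g.has_edge(c, er_node):
                g.remove_edge(c, er_node)
        g.add_edges_from([(c, m1), (c, m2), (m1, e), (m2, e)])
        truth.planted_linker = c
        truth.motif = {"linker": c, "mito": (m1, m2), "er": e}

    for v, comp in primary.items():
        g.nodes[v]["compartment"] = comp
    return g, truth


def generate_expression(
    catalog: ProteinCatalog | Sequence[str],
    n_studies: int = 3,
    n_per_group: int | Sequence[tuple[int, int]] = 10,
    deg_fraction: float = 0.1,
    delta: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list, SyntheticTruth]:
    """Multi-study case/control expression with a shared planted DEG set.

    Gene baselines mu_g ~ Normal(8, 2) are drawn once and shared across
    studies; control samples are Normal(mu_g, noise_sd) and case samples
    Normal(mu_g + delta, noise_sd) for planted DEGs.  ``n_per_group`` is
    either one integer (both groups, all studies) or a per-study sequence
    of (n_case, n_control) pairs, so unbalanced designs at an arbitrary
    total sample count are expressible.
    """
    if not 0 <= deg_fraction <= 1:
        raise ValueError("deg_fraction must lie in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    genes = list(catalog.symbols) if isinstance(catalog, ProteinCatalog) else list(catalog)
    if isinstance(n_per_group, int):
        sizes = [(n_per_group, n_per_group)] * n_studies
    else:
        sizes = [tuple(x) for x in n_per_group]
        if len(sizes) != n_studies:
            raise ValueError("need one (n_case, n_control) pair per study")
    if any(nc < 2 or n0 < 2 for nc, n0 in sizes):
        raise ValueError("each group needs >= 2 samples")
    ss = np.random.SeedSequence(seed)
    rng_global, *study_children = ss.spawn(n_studies + 1)
    rng = np.random.default_rng(rng_global)
    mu = rng.normal(8.0, 2.0, size=len(genes))
    n_deg = int(round(deg_fraction * len(genes)))
    deg_idx = rng.choice(len(genes), size=n_deg, replace=False) if n_deg else []
    deg_set = frozenset(genes[i] for i in deg_idx)
    shift = np.zeros(len(genes))
    shift[list(deg_idx)] = delta

    studies = []
    for k, ((n_case, n_ctrl), child) in enumerate(zip(sizes, study_children)):
        srng = np.random.default_rng(child)
        sid = f"study{k + 1}"
        case = srng.normal(0.0, noise_sd, size=(len(genes), n_case)) + (mu + shift)[:, None]
        ctrl = srng.normal(0.0, noise_sd, size=(len(genes), n_ctrl)) + mu[:, None]
        cols = [f"{sid}_case_{i + 1}" for i in range(n_case)] + \
               [f"{sid}_ctrl_{i + 1}" for i in range(n_ctrl)]
        matrix = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=cols)
        groups = pd.Series(
            ["case"] * n_case + ["control"] * n_ctrl, index=cols
        )
        studies.append(ExpressionStudy(matrix, groups, sid))
    truth = SyntheticTruth(seed=seed, planted_deg_set=deg_set, delta=delta)
    return studies, truth


def generate_ct_table(
    group_names: Sequence[str],
    n_per_group: int,
    true_fold_changes: Mapping[str, float] | None = None,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    control_group: str = "control",
    reference_ct: float = 20.0,
    base_dct: float = 4.0,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table on the comparative-Ct model.

    The reference gene is constant in expectation across groups; the target
    gene of each group is shifted by -log2(fold) relative to the control
    group, so the comparative-Ct readout recovers the planted fold.  Noise
    is additive Gaussian on both Ct columns.
    """
    folds = dict(true_fold_changes or {})
    if control_group not in group_names:
        raise ValueError(f"control group {control_group!r} missing from group_names")
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for group in group_names:
        fold = folds.get(group, 1.0)
        for i in range(n_per_group):
            ref = reference_ct + rng.normal(0.0, ct_noise_sd)
            target = (reference_ct + base_dct - math.log2(fold)
                      + rng.normal(0.0, ct_noise_sd))
            rows.append({
                "sample": f"{group}_{i + 1}",
                "group": group,
                "ct_target": target,
                "ct_reference": ref,
            })
    return pd.DataFrame(rows, columns=["sample", "group", "ct_target", "ct_reference"])


def write_expression_tsv(studies: Sequence[ExpressionStudy], expr_path, meta_path) -> None:
    """Write studies as one genes x samples matrix plus sample metadata."""
    matrix = pd.concat([s.matrix for s in studies], axis=1)
    matrix.rename_axis("gene").to_csv(expr_path, sep="\t", float_format="%.6f")
    rows = []
    for s in studies:
        for sample in s.matrix.columns:
            rows.append({"sample": sample, "group": s.groups[sample], "study": s.study_id})
    pd.DataFrame(rows, columns=["sample", "group", "study"]).to_csv(
        meta_path, sep="\t", index=False
    )
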