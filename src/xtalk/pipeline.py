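"""End-to-end orchestration of the organelle cross-talk screen.

One config drives the whole chain: obtain data (simulate or load) ->
harmonize/annotate the catalog -> build the compartment-labeled graph ->
extract dense complexes -> meta differential expression -> nominate PD
clusters -> select the tri-compartment cluster and rank cytosolic linkers
-> (optionally) comparative-Ct validation statistics.  Every stage writes
its table under the output directory, a line-oriented report collects the
headline counts, and a manifest records the config, seeds and SHA-256 of
every output so a run can be reproduced bit-identically.  Outputs contain
no timestamps for exactly that reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures, synthetic_data
from .crosstalk_linker import (
    linkers_to_frame,
    score_cytosolic_linkers,
    select_tricompartment_cluster,
    write_linkers_tsv,
    write_witness_dot,
)
from .mcode_clustering import MCODEParams, find_complexes, top_k, write_complexes_tsv
from .meta_expression import (
    call_degs,
    combine_studies,
    differential_expression,
    map_degs_to_clusters,
    meta_to_tsv,
    pd_clusters,
    read_expression_tsv,
)
from .organelle_catalog import ProteinCatalog, assign_primary_compartment
from .ppi_network import build_graph, read_edge_table, write_edge_tsv
from .validation_stats import ct_report, read_ct_tsv

logger = logging.getLogger(__name__)

DEFAULTS = {
    "seed": 0,
    "policy": "source_majority",
    "min_confidence": None,
    "mcode": {},
    "top_k": 3,
    "alpha": 0.05,
    "adjust": "none",
    "min_hits": 1,
    "control_group": "control",
    "max_witness_paths": 10,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    out = {**DEFAULTS, **cfg}
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
    if "outdir" not in out:
        raise ValueError("config must name an 'outdir'")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _acquire_data(cfg: dict):
    """Return (catalog, graph_or_edge_table, studies, ct_table)."""
    if "simulate" in cfg:
        sim = cfg["simulate"] or {}
        seed = int(cfg["seed"])
        if sim.get("preset") == "reference_screen":
            bundle = fixtures.reference_screen_fixture(seed)
            if not cfg.get("mcode"):
                cfg["mcode"] = {"fluff": True}
            cfg["control_group"] = bundle.control_group
            return bundle.catalog, bundle.graph, bundle.studies, bundle.ct_table, bundle.truth
        cat_kw = dict(sim.get("catalog") or {})
        catalog = synthetic_data.generate_catalog(seed=seed, **cat_kw)
        net_kw = dict(sim.get("network") or {})
        specs = [synthetic_data.ComplexSpec(**s) for s in net_kw.pop("complexes", [])]
        graph, truth = synthetic_data.generate_network(
            catalog, specs, seed=seed, **net_kw
        )
        studies = None
        if "expression" in sim:
            studies, expr_truth = synthetic_data.generate_expression(
                catalog, seed=seed, **dict(sim["expression"])
            )
            truth.planted_deg_set = expr_truth.planted_deg_set
            truth.delta = expr_truth.delta
        ct = None
        if "ct" in sim:
            ct = synthetic_data.generate_ct_table(seed=seed, **dict(sim["ct"]))
        return catalog, graph, studies, ct, truth
    inputs = cfg["inputs"]
    catalog = ProteinCatalog.from_tsv(inputs["catalog"])
    edge_table = read_edge_table(inputs["edges"])
    studies = None
    if "expression" in inputs:
        studies = read_expression_tsv(inputs["expression"], inputs["metadata"])
    ct = read_ct_tsv(inputs["ct"]) if "ct" in inputs else None
    return catalog, edge_table, studies, ct, None


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Execute the full screen; returns a result dict and writes all outputs.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs written before the failure are retained.
    """
    cfg = validate_config(cfg)
    outdir = Path(outdir if outdir is not None else cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: list[str] = []
    outputs: list[Path] = []
    result: dict = {"outdir": str(outdir)}

    def emit(line: str) -> None:
        logger.info(line)
        report.append(line)

    def save(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs.append(path)
        return path

    stage = "acquire"
    try:
        catalog, graph_or_edges, studies, ct_table, truth = _acquire_data(cfg)

        stage = "annotate"
        catalog = assign_primary_compartment(catalog, policy=cfg["policy"])
        save("catalog.tsv", catalog.to_tsv)
        from .organelle_catalog import compartment_counts

        counts = compartment_counts(catalog)
        emit(f"[annotate] {len(catalog)} proteins "
             f"({counts['mitochondria']} mito / {counts['cytosol']} cytosol / "
             f"{counts['ER']} ER), policy={cfg['policy']}")

        stage = "build-net"
        if isinstance(graph_or_edges, pd.DataFrame):
            graph = build_graph(graph_or_edges, catalog,
                                min_confidence=cfg["min_confidence"])
        else:
            graph = graph_or_edges
        result["graph"] = graph
        n_nonisolated = sum(1 for v in graph.nodes if graph.degree(v) > 0)
        save("edges.tsv", lambda p: write_edge_tsv(graph, p))
        emit(f"[network] {n_nonisolated} nodes / {graph.number_of_edges()} edges "
             f"({graph.number_of_nodes() - n_nonisolated} isolated proteins)")

        stage = "cluster"
        params = MCODEParams(**(cfg["mcode"] or {}))
        complexes = find_complexes(graph, params)
        top = top_k(complexes, cfg["top_k"]) if complexes else []
        save("complexes.tsv", lambda p: write_complexes_tsv(complexes, p))
        for c in top:
            emit(f"[cluster] rank {c.rank}: {c.size} members / {c.edge_count} edges "
                 f"(score {c.score:.3f}, seed {c.seed})")
        result["top_clusters"] = top

        degs: set = set()
        if studies:
            stage = "meta-de"
            per_study = {s.study_id: differential_expression(s) for s in studies}
            meta = combine_studies(per_study, alpha=cfg["alpha"])
            degs = call_degs(meta, alpha=cfg["alpha"], adjust=cfg["adjust"])
            save("meta_de.tsv", lambda p: meta_to_tsv(meta, p))
            emit(f"[meta-de] {len(studies)} studies, {len(meta)} genes, "
                 f"{len(degs)} DEGs at alpha {cfg['alpha']} (adjust={cfg['adjust']})")
            result["n_degs"] = len(degs)
        else:
            emit("[meta-de] skipped: no expression data")

        stage = "map-degs"
        mapped = map_degs_to_clusters(top, degs, min_hits=cfg["min_hits"])
        pd_list = pd_clusters(mapped)
        emit(f"[map] PD clusters: ranks {[c.rank for c in pd_list]} "
             f"(min_hits={cfg['min_hits']})")
        result["pd_clusters"] = pd_list

        stage = "linker"
        if pd_list:
            selected, composition = select_tricompartment_cluster(pd_list, catalog)
        else:
            selected, composition = None, {"reason": "no PD clusters"}
        if selected is None:
            emit(f"[linker] skipped: {composition.get('reason')}")
            linkers = []
        else:
            emit(f"[linker] selected cluster rank {selected.rank}: {selected.size} "
                 f"members ({composition['mitochondria']} mito / "
                 f"{composition['cytosol']} cytosol / {composition['ER']} ER)")
            sub = selected.subgraph(graph)
            linkers = score_cytosolic_linkers(sub)
            save("linkers.tsv", lambda p: write_linkers_tsv(linkers, p))
            save("witness.dot", lambda p: write_witness_dot(
                sub, linkers, p, cfg["max_witness_paths"]))
            for l in linkers[:3]:
                emit(f"[linker] rank {l.rank}: {l.node} bridge_length="
                     f"{l.bridge_length} n_paths={l.n_paths} "
                     f"witness={'>'.join(l.witness_er)}|{'>'.join(l.witness_mito)}")
        result["selected_cluster"] = selected
        result["composition"] = composition
        result["linkers"] = linkers

        if ct_table is not None:
            stage = "ddct"
            validation = ct_report(ct_table, cfg["control_group"], cfg["alpha"])
            save("ddct_per_sample.tsv", lambda p: validation["per_sample"].to_csv(
                p, sep="\t", index=False, float_format="%.6g"))
            save("ddct_per_group.tsv", lambda p: validation["per_group"].to_csv(
                p, sep="\t", index=False, float_format="%.6g"))
            save("tukey.tsv", lambda p: validation["tukey"].to_csv(
                p, sep="\t", index=False, float_format="%.6g"))
            for row in validation["per_group"].itertuples(index=False):
                emit(f"[ddct] group {row.group}: mean fold {row.mean_fold:.3f} "
                     f"(SD {row.sd_fold:.3f}, n={row.n})")
            a = validation["anova"]
            emit(f"[anova] F={a['F']:.4g} df=({a['df_between']},{a['df_within']}) "
                 f"p={a['p']:.4g}")
            for row in validation["tukey"].itertuples(index=False):
                emit(f"[tukey] {row.group_a} vs {row.group_b}: p_adj={row.p_adj:.4g}"
                     f"{' *' if row.significant else ''}")
            result["validation"] = validation
        else:
            emit("[ddct] skipped: no Ct table")
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - error path
        raise PipelineError(stage, str(exc)) from exc

    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(report) + "\n")
    outputs.append(report_path)
    manifest = {
        "config": _jsonable(cfg),
        "seed": cfg["seed"],
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    result["report"] = report
    result["truth"] = truth
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
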