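"""End-to-end orchestration: ingest/simulate -> preprocess -> outlier QC ->
differential expression -> meta-integration -> core-network extraction.

A single YAML config drives the run.  Test datasets feed the per-class
DEG intersections and the core-gene selection; validation datasets feed
the final-DEG filter and the direction table.  Every stage writes its
artifacts to the output directory and the run closes with a manifest of
content hashes, so a re-run with identical inputs is verifiably
byte-identical (timestamps live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import diffexpr, io as dio, meta, network as net, outliers, preprocess
from . import simulate as sim

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "max_absent": 2,
    "absent_mode": "all_groups",
    "outlier_threshold": -2.0,
    "outlier_convention": "correlation",
    "outlier_iterations": 1,
    "lfc_cut": 0.5,
    "alpha": 0.05,
    "report_cut": 0.2,
    "presence_cut": 0.2,
    "allow_one_discordant": False,
    "sp_mode": "complete",
}


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None
    datasets: list[dict] = dataclasses.field(default_factory=list)
    sample_sheet: str | None = None
    network: dict = dataclasses.field(default_factory=dict)
    core_genes: str | None = None
    thresholds: dict = dataclasses.field(default_factory=dict)
    restrict_network_to_final: bool = True
    plots: bool = False  # PCA scatter + dendrogram per dataset; never load-bearing

    def threshold(self, name: str):
        return self.thresholds.get(name, DEFAULT_THRESHOLDS[name])


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "outdir" not in raw:
        raise ValueError("config must set 'outdir'")
    return PipelineConfig(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations; empty means the config is runnable."""
    problems: list[str] = []
    thr = {**DEFAULT_THRESHOLDS, **config.thresholds}
    for key in config.thresholds:
        if key not in DEFAULT_THRESHOLDS:
            problems.append(f"unknown threshold {key!r}")
    if not 0 < thr["alpha"] < 1:
        problems.append(f"alpha must be in (0, 1), got {thr['alpha']}")
    for key in ("lfc_cut", "report_cut", "presence_cut"):
        if thr[key] < 0:
            problems.append(f"{key} must be non-negative, got {thr[key]}")
    if thr["absent_mode"] not in ("all_groups", "any_group"):
        problems.append(f"invalid absent_mode {thr['absent_mode']!r}")
    if thr["outlier_convention"] not in ("correlation", "distance"):
        problems.append(f"invalid outlier_convention {thr['outlier_convention']!r}")
    if thr["sp_mode"] not in ("complete", "edges_only"):
        problems.append(f"invalid sp_mode {thr['sp_mode']!r}")
    if config.simulate is None:
        if not config.datasets:
            problems.append("no datasets configured and no simulate block")
        if not any(d.get("role") == "test" for d in config.datasets):
            problems.append("at least one dataset must have role 'test'")
        for entry in config.datasets:
            for key in ("expression", "calls", "probe_map"):
                p = entry.get(key)
                if p and not Path(p).exists():
                    problems.append(f"dataset {entry.get('id', '?')}: "
                                    f"missing file {p}")
            if entry.get("role") not in ("test", "validation"):
                problems.append(f"dataset {entry.get('id', '?')}: role must be "
                                "test or validation")
        if config.sample_sheet and not Path(config.sample_sheet).exists():
            problems.append(f"missing sample sheet {config.sample_sheet}")
        edges = config.network.get("edges")
        if not edges:
            problems.append("network.edges path is required without simulation")
        elif not Path(edges).exists():
            problems.append(f"missing network edge list {edges}")
    if config.core_genes and not Path(config.core_genes).exists():
        problems.append(f"missing core gene file {config.core_genes}")
    return problems


def _qc_plots(expr: pd.DataFrame, sheet: pd.DataFrame, name: str,
              plot_dir: Path) -> None:
    """PCA scatter and correlation-distance dendrogram for one dataset."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    plot_dir.mkdir(parents=True, exist_ok=True)
    coords, evr = outliers.pca_embedding(expr)
    fig, ax = plt.subplots(figsize=(5, 4))
    group_of = dict(zip(sheet["sample"], sheet["group"]))
    colors = {"normal": "tab:green", "primary": "tab:blue",
              "metastatic": "tab:red"}
    for sample in coords.index:
        g = group_of.get(sample, "normal")
        ax.scatter(coords.loc[sample, "PC1"], coords.loc[sample, "PC2"],
                   color=colors[g], label=g, s=18)
        ax.annotate(sample, coords.loc[sample], fontsize=5)
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), fontsize=7)
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    fig.tight_layout()
    fig.savefig(plot_dir / f"{name}_pca.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3.5))
    linkage = outliers.dendrogram_linkage(expr)
    dendrogram(linkage, labels=list(expr.columns), ax=ax, leaf_font_size=6)
    ax.set_ylabel("1 - r (average linkage)")
    fig.tight_layout()
    fig.savefig(plot_dir / f"{name}_dendrogram.png", dpi=120)
    plt.close(fig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulation_config(block: dict, seed: int) -> sim.SimulationConfig:
    block = dict(block or {})
    ppi = sim.PPISpec(**block.pop("ppi", {}))
    for key in ("group_sizes", "probe_multiplicity"):
        if key in block:
            block[key] = tuple(tuple(x) if isinstance(x, list) else x
                               for x in block[key]) if key == "probe_multiplicity" \
                else tuple(block[key])
    return sim.SimulationConfig(seed=seed, ppi=ppi, **block)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain; returns the run manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    warnings_log: list[str] = []

    # ------------------------------------------------------------------ ingest
    if config.simulate is not None:
        sim_cfg = _simulation_config(config.simulate, config.seed)
        study = sim.simulate_expression_study(sim_cfg)
        # PPI wired to the study's gene universe: cores from the MvsP block,
        # proximal neighbors from the other planted blocks
        planted = study.truth.planted_degs
        mvsp = sorted(planted["MvsP"])
        others = sorted(set(planted["MvsN"]) | set(planted["PvsN"]))
        spec = sim_cfg.ppi
        core_names = mvsp[:spec.n_core]
        pool = core_names + others
        non_network = [g for g in study.truth.group_offsets.index
                       if g not in set(pool)]
        node_names = (pool + non_network)[:spec.n_nodes]
        edges, ppi_truth = sim.simulate_ppi(sim_cfg, node_names=node_names,
                                            core_names=core_names)
        study.truth.core_nodes = ppi_truth.core_nodes
        study.truth.planted_proximal_nodes = ppi_truth.planted_proximal_nodes
        input_dir = outdir / "inputs"
        sim.write_study(study, input_dir)
        dio.write_string_edgelist(edges, input_dir / "ppi_edges.tsv",
                                  score_scale="milli")
        sim.write_ground_truth(study.truth, outdir / "ground_truth")
        datasets = [{"id": ds.name, "role": ds.role, "kind": ds.kind,
                     "_data": ds} for ds in study.datasets]
        sheet = study.sample_sheet
        edge_table = dio.read_string_edgelist(input_dir / "ppi_edges.tsv",
                                              score_scale="milli")
    else:
        datasets = [dict(d) for d in config.datasets]
        for entry in datasets:
            expr = dio.read_expression_tsv(entry["expression"])
            calls = (dio.read_calls_tsv(entry["calls"], expr)
                     if entry.get("calls") else None)
            pmap = (dio.read_probe_map(entry["probe_map"])
                    if entry.get("probe_map") else None)
            entry["_data"] = sim.SimulatedDataset(
                entry["id"], entry["role"],
                entry.get("kind", "precomputed"), expr, calls, pmap)
        sheet_path = config.sample_sheet or (
            Path(config.datasets[0]["expression"]).parent / "sample_sheet.tsv")
        sheet = dio.read_sample_sheet(sheet_path)
        edge_table = dio.read_string_edgelist(
            config.network["edges"],
            score_scale=config.network.get("score_scale", "milli"))

    # -------------------------------------------------- per-dataset processing
    analyses: list[meta.AnalysisResult] = []
    stage_counts: dict[str, dict] = {}
    for entry in datasets:
        ds = entry["_data"]
        ds_sheet = sheet[sheet["dataset"] == ds.name]
        counts: dict[str, object] = {"role": ds.role, "kind": ds.kind}
        expr = ds.expression
        if ds.kind == "microarray":
            expr, rep = preprocess.filter_absent(
                expr, ds.calls, ds_sheet,
                max_absent=config.threshold("max_absent"),
                mode=config.threshold("absent_mode"))
            counts["absent_removed"] = rep.features_removed
            expr = preprocess.quantile_normalize(expr)
            expr, rep = preprocess.filter_low_variance(expr)
            counts["low_variance_removed"] = rep.features_removed
            expr, rep = preprocess.collapse_probes(expr, ds.probe_map)
            counts["genes_after_collapse"] = len(expr)
        else:
            expr = preprocess.prepare_precomputed(
                expr, already_log2=entry.get("already_log2", True))
            counts["genes_after_zero_filter"] = len(expr)
        if config.plots:
            _qc_plots(expr, ds_sheet, ds.name, outdir / "plots")
        expr, ds_sheet, reports = outliers.remove_outliers(
            expr, ds_sheet,
            max_iterations=config.threshold("outlier_iterations"),
            threshold=config.threshold("outlier_threshold"),
            convention=config.threshold("outlier_convention"))
        removed = sorted(set().union(*(r.flagged for r in reports))
                         if reports else set())
        counts["outliers_removed"] = removed
        outlier_frames = [r.to_frame() for r in reports]
        if outlier_frames:
            pd.concat(outlier_frames).to_csv(
                outdir / f"{ds.name}_outlier_report.tsv", sep="\t",
                float_format="%.17g")
        groups = set(ds_sheet["group"])
        for label, (num, den) in dio.COMPARISON_CLASSES.items():
            if {num, den} <= groups:
                spec_ = diffexpr.ComparisonSpec(num, den, label, ds.name)
                result = diffexpr.moderated_t_test(
                    expr, ds_sheet, spec_,
                    lfc_cut=config.threshold("lfc_cut"),
                    alpha=config.threshold("alpha"))
                result.to_csv(outdir / f"{ds.name}_{label}_de.tsv", sep="\t",
                              float_format="%.17g")
                analyses.append(meta.AnalysisResult(ds.name, label, result))
                counts[f"degs_{label}"] = int((result["call"] != "NotDE").sum())
        stage_counts[ds.name] = counts
        logger.info("dataset %s: %s", ds.name, counts)

    # ------------------------------------------------------- meta-integration
    roles = {entry["id"]: entry["role"] for entry in datasets}
    test_analyses = [a for a in analyses if roles[a.dataset] == "test"]
    val_analyses = [a for a in analyses if roles[a.dataset] == "validation"]
    lfc_cut, alpha = config.threshold("lfc_cut"), config.threshold("alpha")
    class_intersections: dict[str, dict[str, str]] = {}
    for label in dio.COMPARISON_CLASSES:
        sets = [diffexpr.select_degs(a.result, lfc_cut, alpha)
                for a in test_analyses if a.label == label]
        if sets:
            class_intersections[label] = meta.intersect_class(sets)
            dio.write_gene_set(sorted(class_intersections[label]),
                               outdir / f"common_degs_{label}.txt")
    final = meta.final_deg_set(
        class_intersections, val_analyses,
        presence_cut=config.threshold("presence_cut"),
        allow_one_discordant=config.threshold("allow_one_discordant"))
    dio.write_gene_set(sorted(final), outdir / "final_degs.txt")
    user_core = (dio.read_gene_set(config.core_genes)
                 if config.core_genes else None)
    core = meta.select_core_genes(class_intersections, final, user_core)
    dio.write_gene_set(sorted(core), outdir / "core_genes.txt")
    table = meta.direction_table(
        analyses, sorted(final), report_cut=config.threshold("report_cut"))
    meta.concordance_report(table).to_csv(outdir / "direction_table.tsv",
                                          sep="\t")
    logger.info("meta: %s; final=%d core=%d",
                {k: len(v) for k, v in class_intersections.items()},
                len(final), len(core))

    # ------------------------------------------------------------ core network
    if config.restrict_network_to_final:
        keep = final | core
        edge_table = edge_table[edge_table["node_a"].isin(keep)
                                & edge_table["node_b"].isin(keep)]
    graph = net.build_graph(edge_table)
    gc = net.giant_component(graph)
    dio.write_graph(gc, outdir / "giant_component.graphml")
    tom = net.tom_similarity(gc)
    sp = net.shortest_path_matrix(net.tom_distance(tom),
                                  mode=config.threshold("sp_mode"), graph=gc)
    core_in_graph = core & set(gc.nodes)
    if not core_in_graph:
        raise RuntimeError("no core gene appears in the network giant component")
    scores = net.dj_scores(sp, core_in_graph)
    dio.write_score_table(scores, outdir / "dj_scores.tsv")
    core_net = net.extract_core_network(gc, scores)
    dio.write_graph(core_net, outdir / "core_network.graphml")
    dio.write_graph(core_net, outdir / "core_network_edges.tsv", format="tsv")
    desc = net.network_descriptives(gc)
    node_stats = desc.pop("node_stats")
    node_stats.to_csv(outdir / "node_stats.tsv", sep="\t",
                      float_format="%.17g")
    desc["core_network_nodes"] = core_net.number_of_nodes()
    desc["core_network_edges"] = core_net.number_of_edges()
    desc["core_network_components"] = (
        nx.number_connected_components(core_net)
        if core_net.number_of_nodes() else 0)
    with open(outdir / "network_descriptives.json", "w", encoding="utf-8") as fh:
        json.dump(desc, fh, indent=2, sort_keys=True)
    logger.info("network: giant %d/%d, core network %d nodes",
                gc.number_of_nodes(), graph.number_of_nodes(),
                core_net.number_of_nodes())

    # ---------------------------------------------------------------- manifest
    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "stage_counts": stage_counts,
        "class_intersections": {k: len(v) for k, v in class_intersections.items()},
        "final_degs": len(final),
        "core_genes": sorted(core),
        "network": desc,
        "elapsed_seconds": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "warnings": warnings_log,
        "outputs": {},
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
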