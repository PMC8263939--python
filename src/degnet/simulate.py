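"""Synthetic multi-dataset expression studies and PPI networks with ground truth.

The generator emulates the structure of a multi-cohort cancer-progression
meta-analysis so every downstream stage has a recoverable planted signal:

* several *test* and *validation* datasets, each with normal / primary /
  metastatic sample groups on the log2 intensity scale;
* three disjoint blocks of planted DEGs, one designated per comparison
  class (MvsN, PvsN, MvsP), shifting group means by exactly
  ``+-effect_size`` in the designated class consistently across
  datasets; a configurable fraction of the MvsN block follows a
  monotone normal < primary < metastatic trend;
* planted outlier samples built as a convex mixture of the sample's
  clean profile with an independent random profile (the outlier
  statistic downstream is correlation-based, so decorrelation - not a
  mean shift - is the right corruption model);
* probe-level test datasets with many-to-one and one-to-many
  probe/gene mappings plus present/absent detection calls enriched in
  low-intensity cells; validation datasets are emitted gene-level
  (RNA-seq style);
* a weighted PPI edge list containing a planted high-weight clique
  (cores plus proximal neighbors) over an Erdos-Renyi background.

Ground truth is returned (and written) separately from the simulated
measurements; pipeline stages never see it.  Every output is a pure
function of the master seed: each dataset draws from its own RNG stream
derived from the seed by fixed offsets, so adding datasets does not
perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as dio

GROUPS = ("normal", "primary", "metastatic")


@dataclass(frozen=True)
class PPISpec:
    """Planted-module PPI generator settings.

    ``module_size`` counts the *proximal non-core* members: the planted
    clique has ``n_core + module_size`` nodes.  Defaults echo the scale
    of a STRING subnetwork around a small core set (a ~200-node giant
    component, 12 cores, 27 proximal neighbors, density a few percent).
    """

    n_nodes: int = 205
    n_core: int = 12
    module_size: int = 27
    within_weight: tuple[float, float] = (0.7, 0.95)
    p_background: float = 0.026
    background_weight: tuple[float, float] = (0.15, 0.4)
    #: module<->background coupling probability as a fraction of
    #: p_background (planted-partition style: between-community edges an
    #: order of magnitude rarer than within-community ones)
    coupling_factor: float = 0.2

    def validate(self) -> None:
        if self.n_core < 1:
            raise ValueError("need at least one core node")
        if self.n_core + self.module_size > self.n_nodes:
            raise ValueError("planted module larger than the network")
        if not 0 <= self.p_background <= 1:
            raise ValueError("background edge probability must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Group sizes, noise level, effect size and DEG fraction default to a
    desk-scale version of a three-test / two-validation colorectal
    progression design: 2000 genes, 15 samples per group, log2 effect
    size 1 at within-group SD 0.5, 5% planted DEGs per class, one
    planted outlier per dataset at decorrelation strength 0.9.
    """

    n_genes: int = 2000
    group_sizes: tuple[int, int, int] = (15, 15, 15)  # normal, primary, metastatic
    n_datasets_test: int = 3
    n_datasets_validation: int = 2
    de_fraction: float = 0.05
    effect_size: float = 1.0
    noise_sd: float = 0.5
    monotone_fraction: float = 0.5
    discordant_fraction: float = 0.0
    outlier_count: int = 1
    outlier_strength: float = 0.9
    probe_multiplicity: tuple[tuple[int, float], ...] = ((1, 0.6), (2, 0.3), (3, 0.1))
    shared_probe_rate: float = 0.02
    absent_rate: float = 0.1
    ppi: PPISpec = field(default_factory=PPISpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_datasets_test < 1:
            raise ValueError("counts must be positive")
        if min(self.group_sizes) < 3:
            raise ValueError("group sizes below 3 leave downstream variance "
                             "estimates undefined")
        for name in ("de_fraction", "monotone_fraction", "discordant_fraction",
                     "absent_rate", "shared_probe_rate", "outlier_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if 3 * round(self.de_fraction * self.n_genes) > self.n_genes:
            raise ValueError("de_fraction too large for three disjoint blocks")
        self.ppi.validate()


@dataclass
class GroundTruth:
    """Planted signal: what a perfect analysis should recover."""

    planted_degs: dict[str, dict[str, str]]  # class -> {gene: Up/Down}
    planted_outliers: set[str]
    core_nodes: set[str] = field(default_factory=set)
    planted_proximal_nodes: set[str] = field(default_factory=set)
    discordant_genes: dict[str, str] = field(default_factory=dict)  # gene -> dataset
    group_offsets: pd.DataFrame | None = None  # gene x group true mean offsets


@dataclass
class SimulatedDataset:
    """One cohort: expression (+ calls / probe map for microarray kind)."""

    name: str
    role: str  # test / validation
    kind: str  # microarray (probe-level) / precomputed (gene-level log2)
    expression: pd.DataFrame
    calls: pd.DataFrame | None = None
    probe_map: pd.DataFrame | None = None


@dataclass
class SimulatedStudy:
    datasets: list[SimulatedDataset]
    sample_sheet: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def _plant_truth(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene-level baseline and per-group mean offsets plus the DEG map."""
    rng = _rng(config.seed, 0)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    # skewed baseline on the log2 scale (microarray-like intensity shape)
    baseline = 3.0 + rng.gamma(shape=4.0, scale=1.0, size=config.n_genes)
    offsets = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"),
                           columns=list(GROUPS))
    n_de = round(config.de_fraction * config.n_genes)
    order = rng.permutation(config.n_genes)
    blocks = {"PvsN": order[:n_de],
              "MvsP": order[n_de:2 * n_de],
              "MvsN": order[2 * n_de:3 * n_de]}
    delta = config.effect_size
    planted: dict[str, dict[str, str]] = {c: {} for c in ("MvsN", "PvsN", "MvsP")}
    for label, idx in blocks.items():
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        for gi, s in zip(idx, signs):
            gene = genes[gi]
            if label == "PvsN":
                offsets.loc[gene, ["primary", "metastatic"]] = s * delta
            elif label == "MvsP":
                offsets.loc[gene, "metastatic"] = s * delta
            else:  # MvsN block; monotone subset gets the intermediate step
                offsets.loc[gene, "metastatic"] = s * delta
                offsets.loc[gene, "primary"] = s * delta / 2.0
            planted[label][gene] = "Up" if s > 0 else "Down"
    # non-monotone remainder of the MvsN block collapses the intermediate step
    mvsn_genes = [genes[gi] for gi in blocks["MvsN"]]
    n_mono = round(config.monotone_fraction * len(mvsn_genes))
    for gene in mvsn_genes[n_mono:]:
        offsets.loc[gene, "primary"] = 0.0
    # discordant genes: direction flipped in one (test) dataset
    discordant: dict[str, str] = {}
    n_disc = round(config.discordant_fraction * len(mvsn_genes))
    for gene in mvsn_genes[:n_disc]:
        k = int(rng.integers(config.n_datasets_test))
        discordant[gene] = f"T{k + 1}"
    truth = GroundTruth(planted_degs=planted, planted_outliers=set(),
                        discordant_genes=discordant, group_offsets=offsets)
    base = pd.Series(baseline, index=offsets.index, name="baseline")
    return pd.concat([base, offsets], axis=1), truth


def _dataset_names(config: SimulationConfig) -> list[tuple[str, str]]:
    names = [(f"T{i + 1}", "test") for i in range(config.n_datasets_test)]
    names += [(f"V{i + 1}", "validation")
              for i in range(config.n_datasets_validation)]
    return names


def _probe_layer(
    gene_expr: pd.DataFrame, config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a gene-level matrix to probes with a many-to-many map."""
    mult, probs = zip(*config.probe_multiplicity)
    counts = rng.choice(mult, size=len(gene_expr), p=probs)
    rows, probe_ids, map_rows = [], [], []
    pnum = 0
    genes = list(gene_expr.index)
    for gene, n_probes in zip(genes, counts):
        for _ in range(int(n_probes)):
            pid = f"{pnum + 200000:06d}_at"
            pnum += 1
            affinity = rng.normal(0.0, 0.5)
            noise = rng.normal(0.0, 0.3 * config.noise_sd,
                               size=gene_expr.shape[1])
            rows.append(gene_expr.loc[gene].to_numpy() + affinity + noise)
            probe_ids.append(pid)
            map_rows.append((pid, gene))
            if rng.random() < config.shared_probe_rate:
                other = genes[int(rng.integers(len(genes)))]
                if other != gene:  # one probe -> two genes
                    map_rows.append((pid, other))
    probes = pd.DataFrame(np.vstack(rows),
                          index=pd.Index(probe_ids, name="feature"),
                          columns=gene_expr.columns)
    pmap = pd.DataFrame(map_rows, columns=["probe", "gene"])
    return probes, pmap


def _detection_calls(
    expr: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """P/A calls at ``absent_rate`` on average, enriched at low intensity."""
    values = expr.to_numpy(float)
    u = values.argsort(axis=None).argsort(axis=None) / max(values.size - 1, 1)
    p_absent = np.clip(2.0 * config.absent_rate * (1.0 - u), 0.0, 1.0)
    absent = rng.random(values.size) < p_absent
    calls = np.where(absent.reshape(values.shape), "A", "P")
    return pd.DataFrame(calls, index=expr.index, columns=expr.columns)


def simulate_expression_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the multi-dataset expression study defined by ``config``."""
    config.validate()
    truth_table, truth = _plant_truth(config)
    baseline = truth_table["baseline"]
    offsets = truth_table[list(GROUPS)]
    datasets: list[SimulatedDataset] = []
    sheet_rows: list[tuple[str, str, str]] = []
    for k, (name, role) in enumerate(_dataset_names(config)):
        rng = _rng(config.seed, 100 + k)
        sample_ids, group_of = [], {}
        for group, size in zip(GROUPS, config.group_sizes):
            for i in range(size):
                sid = f"{name}_{group[0].upper()}{i + 1:02d}"
                sample_ids.append(sid)
                group_of[sid] = group
                sheet_rows.append((sid, name, group))
        means = np.column_stack([
            baseline.to_numpy() + _signed_offsets(offsets, group_of[s], name, truth)
            for s in sample_ids])
        clean_means = pd.DataFrame(means, index=offsets.index, columns=sample_ids)
        # planted outliers: convex mixture of the clean mean profile with an
        # independent random profile at the decorrelation strength
        outlier_ids = list(rng.choice(sample_ids, size=config.outlier_count,
                                      replace=False))
        lam = config.outlier_strength
        for sid in outlier_ids:
            indep = rng.normal(baseline.mean(), baseline.std(),
                               size=len(baseline))
            clean_means[sid] = (1 - lam) * clean_means[sid] + lam * indep
            truth.planted_outliers.add(sid)
        noisy = clean_means + rng.normal(0.0, config.noise_sd, clean_means.shape)
        if role == "test":
            probes, pmap = _probe_layer(noisy, config, rng)
            calls = _detection_calls(probes, config, rng)
            datasets.append(SimulatedDataset(name, role, "microarray",
                                             probes, calls, pmap))
        else:
            datasets.append(SimulatedDataset(name, role, "precomputed", noisy))
    sheet = pd.DataFrame(sheet_rows, columns=["sample", "dataset", "group"])
    return SimulatedStudy(datasets=datasets, sample_sheet=sheet,
                          truth=truth, config=config)


def _signed_offsets(offsets: pd.DataFrame, group: str, dataset: str,
                    truth: GroundTruth) -> np.ndarray:
    """Per-gene group offsets, with discordant genes flipped in their dataset."""
    out = offsets[group].to_numpy().copy()
    for gene, flipped_in in truth.discordant_genes.items():
        if flipped_in == dataset:
            gi = offsets.index.get_loc(gene)
            out[gi] = -out[gi]
    return out


def simulate_ppi(
    config: SimulationConfig,
    node_names: list[str] | None = None,
    core_names: list[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Weighted PPI edge list with a planted core-proximal module.

    The planted module is a clique of ``n_core + module_size`` nodes
    with weights drawn from ``within_weight`` (connectivity guaranteed);
    the background is an Erdos-Renyi layer at ``p_background`` *among
    background nodes* with weights from ``background_weight``, and the
    module couples to the background through a sparser inter-community
    layer at ``coupling_factor * p_background`` (planted-partition
    design: the module's crosstalk with the rest of the network is an
    order of magnitude weaker than the background's own wiring, so
    core proximity remains a property of the module rather than of
    global centrality).  Custom node/core names allow wiring the
    network to genes from an expression study.
    """
    spec = config.ppi
    spec.validate()
    rng = _rng(config.seed, 999)
    if node_names is None:
        node_names = [f"N{i:04d}" for i in range(spec.n_nodes)]
    if len(set(node_names)) != spec.n_nodes:
        raise ValueError(f"need {spec.n_nodes} unique node names")
    if core_names is None:
        module = list(node_names[:spec.n_core + spec.module_size])
        core = module[:spec.n_core]
    else:
        core = list(core_names)
        if len(core) != spec.n_core:
            raise ValueError("core_names length must equal ppi.n_core")
        rest = [n for n in node_names if n not in set(core)]
        module = core + rest[:spec.module_size]
    proximal = [n for n in module if n not in set(core)]
    in_module = set(module)
    rows: list[tuple[str, str, float]] = []
    for i, u in enumerate(module):
        for v in module[i + 1:]:
            w = rng.uniform(*spec.within_weight)
            rows.append((min(u, v), max(u, v), w))
    seen = {(r[0], r[1]) for r in rows}
    p_coupling = spec.coupling_factor * spec.p_background
    for i, u in enumerate(node_names):
        for v in node_names[i + 1:]:
            if u in in_module and v in in_module:
                continue
            p = p_coupling if (u in in_module or v in in_module) else spec.p_background
            if rng.random() < p:
                key = (min(u, v), max(u, v))
                if key not in seen:
                    seen.add(key)
                    rows.append((*key, rng.uniform(*spec.background_weight)))
    # guarantee the planted module sits inside the giant component (the
    # analysis chain works on the giant component, so a module stranded in
    # a smaller component would be unrecoverable by construction): bridge
    # the module's component to the largest one with single weak edges
    # until it dominates
    graph = nx.Graph()
    graph.add_nodes_from(node_names)
    graph.add_edges_from((a, b) for a, b, _ in rows)
    while True:
        components = sorted(nx.connected_components(graph),
                            key=lambda c: (-len(c), min(c)))
        if core[0] in components[0]:
            break
        largest = components[0]
        u = min(module)
        v = min(largest)
        rows.append((min(u, v), max(u, v),
                     rng.uniform(*spec.background_weight)))
        graph.add_edge(u, v)
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    truth = GroundTruth(planted_degs={}, planted_outliers=set(),
                        core_nodes=set(core),
                        planted_proximal_nodes=set(proximal))
    return edges, truth


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, outdir) -> dict[str, dict]:
    """Write all study inputs as TSV; returns a manifest of paths per dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for ds in study.datasets:
        entry = {"role": ds.role, "kind": ds.kind}
        p = outdir / f"{ds.name}_expression.tsv"
        dio.write_expression_tsv(ds.expression, p)
        entry["expression"] = str(p)
        if ds.calls is not None:
            p = outdir / f"{ds.name}_calls.tsv"
            dio.write_calls_tsv(ds.calls, p)
            entry["calls"] = str(p)
        if ds.probe_map is not None:
            p = outdir / f"{ds.name}_probe_map.tsv"
            dio.write_probe_map(ds.probe_map, p)
            entry["probe_map"] = str(p)
        manifest[ds.name] = entry
    dio.write_sample_sheet(study.sample_sheet, outdir / "sample_sheet.tsv")
    return manifest


def write_ground_truth(truth: GroundTruth, outdir) -> None:
    """Write the planted signal as separate TSV files (never pipeline input)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [(label, gene, direction)
            for label, degs in truth.planted_degs.items()
            for gene, direction in sorted(degs.items())]
    pd.DataFrame(rows, columns=["class", "gene", "direction"]).to_csv(
        outdir / "planted_degs.tsv", sep="\t", index=False)
    dio.write_gene_set(sorted(truth.planted_outliers),
                       outdir / "planted_outliers.txt")
    dio.write_gene_set(sorted(truth.core_nodes), outdir / "core_nodes.txt")
    dio.write_gene_set(sorted(truth.planted_proximal_nodes),
                       outdir / "planted_proximal_nodes.txt")
    if truth.group_offsets is not None:
        truth.group_offsets.to_csv(outdir / "group_offsets.tsv", sep="\t")
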