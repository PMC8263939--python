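"""Weighted PPI network analysis: TOM distances, shortest paths, Dj scores.

The input is a weighted undirected interaction graph (edge weights are
confidence scores in (0, 1], e.g. STRING combined scores / 1000).  The
adjacency matrix is converted to a topological-overlap similarity,

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{u != i} a_iu,

whose complement 1 - TOM serves as a distance.  All-pairs shortest
paths over that distance matrix (Dijkstra) give the SP matrix, from
which every node j is scored by its proximity to a designated core set:

    Dj = (mean_{i not in C} SP_ij - mean_{i in C} SP_ij) / mean_i SP_ij

with the sums running over all nodes (the j = j term contributes 0) and
C/NC the global core/non-core counts.  A positive Dj marks a node
closer to the core genes than to the rest of the network; the core
network is the induced subgraph on the cores plus the strictly-positive
scorers.

Two shortest-path modes exist because the distance matrix itself is
complete: ``complete`` (default) treats every finite off-diagonal entry
as a traversable step, so SP <= 1 always; ``edges_only`` restricts
traversal to the original interaction edges with 1 - TOM weights.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import csgraph_from_dense, dijkstra

logger = logging.getLogger(__name__)


def build_graph(edges: pd.DataFrame) -> nx.Graph:
    """Simple undirected weighted graph from a validated edge list.

    Zero-weight rows are dropped with a warning (edge weights live in
    (0, 1]); duplicate pairs should already be collapsed upstream but
    are tolerated keeping the maximum weight.
    """
    graph = nx.Graph()
    zero = edges["weight"] <= 0
    if zero.any():
        warnings.warn(f"dropped {int(zero.sum())} non-positive-weight edge(s)")
        edges = edges[~zero]
    if (edges["weight"] > 1).any():
        raise ValueError("edge weights must lie in (0, 1]")
    for a, b, w in edges[["node_a", "node_b", "weight"]].itertuples(index=False):
        if a == b:
            continue
        if graph.has_edge(a, b):
            w = max(w, graph[a][b]["weight"])
        graph.add_edge(a, b, weight=float(w))
    return graph


def giant_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties break toward the component containing the
    lexicographically smallest node.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph has no giant component")
    components = sorted(nx.connected_components(graph),
                        key=lambda c: (-len(c), min(c)))
    return graph.subgraph(components[0]).copy()


def _adjacency(graph: nx.Graph) -> tuple[np.ndarray, list[str]]:
    nodes = sorted(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("edge weights must lie in [0, 1]")
    return a, nodes


def tom_similarity(graph: nx.Graph) -> pd.DataFrame:
    """Unsigned topological overlap matrix; diagonal 1.

    Non-adjacent pairs still receive positive TOM through shared
    neighbors.
    """
    a, nodes = _adjacency(graph)
    k = a.sum(axis=0)
    l = a @ a  # noqa: E741  - shared-neighbor term (diag of a is 0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=nodes, columns=nodes)


def tom_distance(tom: pd.DataFrame) -> pd.DataFrame:
    """Distance matrix 1 - TOM with a zero diagonal."""
    dist = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=tom.index, columns=tom.columns)


def shortest_path_matrix(
    dist: pd.DataFrame,
    mode: str = "complete",
    graph: nx.Graph | None = None,
) -> pd.DataFrame:
    """All-pairs Dijkstra over the TOM-distance matrix.

    ``mode='complete'`` (default) admits every finite off-diagonal
    entry as a step; ``'edges_only'`` admits only the original
    interaction edges (requires ``graph``) with their 1 - TOM weights.
    """
    d = dist.to_numpy(float).copy()
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if mode == "complete":
        pass
    elif mode == "edges_only":
        if graph is None:
            raise ValueError("mode='edges_only' requires the interaction graph")
        nodes = list(dist.index)
        idx = {n: i for i, n in enumerate(nodes)}
        mask = np.zeros_like(d, dtype=bool)
        for u, v in graph.edges:
            mask[idx[u], idx[v]] = mask[idx[v], idx[u]] = True
        d[~mask] = np.inf
    else:
        raise ValueError(f"unknown shortest-path mode {mode!r}")
    np.fill_diagonal(d, np.inf)  # diagonal handled by dijkstra itself
    sp = dijkstra(csgraph_from_dense(d, null_value=np.inf), directed=False)
    return pd.DataFrame(sp, index=dist.index, columns=dist.columns)


def dj_scores(sp: pd.DataFrame, core: set[str]) -> pd.DataFrame:
    """Core-proximity score Dj for every node.

    Requires a non-empty core set that is a proper subset of the nodes.
    A node at distance 0 from everything (degenerate) scores 0 with a
    warning.  Returns a frame indexed by node with columns ``dj`` and
    ``is_core``.
    """
    nodes = list(sp.index)
    core = set(core)
    missing = core - set(nodes)
    if missing:
        raise ValueError(f"core nodes absent from the SP matrix: {sorted(missing)}")
    if not core:
        raise ValueError("core set is empty")
    if len(core) >= len(nodes):
        raise ValueError("core set must be a proper subset of the nodes")
    is_core = np.array([n in core for n in nodes])
    c = int(is_core.sum())
    nc = len(nodes) - c
    m = sp.to_numpy(float)
    if not np.isfinite(m).all():
        raise ValueError("SP matrix contains infinite distances; "
                         "restrict to a connected component first")
    total = m.sum(axis=0)
    core_mean = m[is_core].sum(axis=0) / c
    noncore_mean = m[~is_core].sum(axis=0) / nc
    overall_mean = total / (c + nc)
    with np.errstate(invalid="ignore", divide="ignore"):
        dj = (noncore_mean - core_mean) / overall_mean
    degenerate = total == 0
    if degenerate.any():
        warnings.warn("node(s) coincident with the whole network; Dj set to 0")
        dj = np.where(degenerate, 0.0, dj)
    out = pd.DataFrame({"dj": dj, "is_core": is_core},
                       index=pd.Index(nodes, name="node"))
    return out


def extract_core_network(graph: nx.Graph, scores: pd.DataFrame) -> nx.Graph:
    """Induced subgraph on the cores plus strictly-positive Dj scorers.

    Uses the original interaction edges; the result may have several
    components.  Dj and core flags are attached as node attributes.
    """
    missing = set(graph.nodes) - set(scores.index)
    if missing:
        raise ValueError(f"scores missing for node(s) {sorted(missing)[:5]}")
    keep = [n for n in graph.nodes
            if scores.loc[n, "is_core"] or scores.loc[n, "dj"] > 0]
    sub = graph.subgraph(keep).copy()
    for n in sub.nodes:
        sub.nodes[n]["dj"] = float(scores.loc[n, "dj"])
        sub.nodes[n]["is_core"] = bool(scores.loc[n, "is_core"])
    logger.info("core network: %d/%d nodes retained",
                sub.number_of_nodes(), graph.number_of_nodes())
    return sub


def network_descriptives(graph: nx.Graph) -> dict:
    """Standard topology summary of a weighted interaction graph.

    Diameter, transitivity and mean distance are computed unweighted on
    the giant component; edge density on the full graph; betweenness on
    the full graph with 1 - weight edge distances (normalized).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    gc = giant_component(graph)
    for u, v, data in graph.edges(data=True):
        data["distance"] = 1.0 - data.get("weight", 1.0)
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, weight="distance",
                                            normalized=True)
    summary = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "density": nx.density(graph),
        "giant_component_nodes": gc.number_of_nodes(),
        "giant_component_edges": gc.number_of_edges(),
        "diameter": nx.diameter(gc) if gc.number_of_nodes() > 1 else 0,
        "transitivity": nx.transitivity(gc),
        "mean_distance": (nx.average_shortest_path_length(gc)
                          if gc.number_of_nodes() > 1 else 0.0),
        "n_components": nx.number_connected_components(graph),
    }
    node_stats = pd.DataFrame({"degree": pd.Series(degree),
                               "betweenness": pd.Series(betweenness)})
    node_stats.index.name = "node"
    summary["node_stats"] = node_stats.sort_index()
    return summary
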