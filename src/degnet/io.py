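"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular artifacts are plain TSV: tab-delimited, UTF-8, no quoting.
Missing expression values are encoded as ``NA``.  Gene/probe/node
identifiers are case-sensitive and never translated here; symbol
remapping is a scientific step, not I/O.  Readers validate strictly and
raise :class:`FormatError` rather than silently coercing malformed input.

Formats covered: expression TSV (features x samples), sample-sheet TSV
(sample, dataset, group), detection-call TSV (P/A), probe-map TSV
(probe, gene), STRING-style edge-list TSV, GraphML / edge-list graph
export, gene-set text files and Dj score tables.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("normal", "primary", "metastatic")

#: comparison classes, label -> (numerator group, denominator group)
COMPARISON_CLASSES = {
    "MvsN": ("metastatic", "normal"),
    "PvsN": ("primary", "normal"),
    "MvsP": ("metastatic", "primary"),
}


class FormatError(ValueError):
    """Malformed or invalid on-disk artifact."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _parse_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Convert a string-valued frame to float, reporting the first bad cell.

    Uses Python's correctly-rounded ``float`` so that writer/reader pairs
    round-trip values bit-exactly.
    """
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, value in enumerate(df[col].to_numpy()):
            if value == "NA":
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(value)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {value!r} at feature "
                    f"{df.index[i]!r}, sample {col!r}") from None
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a feature x sample expression matrix.

    First column holds feature IDs, header row holds sample IDs.  Values
    are floats on the log2 scale; literal ``NA`` marks a missing value.
    Duplicate feature or sample IDs and ragged/empty cells are hard errors.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged TSV ({exc})") from exc
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate feature ID {dup[0]!r}")
    dup = df.columns[df.columns.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate sample ID {dup[0]!r}")
    if (df == "").any().any():
        raise FormatError(f"{path}: empty cell (ragged row?)")
    df.index = df.index.astype(str)
    df.index.name = "feature"
    return _parse_numeric(df, path)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr = expr.copy()
    expr.index.name = "feature"
    expr.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet with columns (sample, dataset, group)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample", "dataset", "group"]
    if list(sheet.columns[:3]) != required:
        raise FormatError(f"{path}: expected columns {required}, "
                          f"got {list(sheet.columns)}")
    return validate_sample_sheet(sheet[required], context=str(path))


def validate_sample_sheet(sheet: pd.DataFrame, context: str = "sample sheet") -> pd.DataFrame:
    dup = sheet["sample"][sheet["sample"].duplicated()]
    if len(dup):
        raise FormatError(f"{context}: duplicate sample ID {dup.iloc[0]!r}")
    bad = set(sheet["group"]) - set(VALID_GROUPS)
    if bad:
        raise FormatError(f"{context}: invalid group label(s) {sorted(bad)}; "
                          f"expected one of {VALID_GROUPS}")
    return sheet.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[["sample", "dataset", "group"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# detection calls and probe maps
# ---------------------------------------------------------------------------

def read_calls_tsv(path, expr: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a present/absent call matrix; ``M`` (marginal) maps to ``P``.

    When ``expr`` is given the call matrix must match its feature and
    sample IDs exactly.
    """
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False)
    calls.index = calls.index.astype(str)
    calls = calls.replace("M", "P")
    bad = set(np.unique(calls.to_numpy())) - {"P", "A"}
    if bad:
        raise FormatError(f"{path}: invalid call value(s) {sorted(bad)}")
    if expr is not None:
        if list(calls.index) != list(expr.index) or list(calls.columns) != list(expr.columns):
            raise FormatError(f"{path}: call matrix IDs do not match the "
                              "paired expression matrix")
    calls.index.name = "feature"
    return calls


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls = calls.copy()
    calls.index.name = "feature"
    calls.to_csv(path, sep="\t")


def read_probe_map(path) -> pd.DataFrame:
    """Read a (probe, gene) map; many-to-many relations are allowed."""
    pmap = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(pmap.columns[:2]) != ["probe", "gene"]:
        raise FormatError(f"{path}: expected columns ['probe', 'gene']")
    if (pmap[["probe", "gene"]] == "").any().any():
        raise FormatError(f"{path}: empty probe or gene field")
    return pmap[["probe", "gene"]].drop_duplicates().reset_index(drop=True)


def write_probe_map(pmap: pd.DataFrame, path) -> None:
    pmap[["probe", "gene"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# STRING-style edge lists
# ---------------------------------------------------------------------------

def read_string_edgelist(path, score_scale: str = "milli") -> pd.DataFrame:
    """Read a STRING-format weighted edge list into (node_a, node_b, weight).

    ``score_scale='milli'`` declares integer combined scores in 0..1000
    (divided by 1000 on load); ``'unit'`` declares floats in [0, 1].
    Self-loops are dropped with a warning; duplicate unordered pairs are
    collapsed keeping the maximum score.  Scores outside the declared
    range are a hard error.
    """
    if score_scale not in ("milli", "unit"):
        raise ValueError(f"score_scale must be 'milli' or 'unit', got {score_scale!r}")
    raw = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                      keep_default_na=False, engine="python")
    if raw.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (node, node, score)")
    raw = raw.iloc[:, :3]
    raw.columns = ["node_a", "node_b", "score"]
    # tolerate a header line
    try:
        float(raw.iloc[0, 2])
    except (ValueError, IndexError):
        raw = raw.iloc[1:]
    if raw.empty:
        return pd.DataFrame(columns=["node_a", "node_b", "weight"])
    score = pd.to_numeric(raw["score"], errors="coerce")
    if score.isna().any():
        bad = raw["score"][score.isna()].iloc[0]
        raise FormatError(f"{path}: non-numeric score {bad!r}")
    if score_scale == "milli":
        if ((score < 0) | (score > 1000)).any():
            raise FormatError(f"{path}: combined score outside 0..1000")
        weight = score / 1000.0
    else:
        if ((score < 0) | (score > 1)).any():
            raise FormatError(f"{path}: score outside [0, 1]")
        weight = score.astype(float)
    edges = pd.DataFrame({"node_a": raw["node_a"].astype(str).to_numpy(),
                          "node_b": raw["node_b"].astype(str).to_numpy(),
                          "weight": weight.to_numpy()})
    loops = edges["node_a"] == edges["node_b"]
    if loops.any():
        logger.warning("%s: dropped %d self-loop(s)", path, int(loops.sum()))
        edges = edges[~loops]
    # canonical unordered pair, keep max weight over duplicates
    lo = edges[["node_a", "node_b"]].min(axis=1)
    hi = edges[["node_a", "node_b"]].max(axis=1)
    edges = (pd.DataFrame({"node_a": lo, "node_b": hi, "weight": edges["weight"]})
             .groupby(["node_a", "node_b"], as_index=False)["weight"].max())
    return edges.reset_index(drop=True)


def write_string_edgelist(edges: pd.DataFrame, path, score_scale: str = "milli") -> None:
    out = edges.copy()
    if score_scale == "milli":
        out["combined_score"] = np.rint(out.pop("weight") * 1000).astype(int)
    elif score_scale == "unit":
        out["combined_score"] = out.pop("weight")
    else:
        raise ValueError(f"unknown score_scale {score_scale!r}")
    out.to_csv(path, sep="\t", index=False,
               header=["node1", "node2", "combined_score"])


# ---------------------------------------------------------------------------
# graphs, gene sets, score tables
# ---------------------------------------------------------------------------

def write_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Export a weighted graph losslessly (nodes, edges, weights, attributes).

    ``graphml`` preserves node attributes such as the Dj score and core
    flag; ``tsv`` writes a 3-column edge list (plus isolated nodes as
    single-column rows).
    """
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node1\tnode2\tweight\n")
            for u, v, w in sorted(graph.edges(data="weight")):
                fh.write(f"{u}\t{v}\t{w:.17g}\n")
            for n in sorted(nx.isolates(graph)):
                fh.write(f"{n}\n")
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def read_gene_set(path) -> list[str]:
    """Read a gene-set file, one symbol per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    seen: set[str] = set()
    out = []
    for g in genes:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def write_gene_set(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_score_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"node": str})
    if not {"node", "dj", "is_core"}.issubset(tab.columns):
        raise FormatError(f"{path}: expected columns node, dj, is_core")
    tab["is_core"] = tab["is_core"].astype(bool)
    return tab.set_index("node")


def write_score_table(scores: pd.DataFrame, path) -> None:
    out = scores.reset_index()
    out.columns = ["node"] + list(out.columns[1:])
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
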