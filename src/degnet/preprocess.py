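"""Per-dataset filtering and normalization cascade for expression matrices.

The cascade order is fixed: absent-call filter -> quantile normalization
-> median-SD variance filter -> highest-IQR probe collapse.  Each stage
returns the filtered matrix together with a :class:`FilterReport` so the
whole chain is auditable.  RNA-seq-style matrices that arrive already
summarized take the lighter :func:`prepare_precomputed` path instead
(zero-row removal plus an optional log2 transform).

Conventions pinned for reproducibility (inputs the methods leave open):
sample SD uses the unbiased (ddof=1) estimator, quartiles use linear
interpolation, quantile-normalization ties receive the mean of the tied
target quantiles, and the variance filter keeps features *strictly*
above the median SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Audit record for one filtering stage."""

    stage: str
    features_in: int
    features_removed: int
    removed_ids: list[str]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features_removed != len(self.removed_ids):
            raise ValueError("features_removed must equal len(removed_ids)")
        if self.features_removed > self.features_in:
            raise ValueError("cannot remove more features than supplied")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "features_in": self.features_in,
            "features_removed": self.features_removed,
            "removed_ids": list(self.removed_ids),
            **self.extra,
        }


def filter_absent(
    expr: pd.DataFrame,
    calls: pd.DataFrame | None,
    sheet: pd.DataFrame,
    max_absent: int = 2,
    mode: str = "all_groups",
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove features that the detection calls mark as absent.

    A feature counts as absent in a group when its number of ``A`` calls
    among that group's samples exceeds ``max_absent``.  Under
    ``mode='all_groups'`` (the default, literal reading of the rule) the
    feature is removed only when this holds in *every* group; under
    ``'any_group'`` one failing group suffices.

    ``calls=None`` skips the stage with a warning (detection calls are an
    optional input).
    """
    if mode not in ("all_groups", "any_group"):
        raise ValueError(f"mode must be 'all_groups' or 'any_group', got {mode!r}")
    if calls is None:
        warnings.warn("no detection-call matrix supplied; absent filter skipped")
        return expr, FilterReport("filter_absent", len(expr), 0, [],
                                  {"skipped": True})
    if list(calls.index) != list(expr.index) or list(calls.columns) != list(expr.columns):
        raise ValueError("call matrix IDs do not match the expression matrix")
    sheet = sheet[sheet["sample"].isin(expr.columns)]
    per_group = []
    for _, members in sheet.groupby("group")["sample"]:
        absent_n = (calls[list(members)] == "A").sum(axis=1)
        per_group.append(absent_n > max_absent)
    flags = pd.concat(per_group, axis=1)
    removed = flags.all(axis=1) if mode == "all_groups" else flags.any(axis=1)
    removed_ids = list(expr.index[removed])
    out = expr.loc[~removed]
    report = FilterReport("filter_absent", len(expr), len(removed_ids),
                          removed_ids, {"max_absent": max_absent, "mode": mode})
    logger.info("absent filter: %d/%d features removed", len(removed_ids), len(expr))
    return out, report


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common distribution of row-mean quantiles.

    Each column's k-th order statistic is replaced by the mean of the
    k-th order statistics across columns; ranks within a column are
    preserved and tied values receive the mean of their tied targets.
    """
    if expr.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix "
                         "(missing values present)")
    values = expr.to_numpy(float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average the targets within tie groups
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def filter_low_variance(expr: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop features whose across-sample SD is at or below the median SD."""
    if expr.shape[1] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    sd = expr.std(axis=1, ddof=1)
    cutoff = float(sd.median())
    keep = sd > cutoff
    if not keep.any():
        warnings.warn("all features share the median SD; every feature removed")
    removed_ids = list(expr.index[~keep])
    report = FilterReport("filter_low_variance", len(expr), len(removed_ids),
                          removed_ids, {"sd_cutoff": cutoff})
    logger.info("variance filter: %d/%d features removed (median SD %.4g)",
                len(removed_ids), len(expr), cutoff)
    return expr.loc[keep], report


def _iqr(values: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    return q75 - q25


def collapse_probes(
    expr: pd.DataFrame, probe_map: pd.DataFrame
) -> tuple[pd.DataFrame, FilterReport]:
    """Collapse a probe-level matrix to gene symbols by highest IQR.

    For every gene the mapped probe with the largest interquartile range
    across samples is kept; a probe mapping to several genes competes for
    each of them.  IQR ties break toward the lexicographically smallest
    probe ID.  Probes absent from the map are dropped with a warning.
    """
    pmap = probe_map[probe_map["probe"].isin(expr.index)]
    unmapped = sorted(set(expr.index) - set(pmap["probe"]))
    if unmapped:
        warnings.warn(f"{len(unmapped)} probe(s) missing from the probe map "
                      "were dropped")
    iqr = pd.Series(_iqr(expr.to_numpy(float)), index=expr.index)
    chosen: dict[str, str] = {}
    for gene, probes in pmap.groupby("gene")["probe"]:
        ranked = sorted(probes, key=lambda p: (-iqr[p], p))
        chosen[gene] = ranked[0]
    genes = sorted(chosen)
    out = expr.loc[[chosen[g] for g in genes]]
    out.index = pd.Index(genes, name="feature")
    report = FilterReport(
        "collapse_probes", len(expr), len(unmapped), unmapped,
        {"genes_out": len(genes),
         "probe_for_gene": {g: chosen[g] for g in genes}},
    )
    logger.info("probe collapse: %d probes -> %d genes", len(expr), len(genes))
    return out, report


def prepare_precomputed(
    expr: pd.DataFrame, already_log2: bool, offset: float = 1.0
) -> pd.DataFrame:
    """Prepare a pre-normalized (RNA-seq style) matrix for testing.

    Rows that are zero in every sample are removed; linear-scale input is
    transformed to ``log2(x + offset)`` (the default offset of 1 keeps
    zeros at zero).  Negative values on the linear scale are an error.
    """
    values = expr.to_numpy(float)
    if not already_log2 and (values < 0).any():
        raise ValueError("negative values in a linear-scale matrix")
    nonzero = ~(values == 0).all(axis=1)
    out = expr.loc[nonzero]
    if not already_log2:
        out = pd.DataFrame(np.log2(out.to_numpy(float) + offset),
                           index=out.index, columns=out.columns)
    n_removed = int((~nonzero).sum())
    if n_removed:
        logger.info("removed %d all-zero gene row(s)", n_removed)
    return out
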