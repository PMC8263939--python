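"""Correlation-based sample outlier detection (Number-SD statistic).

Inter-sample agreement is measured by Pearson correlation; the distance
between two samples is 1 - r.  Each sample's mean off-diagonal statistic
is standardized against the other samples of its group, and samples
whose standardized score falls below -2 (strictly) are flagged.  The
default convention standardizes mean *correlations*, under which
aberrant samples score negative, consistent with the "< -2" rule; the
``distance`` convention standardizes mean distances instead, flipping
the sign so outliers score positive.

PCA embeddings and average-linkage dendrograms are provided for visual
QC only and never drive automated flagging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    """Per-sample Number-SD scores for one group of samples."""

    scores: pd.DataFrame  # columns: mean_stat, number_sd
    convention: str
    group: str | None = None
    dataset: str | None = None
    iteration: int = 0
    threshold: float | None = None
    flagged: set[str] = field(default_factory=set)
    degenerate: bool = False  # all samples equidistant; scores forced to 0

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["flagged"] = [s in self.flagged for s in out.index]
        out["group"] = self.group
        out["dataset"] = self.dataset
        out["iteration"] = self.iteration
        return out


def _correlations(expr: pd.DataFrame) -> np.ndarray:
    values = expr.to_numpy(float)
    sds = values.std(axis=0)
    if (sds == 0).any():
        bad = expr.columns[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero variance; "
                         "correlation undefined")
    return np.corrcoef(values, rowvar=False)


def correlation_distance_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample distances D_ij = 1 - Pearson(sample_i, sample_j)."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 features")
    dist = 1.0 - _correlations(expr)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=expr.columns, columns=expr.columns)


def number_sd_scores(
    expr: pd.DataFrame, convention: str = "correlation"
) -> OutlierReport:
    """Standardized mean inter-sample agreement per sample.

    For each sample s, ``m_s`` is the mean of its off-diagonal statistic
    (Pearson r under ``convention='correlation'``, 1 - r under
    ``'distance'``) and ``score_s = (m_s - mean(m)) / SD(m)`` with the
    unbiased SD.  When SD(m) = 0 (all samples mutually equidistant) the
    scores are defined as 0 with a warning.
    """
    if convention not in ("correlation", "distance"):
        raise ValueError(f"unknown convention {convention!r}")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    corr = _correlations(expr)
    n = corr.shape[0]
    stat = corr if convention == "correlation" else 1.0 - corr
    m = (stat.sum(axis=0) - np.diag(stat)) / (n - 1)
    sd = m.std(ddof=1)
    # identical columns leave only float jitter in the correlations
    degenerate = sd < 1e-12 or not np.isfinite(sd)
    if degenerate:
        warnings.warn("all samples equidistant; Number-SD scores set to 0")
        scores = np.zeros(n)
    else:
        scores = (m - m.mean()) / sd
    frame = pd.DataFrame({"mean_stat": m, "number_sd": scores},
                         index=expr.columns)
    frame.index.name = "sample"
    return OutlierReport(scores=frame, convention=convention,
                         degenerate=degenerate)


def detect_outliers(report: OutlierReport, threshold: float = -2.0) -> set[str]:
    """Flag samples beyond the Number-SD threshold (strict inequality).

    Under the correlation convention outliers score *below* the
    (negative) threshold; under the distance convention the scores carry
    the opposite sign, so samples scoring strictly above ``-threshold``
    are flagged.
    """
    s = report.scores["number_sd"]
    if report.convention == "correlation":
        flagged = set(s.index[s < threshold])
    else:
        flagged = set(s.index[s > -threshold])
    report.threshold = threshold
    report.flagged = flagged
    return flagged


def remove_outliers(
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    per_group: bool = True,
    max_iterations: int = 1,
    threshold: float = -2.0,
    convention: str = "correlation",
) -> tuple[pd.DataFrame, pd.DataFrame, list[OutlierReport]]:
    """Iteratively drop Number-SD outliers, by default within each group.

    Groups that start with (or shrink below) 3 samples are left alone
    with a warning, since the statistic is undefined there.  A single
    pass (``max_iterations=1``) is the default.
    """
    sheet = sheet[sheet["sample"].isin(expr.columns)].copy()
    reports: list[OutlierReport] = []
    for iteration in range(max_iterations):
        any_flagged = False
        if per_group:
            units = [(group, list(members))
                     for (group, members) in sheet.groupby("group")["sample"]]
        else:
            units = [("all", list(sheet["sample"]))]
        for group, members in units:
            if len(members) < 3:
                warnings.warn(
                    f"group {group!r} has fewer than 3 samples; "
                    "outlier detection skipped")
                continue
            report = number_sd_scores(expr[members], convention=convention)
            report.group = group
            report.iteration = iteration
            datasets = sheet.loc[sheet["sample"].isin(members), "dataset"].unique()
            report.dataset = datasets[0] if len(datasets) == 1 else None
            flagged = detect_outliers(report, threshold=threshold)
            reports.append(report)
            if flagged:
                any_flagged = True
                logger.info("iteration %d, group %s: removing %s",
                            iteration, group, sorted(flagged))
                expr = expr.drop(columns=sorted(flagged))
                sheet = sheet[~sheet["sample"].isin(flagged)]
        if not any_flagged:
            break
    return expr, sheet.reset_index(drop=True), reports


def pca_embedding(expr: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-component PCA of samples (QC visualization only).

    Returns per-sample coordinates on the first two components and the
    explained-variance fractions of all components.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(float).T  # samples x features
    pca = PCA(n_components=min(x.shape[0] - 1, x.shape[1]), svd_solver="full")
    coords = pca.fit_transform(x)[:, :2]
    frame = pd.DataFrame(coords, index=expr.columns, columns=["PC1", "PC2"])
    frame.index.name = "sample"
    return frame, pca.explained_variance_ratio_


def dendrogram_linkage(expr: pd.DataFrame) -> np.ndarray:
    """Average-linkage tree on 1 - r distances, for report dendrograms."""
    dist = correlation_distance_matrix(expr)
    condensed = squareform(dist.to_numpy(), checks=False)
    return average(condensed)
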