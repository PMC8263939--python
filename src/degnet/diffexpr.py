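"""Two-group differential expression with empirical-Bayes moderation.

Per gene, the log2 fold change is the difference of group means and the
residual variance is the pooled two-sample estimate with ``n1 + n2 - 2``
degrees of freedom.  The gene-wise variances are shrunk toward a common
prior by moment-matching the marginal scaled-F distribution of the
sample variances on the log scale: with ``z_g = log(s_g^2)`` and
``e_g = z_g - psi(d/2) + log(d/2)``,

    E[e]   = log(s0^2) - psi(d0/2) + log(d0/2)
    Var[e] = psi'(d/2) + psi'(d0/2)

so the prior degrees of freedom ``d0`` come from inverting the trigamma
function (monotone bisection) on ``Var[e] - psi'(d/2)`` and the prior
variance ``s0^2`` from the mean equation.  The moderated statistic

    t_g = logFC_g / (s_tilde_g * sqrt(1/n1 + 1/n2)),
    s_tilde_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

is referred to a Student t with ``d0 + d`` degrees of freedom (standard
normal when ``d0`` is infinite).  With ``prior_df=0`` the statistic
reduces exactly to the ordinary pooled two-sample t.

DEG calls use strict cutoffs: |logFC| > 0.5 and BH-adjusted p < 0.05 by
default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group contrast; logFC = mean(numerator) - mean(denominator)."""

    numerator: str
    denominator: str
    label: str  # MvsN / PvsN / MvsP
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator groups must differ")


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 by bisection (psi' is decreasing)."""
    lo, hi = 1e-8, 1e8
    if y >= special.polygamma(1, lo):
        return lo
    if y <= special.polygamma(1, hi):
        return hi
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-14:
            break
    return np.sqrt(lo * hi)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled-F marginal of gene variances.

    Returns ``(d0, s0_squared)``; ``d0`` is ``inf`` when the observed
    log-variance spread is no wider than expected from chi-square
    sampling alone.  Zero variances are excluded from the fit.
    """
    s2 = np.asarray(s2, float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        warnings.warn("too few positive gene variances; no moderation applied")
        return 0.0, 0.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    x = _trigamma_inverse(evar)
    d0 = 2.0 * x
    s0sq = float(np.exp(emean + special.digamma(x) - np.log(x)))
    return d0, s0sq


def moderated_t_test(
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    spec: ComparisonSpec,
    prior_df: float | None = None,
    lfc_cut: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test for one two-group comparison.

    Returns a per-gene frame with columns ``logFC, t, df, p_value,
    adj_p, call``.  Genes with missing values in either group are
    dropped from this comparison (logged).  ``prior_df`` overrides the
    estimated prior degrees of freedom (0 gives the ordinary pooled t,
    ``inf`` fully shrinks to the prior variance).
    """
    sheet = sheet[sheet["sample"].isin(expr.columns)]
    g1 = list(sheet.loc[sheet["group"] == spec.numerator, "sample"])
    g2 = list(sheet.loc[sheet["group"] == spec.denominator, "sample"])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"comparison {spec.label}: both groups need >=2 samples "
            f"(got {len(g1)} {spec.numerator!r}, {len(g2)} {spec.denominator!r})")
    sub = expr[g1 + g2]
    complete = ~sub.isna().any(axis=1)
    if (~complete).any():
        logger.info("dropping %d gene(s) with missing values from %s",
                    int((~complete).sum()), spec.label)
    sub = sub.loc[complete]
    x1 = sub[g1].to_numpy(float)
    x2 = sub[g2].to_numpy(float)
    n1, n2 = len(g1), len(g2)
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df

    if prior_df is None:
        d0, s0sq = fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s0sq = fit_variance_prior(s2, df)
        if d0 == 0:
            s0sq = 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    degenerate = se == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} gene(s) with zero moderated "
                      "variance; p set to 0 (nonzero logFC) or 1")
        p = np.where(degenerate, np.where(logfc == 0, 1.0, 0.0), p)

    adj = benjamini_hochberg(p)
    result = pd.DataFrame(
        {"logFC": logfc, "t": t,
         "df": np.full(len(sub), df_total, dtype=float),
         "p_value": p, "adj_p": adj},
        index=sub.index)
    result["call"] = _calls(result, lfc_cut, alpha)
    result.attrs.update({"label": spec.label, "dataset": spec.dataset,
                         "d0": d0, "s0sq": s0sq, "n1": n1, "n2": n2})
    return result


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _calls(result: pd.DataFrame, lfc_cut: float, alpha: float) -> np.ndarray:
    up = (result["logFC"] > lfc_cut) & (result["adj_p"] < alpha)
    down = (result["logFC"] < -lfc_cut) & (result["adj_p"] < alpha)
    return np.where(up, "Up", np.where(down, "Down", "NotDE"))


def select_degs(
    result: pd.DataFrame, lfc_cut: float = 0.5, alpha: float = 0.05
) -> dict[str, str]:
    """Genes passing |logFC| > lfc_cut and adjusted p < alpha (both strict).

    Returns a mapping gene -> direction ("Up"/"Down").
    """
    calls = _calls(result, lfc_cut, alpha)
    return {g: c for g, c in zip(result.index, calls) if c != "NotDE"}
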