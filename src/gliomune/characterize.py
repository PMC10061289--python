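"""Molecular and clinical characterization of the discovered subtypes.

The differential-expression screen is a one-vs-rest rank-sum test per gene at
the fixed thresholds |log2FC| > 1, FDR < 0.05 and BH-adjusted p < 0.001, with
log2FC computed on mean FPKM + 1.  (A negative-binomial count model is
deliberately not used: the thresholds, not the test engine, define the DEG
sets this pipeline consumes, and FPKM matrices carry no count information.)
Over-representation of differential genes in user-supplied pathway sets is
the upper-tail hypergeometric probability; categorical subtype/covariate
associations use Pearson's chi-square without continuity correction; and
survival is compared with Kaplan-Meier curves and the k-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "de_screen",
    "ora_hypergeometric",
    "chi_square_independence",
    "SurvivalCurves",
    "km_logrank",
]


def bh_adjust(p_values: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_screen(
    expr: pd.DataFrame,
    labels: pd.Series,
    group: str,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    adj_p_threshold: float = 0.001,
) -> pd.DataFrame:
    """One-vs-rest differential-expression screen for one subtype.

    Returns a per-gene table with ``log2_fc`` (on mean FPKM + 1), the raw
    two-sided rank-sum p, the BH-adjusted p (``fdr``), and the
    ``differential`` flag applying all three thresholds strictly.
    Constant genes receive p = 1 and stay in the table.
    """
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some expression samples")
    in_group = (labels == group).to_numpy()
    if in_group.sum() < 3 or (~in_group).sum() < 3:
        raise ValueError(f"group {group!r} needs >= 3 samples on each side")
    values = expr.to_numpy(dtype=np.float64)
    x = values[:, in_group]
    y = values[:, ~in_group]

    log2_fc = np.log2((x.mean(axis=1) + 1.0) / (y.mean(axis=1) + 1.0))
    constant = np.all(values == values[:, [0]], axis=1)
    p = np.ones(values.shape[0])
    variable = ~constant
    if variable.any():
        res = stats.mannwhitneyu(
            x[variable], y[variable], axis=1, alternative="two-sided"
        )
        p[variable] = res.pvalue
    fdr = bh_adjust(p)
    differential = (
        (np.abs(log2_fc) > lfc_threshold)
        & (fdr < fdr_threshold)
        & (fdr < adj_p_threshold)
    )
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p,
            "fdr": fdr,
            "differential": differential,
        },
        index=expr.index,
    )


def ora_hypergeometric(
    hit_genes: set[str] | frozenset[str],
    gene_set: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> tuple[float, int]:
    """Upper-tail hypergeometric over-representation probability.

    P(overlap >= observed) for ``hit_genes`` drawn from ``universe`` against
    ``gene_set``.  Returns (p, observed overlap).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = frozenset(hit_genes) & universe
    gene_set = frozenset(gene_set) & universe
    overlap = len(hits & gene_set)
    M, n, N = len(universe), len(gene_set), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    return p, overlap


def chi_square_independence(contingency: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(contingency, dtype=np.float64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p)


@dataclass
class SurvivalCurves:
    """Kaplan-Meier estimates per group plus the k-group log-rank test."""

    groups: dict[str, pd.DataFrame]  # per group: time, survival, n_at_risk
    statistic: float
    p_value: float
    degrees_of_freedom: int

    def at_risk(self, group: str, times: list[float]) -> list[int]:
        table = self.groups[group]
        counts = []
        for t in times:
            counts.append(int(table.loc[table["time"] <= t, "n_at_risk"].min())
                          if (table["time"] <= t).any()
                          else int(table["n_at_risk"].max()))
        return counts


def km_logrank(survival: pd.DataFrame, labels: pd.Series) -> SurvivalCurves:
    """Kaplan-Meier curves per group and the k-group log-rank statistic.

    ``survival`` needs ``os_months`` (> 0) and ``os_event`` (0/1) columns
    indexed by sample; ``labels`` assigns each sample to a group.
    """
    labels = labels.reindex(survival.index)
    if labels.isna().any():
        raise ValueError("labels missing for some survival samples")
    times = survival["os_months"].to_numpy(dtype=np.float64)
    events = survival["os_event"].to_numpy()
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")

    curves: dict[str, pd.DataFrame] = {}
    for g in uniq:
        sel = (labels == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        tab = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(dtype=np.float64),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            }
        )
        tab["n_at_risk"] = [
            int((times[sel] >= t).sum()) for t in tab["time"]
        ]
        curves[str(g)] = tab

    res = multivariate_logrank_test(times, labels.to_numpy(), events)
    return SurvivalCurves(
        groups=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        degrees_of_freedom=len(uniq) - 1,
    )
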