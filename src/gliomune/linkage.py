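"""Radiogenomic linkage: correlating signature features with pathway scores.

For every (radiomic feature, enrichment score) pair, Pearson's r with its
two-sided p-value is computed over the shared samples; BH adjustment runs
once over the entire feature x score grid and pairs with adjusted p < 0.05
are called significant.  A correlation found in the discovery cohort is
"replicated" when the same pair is significant in the validation cohort with
the same sign of r.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .characterize import bh_adjust

__all__ = ["correlate", "replication_check"]


def correlate(
    features: pd.DataFrame,
    score_matrix: pd.DataFrame,
    dataset: str = "dataset",
    alpha: float = 0.05,
    scope: str = "global",
) -> pd.DataFrame:
    """Pearson correlation grid between feature columns and score rows.

    ``features`` is samples x features, ``score_matrix`` is sets x samples
    (the scoring-module orientation).  BH runs over the full grid
    (``scope="global"``) or within each feature (``scope="per_feature"``).
    Pairs where either variable is constant are reported with r = NaN and
    excluded from the adjustment.
    """
    shared = features.index.intersection(score_matrix.columns)
    if len(shared) < 10:
        raise ValueError(
            f"need at least 10 shared samples, got {len(shared)}"
        )
    F = features.loc[shared].to_numpy(dtype=np.float64)
    S = score_matrix[shared].to_numpy(dtype=np.float64).T
    n = len(shared)

    Fc = F - F.mean(axis=0)
    Sc = S - S.mean(axis=0)
    f_sd = Fc.std(axis=0)
    s_sd = Sc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Fc.T @ Sc) / n / np.outer(f_sd, s_sd)
    r[np.outer(f_sd == 0, np.ones_like(s_sd, dtype=bool))] = np.nan
    r[np.outer(np.ones_like(f_sd, dtype=bool), s_sd == 0)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)

    rows = []
    for i, feat in enumerate(features.columns):
        for j, sc in enumerate(score_matrix.index):
            rows.append({"feature": feat, "score": sc, "r": r[i, j]})
    table = pd.DataFrame(rows)
    valid = table["r"].notna() & (np.abs(table["r"]) < 1.0)
    exact = table["r"].notna() & (np.abs(table["r"]) >= 1.0)
    t_stat = table.loc[valid, "r"] * np.sqrt(
        (n - 2) / (1.0 - table.loc[valid, "r"] ** 2)
    )
    table["p_value"] = np.nan
    table.loc[valid, "p_value"] = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 2)
    table.loc[exact, "p_value"] = 0.0

    table["adj_p"] = np.nan
    defined = table["p_value"].notna()
    if scope == "global":
        table.loc[defined, "adj_p"] = bh_adjust(table.loc[defined, "p_value"])
    elif scope == "per_feature":
        for feat, grp in table[defined].groupby("feature"):
            table.loc[grp.index, "adj_p"] = bh_adjust(grp["p_value"])
    else:
        raise ValueError(f"unknown BH scope {scope!r}")
    table["significant"] = table["adj_p"] < alpha
    table["dataset"] = dataset
    return table


def replication_check(
    linkage_a: pd.DataFrame, linkage_b: pd.DataFrame
) -> pd.DataFrame:
    """Pairs significant in both linkage tables with the same correlation sign.

    Returns the replicated pairs with both r values; raises when the tables
    share no (feature, score) pairs.
    """
    a = linkage_a.set_index(["feature", "score"])
    b = linkage_b.set_index(["feature", "score"])
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("linkage tables share no (feature, score) pairs")
    a, b = a.loc[shared], b.loc[shared]
    replicated = (
        a["significant"]
        & b["significant"]
        & (np.sign(a["r"]) == np.sign(b["r"]))
    )
    out = pd.DataFrame(
        {
            "r_discovery": a["r"],
            "r_validation": b["r"],
            "adj_p_discovery": a["adj_p"],
            "adj_p_validation": b["adj_p"],
        }
    )[replicated]
    return out.reset_index()
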