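"""Single-sample enrichment scoring of cell-marker panels and pathway sets.

The tumor-microenvironment deconvolution at the heart of the subtyping step
scores each marker set in each sample with the rank-weighted running-sum
statistic (ssGSEA): for sample j with N rankable genes, walk the genes in
descending expression order and accumulate

    ES(G, j) = sum_i [ P_in(i) - P_out(i) ]

where ``P_in`` is the cumulative alpha-weighted rank mass of the set genes and
``P_out`` the cumulative fraction of non-set genes.  Tied expression values
receive average ranks, so the score is deterministic and invariant to gene
order and to any strictly monotone transform of a sample's expression.

Scores are min-max normalized per set across the cohort before clustering, and
nine role-tagged cell types are summed into the composite protumor score
(MDSCs, regulatory T cells, neutrophils, M2 macrophages) and antitumor score
(activated CD4+/CD8+ T cells, activated B cells, NK cells, M1 macrophages).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneSetCollection

__all__ = [
    "PROTUMOR_ROLES",
    "ANTITUMOR_ROLES",
    "ssgsea_scores",
    "minmax_normalize",
    "composite_scores",
]

#: cell-type roles summed into the composite protumor score
PROTUMOR_ROLES = (
    "MDSC",
    "Regulatory T cell",
    "Neutrophil",
    "Macrophage M2",
)

#: cell-type roles summed into the composite antitumor score
ANTITUMOR_ROLES = (
    "Activated CD4 T cell",
    "Activated CD8 T cell",
    "Activated B cell",
    "Natural killer cell",
    "Macrophage M1",
)


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_set_genes: int = 3,
) -> pd.DataFrame:
    """Score every gene set in every sample with the ssGSEA running sum.

    Parameters
    ----------
    expr
        Genes x samples FPKM matrix.  Ranks are computed on the raw values;
        the statistic is rank-based, so any log transform is irrelevant.
    sets
        Gene sets; genes absent from ``expr`` are ignored per set.  Sets whose
        intersection with the matrix falls below ``min_set_genes`` are dropped
        with a warning (and listed in ``result.attrs["dropped_sets"]``).
    alpha
        Rank-weight exponent of the running sum (conventional default 0.25).

    Returns
    -------
    DataFrame of shape (n kept sets, n samples).
    """
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    values = expr.to_numpy(dtype=np.float64)
    n_genes, n_samples = values.shape
    gene_index = {g: i for i, g in enumerate(expr.index)}

    kept_names: list[str] = []
    dropped: list[str] = []
    memberships: list[np.ndarray] = []
    for name in sets.names:
        idx = [gene_index[g] for g in sets[name] if g in gene_index]
        if len(idx) < min_set_genes:
            dropped.append(name)
            continue
        member = np.zeros(n_genes, dtype=bool)
        member[idx] = True
        kept_names.append(name)
        memberships.append(member)
    if dropped:
        warnings.warn(
            "sets dropped (fewer than "
            f"{min_set_genes} genes found in the matrix): {sorted(dropped)}",
            stacklevel=2,
        )
    if not kept_names:
        raise ValueError("no gene set overlaps the expression matrix")
    member_mat = np.stack(memberships)  # sets x genes
    set_sizes = member_mat.sum(axis=1)

    # average ranks, ascending: the top-expressed gene carries rank N
    ranks = rankdata(values, axis=0)
    order = np.argsort(-values, axis=0, kind="stable")

    scores = np.empty((len(kept_names), n_samples))
    for j in range(n_samples):
        col = values[:, j]
        if np.all(col == col[0]):
            raise ValueError(
                f"sample {expr.columns[j]!r} is constant and cannot be ranked"
            )
        oj = order[:, j]
        weights = ranks[oj, j] ** alpha
        member_sorted = member_mat[:, oj]
        in_mass = member_sorted * weights
        p_in = np.cumsum(in_mass, axis=1)
        p_in /= p_in[:, -1][:, None]
        out_count = np.cumsum(~member_sorted, axis=1)
        p_out = out_count / (n_genes - set_sizes)[:, None]
        scores[:, j] = (p_in - p_out).sum(axis=1)

    out = pd.DataFrame(scores, index=kept_names, columns=expr.columns)
    out.attrs["alpha"] = alpha
    out.attrs["normalized"] = False
    out.attrs["dropped_sets"] = sorted(dropped)
    return out


def minmax_normalize(scores: pd.DataFrame, scheme: str = "per_set") -> pd.DataFrame:
    """Min-max normalize a score matrix.

    ``scheme="per_set"`` rescales each row to [0, 1] across the cohort (the
    default used before clustering); ``scheme="global"`` rescales by the range
    of the whole matrix.  Constant rows map to all zeros with a warning.
    """
    if scores.shape[1] < 2:
        raise ValueError("min-max normalization needs at least 2 samples")
    values = scores.to_numpy(dtype=np.float64)
    if scheme == "per_set":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        flat = span[:, 0] == 0
        if flat.any():
            warnings.warn(
                f"constant score rows normalized to 0: {list(scores.index[flat])}",
                stacklevel=2,
            )
        span[flat] = 1.0
        normed = (values - lo) / span
        normed[flat.nonzero()[0], :] = 0.0
    elif scheme == "global":
        lo, hi = values.min(), values.max()
        if hi == lo:
            warnings.warn("constant score matrix normalized to 0", stacklevel=2)
            normed = np.zeros_like(values)
        else:
            normed = (values - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    out = pd.DataFrame(normed, index=scores.index, columns=scores.columns)
    out.attrs.update(scores.attrs)
    out.attrs["normalized"] = True
    out.attrs["normalization_scheme"] = scheme
    return out


def composite_scores(
    norm_scores: pd.DataFrame, role_map: dict[str, str]
) -> pd.DataFrame:
    """Sum normalized infiltration scores into protumor/antitumor composites.

    ``role_map`` maps score-matrix row names to cell-type roles; all nine
    roles listed in :data:`PROTUMOR_ROLES` and :data:`ANTITUMOR_ROLES` must be
    represented among the rows.
    """
    role_to_row: dict[str, str] = {}
    for row, role in role_map.items():
        if row in norm_scores.index:
            role_to_row[role] = row
    missing = [
        r for r in (*PROTUMOR_ROLES, *ANTITUMOR_ROLES) if r not in role_to_row
    ]
    if missing:
        raise ValueError(f"missing cell-type roles in score matrix: {missing}")
    pro = norm_scores.loc[[role_to_row[r] for r in PROTUMOR_ROLES]].sum(axis=0)
    anti = norm_scores.loc[[role_to_row[r] for r in ANTITUMOR_ROLES]].sum(axis=0)
    return pd.DataFrame({"protumor_score": pro, "antitumor_score": anti})
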