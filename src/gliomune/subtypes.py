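"""Immune-subtype discovery by stabilized K-means and cross-cohort replication.

Samples are clustered in normalized infiltration-score space.  The cluster
count is chosen by a majority vote of four internal indices (silhouette,
Calinski-Harabasz, Dunn — maximized — and Davies-Bouldin — minimized).  The
clustering itself is stabilized by subsampling: a reference full-data K-means
fixes label semantics, then many subsample K-means runs are Hungarian-matched
to the reference and their centroids averaged ("refined centroids").  Final
labels are nearest-refined-centroid assignments, which makes the model a
transferable classifier: external cohorts scored and normalized the same way
are labeled by their nearest centroid, and replication is quantified per
cluster with the in-group proportion (IGP) — the percentage of a de-novo
cluster's samples whose transferred label agrees.

Subtype names follow the infiltration-ordering convention of the glioma
immune landscape: C2 = lowest total infiltration ("cold"), C1 = intermediate,
C3 = highest ("inflamed").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "ClusterModel",
    "StabilityReport",
    "dunn_index",
    "select_k",
    "stabilized_kmeans",
    "assign_nearest_centroid",
    "align_labels",
    "compute_igp",
]


@dataclass
class ClusterModel:
    """A transferable subtype classifier: refined centroids + their names."""

    k: int
    centroids: pd.DataFrame  # subtype_names x set_names, normalized-score space
    n_iterations: int
    subsample_fraction: float
    seed: int | None
    normalization_scheme: str = "per_set"
    centroid_dispersion: float | None = None  # mean matched-centroid deviation

    @property
    def set_names(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def subtype_names(self) -> list[str]:
        return list(self.centroids.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "subtype_names": self.subtype_names,
            "set_names": self.set_names,
            "centroids": self.centroids.to_numpy().tolist(),
            "n_iterations": self.n_iterations,
            "subsample_fraction": self.subsample_fraction,
            "seed": self.seed,
            "normalization_scheme": self.normalization_scheme,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        centroids = pd.DataFrame(
            payload["centroids"],
            index=payload["subtype_names"],
            columns=payload["set_names"],
        )
        return cls(
            k=payload["k"],
            centroids=centroids,
            n_iterations=payload["n_iterations"],
            subsample_fraction=payload["subsample_fraction"],
            seed=payload["seed"],
            normalization_scheme=payload["normalization_scheme"],
        )


@dataclass
class StabilityReport:
    """Per-K internal indices, the vote, and optional replication statistics."""

    index_values: pd.DataFrame  # K x index name
    votes: dict[str, int]
    chosen_k: int
    centroid_dispersion: float | None = None
    igp: dict[str, float] | None = None
    extras: dict = field(default_factory=dict)


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min inter-cluster (single-linkage) distance over max diameter."""
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    groups = [X[labels == u] for u in uniq]
    max_diam = 0.0
    for g in groups:
        if len(g) > 1:
            max_diam = max(max_diam, cdist(g, g).max())
    if max_diam == 0:
        return np.inf
    min_between = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            min_between = min(min_between, cdist(groups[i], groups[j]).min())
    return float(min_between / max_diam)


def select_k(
    scores: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    seed: int | None = 0,
) -> tuple[int, StabilityReport]:
    """Choose the cluster count by majority vote of four internal indices.

    ``scores`` is a sets x samples matrix; clustering runs on its transpose.
    Silhouette, Calinski-Harabasz and Dunn each vote for their maximizing K,
    Davies-Bouldin for its minimizing K; the winner is the modal vote, ties
    broken toward the smallest K.
    """
    X = scores.T.to_numpy(dtype=np.float64)
    n = X.shape[0]
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 2:
        raise ValueError("k_range must start at 2 or more")
    if n < 5 * k_hi:
        raise ValueError(
            f"need at least 5*max(k_range)={5 * k_hi} samples, got {n}"
        )
    ks = list(range(k_lo, k_hi + 1))
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        lab = km.labels_
        rows.append(
            {
                "K": k,
                "silhouette": silhouette_score(X, lab),
                "calinski_harabasz": calinski_harabasz_score(X, lab),
                "davies_bouldin": davies_bouldin_score(X, lab),
                "dunn": dunn_index(X, lab),
            }
        )
    table = pd.DataFrame(rows).set_index("K")
    votes = {
        "silhouette": int(table["silhouette"].idxmax()),
        "calinski_harabasz": int(table["calinski_harabasz"].idxmax()),
        "davies_bouldin": int(table["davies_bouldin"].idxmin()),
        "dunn": int(table["dunn"].idxmax()),
    }
    counts = pd.Series(list(votes.values())).value_counts()
    best = counts.max()
    chosen = int(min(k for k, c in counts.items() if c == best))
    return chosen, StabilityReport(index_values=table, votes=votes, chosen_k=chosen)


def _order_subtype_names(centroids: np.ndarray, k: int) -> list[str]:
    """Name clusters by ascending mean total infiltration.

    For K=3 the convention is C2 (cold) < C1 (intermediate) < C3 (inflamed);
    other K get C1..CK in ascending order.
    """
    totals = centroids.sum(axis=1)
    order = np.argsort(totals, kind="stable")
    if k == 3:
        ordered_names = ["C2", "C1", "C3"]
    else:
        ordered_names = [f"C{i + 1}" for i in range(k)]
    names = [""] * k
    for rank, cluster_idx in enumerate(order):
        names[cluster_idx] = ordered_names[rank]
    return names


def stabilized_kmeans(
    scores: pd.DataFrame,
    k: int,
    n_iterations: int = 1000,
    subsample: float = 0.8,
    seed: int | None = None,
    refine: str = "mean",
) -> tuple[ClusterModel, pd.Series]:
    """Subsampled K-means with Hungarian-matched, averaged centroids.

    A reference K-means (k-means++, 10 restarts) on the full data fixes the
    label semantics.  Each of ``n_iterations`` iterations fits K-means to a
    fresh ``subsample`` fraction of the samples; its centroids are matched to
    the reference by minimum-total-distance (Hungarian) assignment.  Refined
    centroids are the element-wise mean (or, with ``refine="medoid"``, the
    medoid) of the matched centroids, and final labels are
    nearest-refined-centroid assignments.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    X = scores.T.to_numpy(dtype=np.float64)
    n = X.shape[0]
    m = int(round(subsample * n))
    if m < 3 * k:
        raise ValueError(
            f"subsample of {m} samples is too small for {k} clusters (need >= {3 * k})"
        )
    ss = np.random.SeedSequence(seed)
    ref_seed, iter_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    rng = np.random.default_rng(iter_seed)

    reference = KMeans(n_clusters=k, n_init=10, random_state=ref_seed).fit(X)
    ref_centroids = reference.cluster_centers_

    matched = np.empty((n_iterations, k, X.shape[1]))
    redraws = 0
    it = 0
    while it < n_iterations:
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(
            n_clusters=k,
            n_init=1,
            random_state=int(rng.integers(2**31)),
        ).fit(X[idx])
        if len(np.unique(km.labels_)) < k:
            redraws += 1
            if redraws > 0.1 * n_iterations:
                raise RuntimeError(
                    "more than 10% of subsample iterations produced an empty cluster"
                )
            warnings.warn("empty cluster in subsample iteration; re-drawing",
                          stacklevel=2)
            continue
        cost = cdist(ref_centroids, km.cluster_centers_)
        _, col = linear_sum_assignment(cost)
        matched[it] = km.cluster_centers_[col]
        it += 1

    if refine == "mean":
        refined = matched.mean(axis=0)
    elif refine == "medoid":
        flat = matched.reshape(n_iterations, -1)
        d = cdist(flat, flat).sum(axis=1)
        refined = matched[int(np.argmin(d))]
    else:
        raise ValueError(f"unknown refine mode {refine!r}")
    dispersion = float(np.mean(np.linalg.norm(matched - refined, axis=(1, 2))))

    names = _order_subtype_names(refined, k)
    name_order = np.argsort(names)  # stable presentation order C1, C2, C3...
    centroids = pd.DataFrame(
        refined[name_order],
        index=[names[i] for i in name_order],
        columns=scores.index,
    )
    model = ClusterModel(
        k=k,
        centroids=centroids,
        n_iterations=n_iterations,
        subsample_fraction=subsample,
        seed=seed,
        normalization_scheme=str(scores.attrs.get("normalization_scheme", "per_set")),
    )
    model.centroid_dispersion = dispersion
    labels, _ = assign_nearest_centroid(model, scores)
    return model, labels


def assign_nearest_centroid(
    model: ClusterModel, scores_new: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Label new samples by their nearest refined centroid (Euclidean).

    ``scores_new`` must contain every set the model was trained on (row order
    is free) and must be normalized by the same scheme.
    """
    missing = [s for s in model.set_names if s not in scores_new.index]
    if missing:
        raise ValueError(f"score matrix is missing sets: {missing}")
    X = scores_new.loc[model.set_names].T.to_numpy(dtype=np.float64)
    D = cdist(X, model.centroids.to_numpy())
    nearest = np.argmin(D, axis=1)
    labels = pd.Series(
        [model.subtype_names[i] for i in nearest],
        index=scores_new.columns,
        name="subtype",
    )
    distances = pd.DataFrame(D, index=scores_new.columns, columns=model.subtype_names)
    return labels, distances


def align_labels(
    labels_a: pd.Series | np.ndarray, labels_b: pd.Series | np.ndarray
) -> tuple[pd.Series, int, dict]:
    """Relabel ``labels_b`` to maximize agreement with ``labels_a``.

    Builds the confusion matrix (padded with zero-count labels when the
    alphabets differ) and solves the assignment with the Hungarian algorithm.
    Returns the relabeled series, the agreement count, and the b -> a mapping.
    """
    a = pd.Series(labels_a).astype(str)
    b_orig = pd.Series(labels_b)
    b = b_orig.astype(str)
    if len(a) != len(b):
        raise ValueError("labelings must cover the same samples")
    cats = sorted(set(a.unique()) | set(b.unique()))
    conf = np.zeros((len(cats), len(cats)), dtype=int)
    pos = {c: i for i, c in enumerate(cats)}
    for x, y in zip(a, b):
        conf[pos[x], pos[y]] += 1
    row, col = linear_sum_assignment(-conf)
    mapping = {cats[c]: cats[r] for r, c in zip(row, col)}
    relabeled = b.map(mapping)
    relabeled.index = b.index
    agreement = int((relabeled.to_numpy() == a.to_numpy()).sum())
    return relabeled, agreement, mapping


def compute_igp(
    denovo_labels: pd.Series | np.ndarray,
    transferred_labels: pd.Series | np.ndarray,
) -> dict[str, float]:
    """Per-cluster in-group proportion (%), after label alignment.

    For each de-novo cluster, the percentage of its samples whose transferred
    label matches.  Empty de-novo clusters are reported as NaN.
    """
    denovo = pd.Series(denovo_labels).to_numpy()
    transferred = pd.Series(transferred_labels).to_numpy()
    if len(denovo) != len(transferred):
        raise ValueError("labelings must cover the same samples")
    out: dict[str, float] = {}
    for cluster in sorted(set(denovo) | set(transferred)):
        members = denovo == cluster
        if members.sum() == 0:
            out[str(cluster)] = float("nan")
        else:
            out[str(cluster)] = float(
                100.0 * (transferred[members] == cluster).mean()
            )
    return out
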