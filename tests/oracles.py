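"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written the slow, obvious way — explicit
loops over the defining formulas — so it shares no code path with the
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def ssgsea_running_sum(
    expression: dict[str, float], gene_set: set[str], alpha: float
) -> float:
    """Enumerate the ssGSEA running sum for one sample, step by step."""
    genes = list(expression)
    n = len(genes)
    # average ranks, ascending (top-expressed gene gets rank n)
    values = [expression[g] for g in genes]
    ranks = {}
    for g in genes:
        v = expression[g]
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks[g] = less + (equal + 1) / 2.0
    order = sorted(genes, key=lambda g: (-expression[g], genes.index(g)))
    denom_in = sum(ranks[g] ** alpha for g in gene_set if g in ranks)
    n_out = n - len([g for g in gene_set if g in ranks])
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in order:
        if g in gene_set:
            cum_in += ranks[g] ** alpha
        else:
            cum_out += 1
        es += cum_in / denom_in - cum_out / n_out
    return es


def bh_step_up(p_values: list[float]) -> list[float]:
    """Hand step-up BH: sort, scale by m/rank, cumulative minimum, cap at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p_values[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int, hits: int) -> float:
    """P(X >= overlap) by exhaustive summation of the hypergeometric pmf."""
    from math import comb

    total = comb(universe, hits)
    acc = 0
    for k in range(overlap, min(set_size, hits) + 1):
        acc += comb(set_size, k) * comb(universe - set_size, hits - k)
    return acc / total


def pearson_r(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = (sum((a - mx) ** 2 for a in x) / n) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / n) ** 0.5
    return cov / (sx * sy)


def auc_pair_counting(labels: list[bool], scores: list[float]) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), over all pos/neg pairs."""
    pos = [s for lab, s in zip(labels, scores) if lab]
    neg = [s for lab, s in zip(labels, scores) if not lab]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def glcm_pair_enumeration(
    levels: np.ndarray, offset: tuple[int, int, int], n_levels: int
) -> np.ndarray:
    """Symmetric co-occurrence counts by looping over every voxel pair."""
    mat = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                nx, ny, nz = x + offset[0], y + offset[1], z + offset[2]
                if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                    continue
                b = levels[nx, ny, nz]
                if b == 0:
                    continue
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    return mat


def glrlm_run_enumeration(
    levels: np.ndarray, offset: tuple[int, int, int], n_levels: int, max_len: int
) -> np.ndarray:
    """Run-length counts by walking every maximal run explicitly."""
    R = np.zeros((n_levels, max_len))
    shape = levels.shape
    d = np.array(offset)

    def inside(pos):
        return all(0 <= pos[i] < shape[i] for i in range(3))

    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                pos = np.array([x, y, z])
                v = levels[x, y, z]
                if v == 0:
                    continue
                prev = pos - d
                if inside(prev) and levels[tuple(prev)] == v:
                    continue  # not the start of a run
                length = 1
                nxt = pos + d
                while inside(nxt) and levels[tuple(nxt)] == v:
                    length += 1
                    nxt = nxt + d
                R[v - 1, length - 1] += 1
    return R


def gldm_dependence_enumeration(
    levels: np.ndarray, n_levels: int
) -> np.ndarray:
    """Gray-level dependence counts (alpha=0, 26-neighborhood, center counted)."""
    shape = levels.shape
    offsets = [
        o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
    ]
    records = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0:
                    continue
                dep = 1
                for dx, dy, dz in offsets:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if (
                        0 <= nx < shape[0]
                        and 0 <= ny < shape[1]
                        and 0 <= nz < shape[2]
                        and levels[nx, ny, nz] == v
                    ):
                        dep += 1
                records.append((v, dep))
    max_dep = max(d for _, d in records)
    D = np.zeros((n_levels, max_dep))
    for v, dep in records:
        D[v - 1, dep - 1] += 1
    return D


def icc_2_1_anova(Y: np.ndarray) -> float:
    """ICC(2,1) from explicit two-way ANOVA sums of squares."""
    n, k = Y.shape
    grand = Y.mean()
    ss_rows = k * sum((Y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((Y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
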