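"""The five gray-level texture-matrix families on a discretized 3D region.

The region is encoded as an integer level volume: 0 outside the mask,
1..n_levels inside.  Conventions (the common defaults of the 3D radiomics
ecosystem):

* GLCM and GLRLM are built per direction over the 13 unique 3D direction
  vectors at distance 1, the matrices are symmetric (GLCM) and feature values
  are averaged over directions.
* GLSZM zones and GLDM/NGTDM neighborhoods use 26-connectivity.
* GLDM dependence uses alpha = 0 (a neighbor is dependent when its level is
  equal) and the dependence size counts the center voxel, so it is always
  >= 1.

``glcm_matrix``/``glrlm_matrix`` are exposed so exhaustive-enumeration
oracles can compare raw counts.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "TEXTURE_FAMILIES",
    "direction_offsets_13",
    "offsets_26",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "texture_features",
]

#: per-family feature counts of the default configuration (24+16+16+5+14 = 75)
TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")

_EPS = np.finfo(np.float64).eps


def direction_offsets_13() -> list[tuple[int, int, int]]:
    """The 13 unique distance-1 direction vectors (26-neighborhood / 2)."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if (dx, dy, dz) > (0, 0, 0):
                    offs.append((dx, dy, dz))
    return offs


def offsets_26() -> list[tuple[int, int, int]]:
    offs = direction_offsets_13()
    return offs + [(-a, -b, -c) for a, b, c in offs]


def _shifted_views(
    levels: np.ndarray, off: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, tuple[slice, ...]]:
    """Overlapping views (a, b) with b displaced by ``off`` relative to a."""
    sl_a, sl_b = [], []
    for o, dim in zip(off, levels.shape):
        if o >= 0:
            sl_a.append(slice(0, dim - o))
            sl_b.append(slice(o, dim))
        else:
            sl_a.append(slice(-o, dim))
            sl_b.append(slice(0, dim + o))
    ta, tb = tuple(sl_a), tuple(sl_b)
    return levels[ta], levels[tb], ta


# ---------------------------------------------------------------- GLCM


def glcm_matrix(
    levels: np.ndarray, off: tuple[int, int, int], n_levels: int
) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction at distance 1."""
    a, b, _ = _shifted_views(levels, off)
    valid = (a > 0) & (b > 0)
    ai, bi = a[valid] - 1, b[valid] - 1
    mat = np.bincount(ai * n_levels + bi, minlength=n_levels * n_levels).reshape(
        n_levels, n_levels
    )
    return (mat + mat.T).astype(np.float64)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)


def _glcm_features_batch(P: np.ndarray) -> dict[str, np.ndarray]:
    """The 24 GLCM features for a stack of D direction matrices at once."""
    D, ng, _ = P.shape
    p = P / P.sum(axis=(1, 2), keepdims=True)
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=2)  # D x ng; symmetric: py == px
    present = px > 0
    ng_present = present.sum(axis=1).astype(np.float64)

    mu_x = (p * ii).sum(axis=(1, 2))
    sig_sq = (p * (ii[None] - mu_x[:, None, None]) ** 2).sum(axis=(1, 2))

    diff = np.abs(ii - jj)
    diff_idx = diff.astype(np.int64).ravel()
    sum_idx = (ii + jj).astype(np.int64).ravel() - 2
    flat = p.reshape(D, -1)
    rows = np.arange(D)[:, None]
    p_diff = np.zeros((D, ng))
    np.add.at(p_diff, (rows, np.broadcast_to(diff_idx, (D, ng * ng))), flat)
    p_sum = np.zeros((D, 2 * ng - 1))
    np.add.at(p_sum, (rows, np.broadcast_to(sum_idx, (D, ng * ng))), flat)
    k_diff = np.arange(ng, dtype=np.float64)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)

    joint_entropy = -_xlog2x(p).sum(axis=(1, 2))
    hx = -_xlog2x(px).sum(axis=1)
    pxpy = px[:, :, None] * px[:, None, :]
    log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = -(p * log_pxpy).sum(axis=(1, 2))
    hxy2 = -(pxpy * log_pxpy).sum(axis=(1, 2))
    imc1 = np.where(hx > 0, (joint_entropy - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0, None))

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k))
    safe_px = np.where(px > 0, px, 1.0)
    a = p / safe_px[:, :, None]  # rows scaled by 1/px(i)
    b = p / safe_px[:, None, :]  # cols scaled by 1/px(k)
    if ng > 1:
        q = a @ b.transpose(0, 2, 1)
        eig = np.sort(np.linalg.eigvals(q).real, axis=1)
        mcc = np.where(ng_present > 1, np.sqrt(np.clip(eig[:, -2], 0.0, None)), 1.0)
    else:
        mcc = np.ones(D)

    autocorr = (p * (ii * jj)).sum(axis=(1, 2))
    correlation = np.where(
        (sig_sq > 0) & (ng_present > 1),
        (autocorr - mu_x**2) / np.where(sig_sq > 0, sig_sq, 1.0),
        1.0,
    )

    da = (p_diff * k_diff).sum(axis=1)
    cluster = ii[None] + jj[None] - 2 * mu_x[:, None, None]
    off_diag = diff > 0
    inv_var = (p[:, off_diag] / (diff[off_diag] ** 2)[None]).sum(axis=1)
    npres = np.maximum(ng_present, 1.0)[:, None, None]

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": (p * cluster**4).sum(axis=(1, 2)),
        "ClusterShade": (p * cluster**3).sum(axis=(1, 2)),
        "ClusterTendency": (p * cluster**2).sum(axis=(1, 2)),
        "Contrast": (p * (ii - jj) ** 2).sum(axis=(1, 2)),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": -_xlog2x(p_diff).sum(axis=1),
        "DifferenceVariance": (p_diff * (k_diff[None] - da[:, None]) ** 2).sum(axis=1),
        "Id": (p / (1.0 + diff)[None]).sum(axis=(1, 2)),
        "Idm": (p / (1.0 + diff**2)[None]).sum(axis=(1, 2)),
        "Idmn": (p / (1.0 + (diff[None] / npres) ** 2)).sum(axis=(1, 2)),
        "Idn": (p / (1.0 + diff[None] / npres)).sum(axis=(1, 2)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": (p**2).sum(axis=(1, 2)),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": p.max(axis=(1, 2)),
        "SumAverage": (p_sum * k_sum).sum(axis=1),
        "SumEntropy": -_xlog2x(p_sum).sum(axis=1),
        "SumSquares": (p * (ii[None] - mu_x[:, None, None]) ** 2).sum(axis=(1, 2)),
    }


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    """24 GLCM features of a single co-occurrence matrix."""
    if P.sum() == 0:
        raise ValueError("empty co-occurrence matrix")
    batch = _glcm_features_batch(P[None].astype(np.float64))
    return {k: float(v[0]) for k, v in batch.items()}


def glcm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """24 GLCM features, computed per direction and averaged over 13 directions."""
    mats = []
    for off in direction_offsets_13():
        mat = glcm_matrix(levels, off, n_levels)
        if mat.sum() > 0:  # a mask can be too thin for some directions
            mats.append(mat)
    if not mats:
        raise ValueError("no voxel pair in any direction (mask too small)")
    batch = _glcm_features_batch(np.stack(mats))
    return {k: float(v.mean()) for k, v in batch.items()}


# ---------------------------------------------------------------- GLRLM


def glrlm_matrix(
    levels: np.ndarray, off: tuple[int, int, int], n_levels: int
) -> np.ndarray:
    """Run-length counts R[level, run_length - 1] for one direction."""
    pad = np.pad(levels, 1)
    d = np.asarray(off)
    coords = np.argwhere(pad > 0)
    vals = pad[tuple(coords.T)]
    prev = pad[tuple((coords - d).T)]
    starts = coords[prev != vals]
    start_vals = pad[tuple(starts.T)]

    max_len = max(levels.shape)
    lengths = np.ones(len(starts), dtype=np.int64)
    cur = starts.copy()
    active = np.arange(len(starts))
    while active.size:
        nxt = cur[active] + d
        cont = pad[tuple(nxt.T)] == start_vals[active]
        active = active[cont]
        cur[active] = nxt[cont]
        lengths[active] += 1

    R = np.zeros((n_levels, max_len), dtype=np.float64)
    np.add.at(R, (start_vals - 1, lengths - 1), 1.0)
    return R


def _rl_style_features(
    M: np.ndarray, n_voxels: int, prefix: tuple[str, str]
) -> dict[str, float]:
    """Shared gray-level x size statistics for run-length and size-zone matrices.

    ``prefix`` holds the family-specific wording, e.g. ("Run", "ShortRun") vs
    ("Zone", "SmallArea").
    """
    unit, small = prefix
    large = {"Run": "LongRun", "Zone": "LargeArea"}[unit]
    n_runs = M.sum()
    i = np.arange(1, M.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, M.shape[1] + 1, dtype=np.float64)[None, :]
    p = M / n_runs
    mu_i = float((p * i).sum())
    mu_l = float((p * l).sum())
    nz = p > 0
    gray_marginal = M.sum(axis=1)
    len_marginal = M.sum(axis=0)
    return {
        f"Short{unit}Emphasis" if unit == "Run" else f"{small}Emphasis": float(
            (M / l**2).sum() / n_runs
        ),
        f"Long{unit}Emphasis" if unit == "Run" else f"{large}Emphasis": float(
            (M * l**2).sum() / n_runs
        ),
        "GrayLevelNonUniformity": float((gray_marginal**2).sum() / n_runs),
        "GrayLevelNonUniformityNormalized": float(
            (gray_marginal**2).sum() / n_runs**2
        ),
        f"{unit}LengthNonUniformity" if unit == "Run" else f"Size{unit}NonUniformity": float(
            (len_marginal**2).sum() / n_runs
        ),
        f"{unit}LengthNonUniformityNormalized"
        if unit == "Run"
        else f"Size{unit}NonUniformityNormalized": float(
            (len_marginal**2).sum() / n_runs**2
        ),
        f"{unit}Percentage": float(n_runs / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        f"{unit}Variance": float((p * (l - mu_l) ** 2).sum()),
        f"{unit}Entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        f"LowGrayLevel{unit}Emphasis": float((M / i**2).sum() / n_runs),
        f"HighGrayLevel{unit}Emphasis": float((M * i**2).sum() / n_runs),
        f"{small}LowGrayLevelEmphasis": float((M / (i**2 * l**2)).sum() / n_runs),
        f"{small}HighGrayLevelEmphasis": float((M * i**2 / l**2).sum() / n_runs),
        f"{large}LowGrayLevelEmphasis": float((M * l**2 / i**2).sum() / n_runs),
        f"{large}HighGrayLevelEmphasis": float((M * i**2 * l**2).sum() / n_runs),
    }


def glrlm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """16 GLRLM features, averaged over the 13 directions."""
    n_voxels = int((levels > 0).sum())
    acc: dict[str, float] = {}
    n_dir = 0
    for off in direction_offsets_13():
        R = glrlm_matrix(levels, off, n_levels)
        if R.sum() == 0:
            continue
        feats = _rl_style_features(R, n_voxels, ("Run", "ShortRun"))
        n_dir += 1
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    if n_dir == 0:
        raise ValueError("empty run-length matrix in every direction")
    return {k: v / n_dir for k, v in acc.items()}


# ---------------------------------------------------------------- GLSZM


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts S[level, zone_size - 1] with 26-connected zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    n_voxels = int((levels > 0).sum())
    S = np.zeros((n_levels, max(n_voxels, 1)), dtype=np.float64)
    for lv in range(1, n_levels + 1):
        binary = levels == lv
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            S[lv - 1, s - 1] += 1
    return S


def glszm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """16 GLSZM features (26-connected zones)."""
    S = glszm_matrix(levels, n_levels)
    if S.sum() == 0:
        raise ValueError("empty size-zone matrix")
    n_voxels = int((levels > 0).sum())
    # trim trailing empty size columns to keep the arithmetic small
    last = int(np.argwhere(S.sum(axis=0) > 0).max()) + 1
    return _rl_style_features(S[:, :last], n_voxels, ("Zone", "SmallArea"))


# ---------------------------------------------------------------- NGTDM


def ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 5 neighborhood gray-tone difference features (26-neighborhood)."""
    inmask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.correlate(
        (levels * inmask).astype(np.float64), kernel, mode="constant"
    )
    nb_cnt = ndimage.correlate(inmask.astype(np.float64), kernel, mode="constant")
    valid = inmask & (nb_cnt > 0)
    n_vp = int(valid.sum())
    if n_vp == 0:
        raise ValueError("no voxel with an in-mask neighbor")
    abar = nb_sum[valid] / nb_cnt[valid]
    lv = levels[valid]

    n_i = np.bincount(lv, minlength=n_levels + 1)[1:].astype(np.float64)
    s_i = np.zeros(n_levels)
    np.add.at(s_i, lv - 1, np.abs(lv - abar))
    p_i = n_i / n_vp
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())

    sum_ps = float((p_i * s_i).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = (
            float((pi * pj * (ii - jj) ** 2)[both].sum())
            / (ngp * (ngp - 1))
            * float(s_i.sum())
            / n_vp
        )
        denom = float(np.abs(i[present, None] * p_i[present, None]
                             - i[None, present] * p_i[None, present]).sum())
        busyness = sum_ps / denom if denom > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i, s_i, indexing="ij")
        complexity = float(
            (np.abs(ii - jj)[both] * (pi[both] * si_[both] + pj[both] * sj_[both])
             / (pi[both] + pj[both])).sum()
        ) / n_vp
        strength_num = float(((pi + pj) * (ii - jj) ** 2)[both].sum())
        strength = strength_num / float(s_i.sum()) if s_i.sum() > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------- GLDM


def gldm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 14 gray-level dependence features (alpha=0, 26-neighborhood).

    The dependence size of a voxel is 1 + the number of 26-neighbors inside
    the mask with the same level (the center counts itself).
    """
    inmask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in offsets_26():
        a, b, ta = _shifted_views(levels, off)
        eq = (a > 0) & (b > 0) & (a == b)
        dep[ta] += eq
    lv = levels[inmask]
    dp = dep[inmask] + 1  # center voxel counts itself
    max_dep = int(dp.max())
    D = np.zeros((n_levels, max_dep), dtype=np.float64)
    np.add.at(D, (lv - 1, dp - 1), 1.0)

    n_z = D.sum()
    i = np.arange(1, n_levels + 1, dtype=np.float64)[:, None]
    d = np.arange(1, max_dep + 1, dtype=np.float64)[None, :]
    p = D / n_z
    mu_i = float((p * i).sum())
    mu_d = float((p * d).sum())
    nz = p > 0
    gray_marginal = D.sum(axis=1)
    dep_marginal = D.sum(axis=0)
    return {
        "SmallDependenceEmphasis": float((D / d**2).sum() / n_z),
        "LargeDependenceEmphasis": float((D * d**2).sum() / n_z),
        "GrayLevelNonUniformity": float((gray_marginal**2).sum() / n_z),
        "DependenceNonUniformity": float((dep_marginal**2).sum() / n_z),
        "DependenceNonUniformityNormalized": float((dep_marginal**2).sum() / n_z**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (d - mu_d) ** 2).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((D / i**2).sum() / n_z),
        "HighGrayLevelEmphasis": float((D * i**2).sum() / n_z),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (D / (i**2 * d**2)).sum() / n_z
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (D * i**2 / d**2).sum() / n_z
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (D * d**2 / i**2).sum() / n_z
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (D * i**2 * d**2).sum() / n_z
        ),
    }


_FAMILY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}


def texture_features(
    levels: np.ndarray, family: str, n_levels: int
) -> dict[str, float]:
    """Dispatch to one of the five texture families (24/16/16/5/14 features)."""
    try:
        func = _FAMILY_FUNCS[family.lower()]
    except KeyError:
        raise ValueError(
            f"unknown texture family {family!r}; expected one of {TEXTURE_FAMILIES}"
        ) from None
    return func(levels, n_levels)
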