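"""Feature repeatability filtering and scanner-batch harmonization.

Repeatability is quantified per feature with the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1) computed
on a subjects x 2 raters design:

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with MS_R/MS_C/MS_E the subject/rater/error mean squares.  Features failing
the 0.85 threshold on either the intra- or the inter-rater test set are
discarded before modeling.

Scanner effects are removed with a parametric empirical-Bayes location/scale
adjustment (ComBat): per feature, values are standardized by the pooled
mean/variance, per-batch locations (gamma) and scales (delta^2) are shrunk
toward their across-feature priors (normal / inverse-gamma, moment-matched
hyperparameters, iterated to 1e-6) and the data are back-transformed.  No
biological covariates are protected — subtype labels are unknown at
harmonization time in the intended workflow — and each feature's grand mean
is restored exactly after adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["icc_2_1", "icc_report", "icc_filter", "combat", "CombatParams"]


def icc_2_1(measurements: np.ndarray) -> np.ndarray:
    """ICC(2,1) per feature from a (n_subjects, k_raters[, n_features]) array.

    Identical rater columns (zero total variance) score 1 with a warning.
    """
    Y = np.asarray(measurements, dtype=np.float64)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    n, k, _ = Y.shape
    if n < 5:
        raise ValueError("ICC needs at least 5 subjects")
    if k != 2:
        raise ValueError("expected exactly 2 repeated measurements per subject")
    grand = Y.mean(axis=(0, 1))
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_means - grand) ** 2).sum(axis=0)
    ss_total = ((Y - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    out = np.empty(Y.shape[2])
    degenerate = ss_total == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with identical rater columns; "
            "ICC reported as 1",
            stacklevel=2,
        )
    safe = ~degenerate
    out[degenerate] = 1.0
    out[safe] = (ms_r[safe] - ms_e[safe]) / denom[safe]
    return out


def icc_report(
    features: pd.DataFrame,
    features_rater2: pd.DataFrame,
    features_intra2: pd.DataFrame,
    threshold: float = 0.85,
) -> pd.DataFrame:
    """Per-feature intra-/inter-rater ICC(2,1) and the pass flag.

    The three tables hold the same features for the same repeatability
    subjects: the reference delineation, a second rater's delineation, and
    the reference rater's repeat delineation.
    """
    common = features.index.intersection(features_rater2.index).intersection(
        features_intra2.index
    )
    if len(common) < 5:
        raise ValueError("need at least 5 shared repeatability subjects")
    cols = features.columns
    base = features.loc[common, cols].to_numpy()
    inter = np.stack([base, features_rater2.loc[common, cols].to_numpy()], axis=1)
    intra = np.stack([base, features_intra2.loc[common, cols].to_numpy()], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        inter_icc = icc_2_1(inter)
        intra_icc = icc_2_1(intra)
    report = pd.DataFrame(
        {
            "intra_icc": intra_icc,
            "inter_icc": inter_icc,
        },
        index=cols,
    )
    report["pass"] = (report["intra_icc"] >= threshold) & (
        report["inter_icc"] >= threshold
    )
    return report


def icc_filter(
    features: pd.DataFrame, report: pd.DataFrame
) -> pd.DataFrame:
    """Keep only the columns whose ICC report row passes."""
    keep = report.index[report["pass"]]
    return features.loc[:, [c for c in features.columns if c in set(keep)]]


@dataclass
class CombatParams:
    """Fitted per-batch location (gamma) and scale (delta^2) estimates."""

    batches: list[str]
    gamma: pd.DataFrame  # batches x features
    delta_sq: pd.DataFrame


def _aprior(delta_hat: np.ndarray) -> float:
    m, v = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * v + m**2) / v if v > 0 else 2.0


def _bprior(delta_hat: np.ndarray) -> float:
    m, v = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * v + m**3) / v if v > 0 else m


def combat(
    features: pd.DataFrame,
    batch: pd.Series,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[pd.DataFrame, CombatParams]:
    """Parametric empirical-Bayes batch harmonization of a feature table.

    ``features`` is samples x features; ``batch`` assigns each sample to a
    scanner/batch (>= 2 batches of >= 3 samples).  Features with zero
    variance inside some batch get a location-only adjustment (logged with a
    warning).  A single batch returns the input unchanged.
    """
    batch = batch.reindex(features.index)
    if batch.isna().any():
        raise ValueError("batch label missing for some samples")
    X = features.to_numpy(dtype=np.float64).copy()
    n, p = X.shape
    batches = sorted(batch.unique())
    if len(batches) == 1:
        params = CombatParams(
            batches=[str(batches[0])],
            gamma=pd.DataFrame(0.0, index=[str(batches[0])], columns=features.columns),
            delta_sq=pd.DataFrame(
                1.0, index=[str(batches[0])], columns=features.columns
            ),
        )
        return features.copy(), params
    masks = [(batch == b).to_numpy() for b in batches]
    sizes = np.array([m.sum() for m in masks])
    if (sizes < 3).any():
        raise ValueError("every batch needs at least 3 samples")

    grand_mean_orig = X.mean(axis=0)
    # design-based grand mean and pooled variance
    batch_means = np.stack([X[m].mean(axis=0) for m in masks])  # B x p
    alpha = (sizes[:, None] * batch_means).sum(axis=0) / n
    # residual variance around each sample's own batch mean
    resid = X.copy()
    for bm, m in zip(batch_means, masks):
        resid[m] -= bm
    pooled_var = (resid**2).sum(axis=0) / n
    degenerate_scale = np.zeros(p, dtype=bool)
    for bm, m in zip(batch_means, masks):
        degenerate_scale |= X[m].var(axis=0) == 0
    if degenerate_scale.any():
        warnings.warn(
            f"{int(degenerate_scale.sum())} feature(s) with a zero-variance batch: "
            "location-only adjustment",
            stacklevel=2,
        )
    pooled_sd = np.sqrt(pooled_var)
    pooled_sd[pooled_sd == 0] = 1.0

    Z = (X - alpha) / pooled_sd
    gamma_hat = np.stack([Z[m].mean(axis=0) for m in masks])
    delta_hat = np.stack(
        [Z[m].var(axis=0, ddof=1) for m in masks]
    )
    delta_hat[delta_hat == 0] = 1.0

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for bi, m in enumerate(masks):
        g_hat = gamma_hat[bi]
        d_hat = delta_hat[bi]
        g_bar, tau_sq = g_hat.mean(), g_hat.var(ddof=1)
        a_prior, b_prior = _aprior(d_hat), _bprior(d_hat)
        n_b = sizes[bi]
        g_new, d_new = g_hat.copy(), d_hat.copy()
        if tau_sq == 0:
            gamma_star[bi], delta_star[bi] = g_new, d_new
            continue
        for _ in range(max_iter):
            g_prev, d_prev = g_new, d_new
            g_new = (n_b * tau_sq * g_hat + d_new * g_bar) / (n_b * tau_sq + d_new)
            sse = ((Z[m] - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sse + b_prior) / (n_b / 2.0 + a_prior - 1.0)
            change = max(
                np.abs(g_new - g_prev).max(), np.abs(d_new - d_prev).max()
            )
            if change < tol:
                break
        gamma_star[bi] = g_new
        delta_star[bi] = d_new

    adjusted = Z.copy()
    for bi, m in enumerate(masks):
        scale = np.sqrt(delta_star[bi])
        scale = np.where(degenerate_scale, 1.0, scale)  # location-only fallback
        gamma_adj = np.where(degenerate_scale, gamma_hat[bi], gamma_star[bi])
        adjusted[m] = (Z[m] - gamma_adj) / scale
    out = adjusted * pooled_sd + alpha
    out += grand_mean_orig - out.mean(axis=0)  # restore the grand mean exactly

    result = pd.DataFrame(out, index=features.index, columns=features.columns)
    params = CombatParams(
        batches=[str(b) for b in batches],
        gamma=pd.DataFrame(
            gamma_star, index=[str(b) for b in batches], columns=features.columns
        ),
        delta_sq=pd.DataFrame(
            delta_star, index=[str(b) for b in batches], columns=features.columns
        ),
    )
    return result, params
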