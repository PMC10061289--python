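"""The 18 first-order intensity features of a region of interest."""

from __future__ import annotations

import numpy as np

__all__ = ["FIRSTORDER_FEATURE_NAMES", "firstorder_features"]

FIRSTORDER_FEATURE_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    intensities: np.ndarray,
    levels: np.ndarray,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """First-order features from the in-mask intensities.

    ``levels`` are the discretized gray levels of the same voxels; Entropy and
    Uniformity are computed on their histogram (log base 2).  ``voxel_volume``
    is the single-voxel volume in mm^3 (Total Energy scales Energy by it).
    Skewness is the population (biased) moment ratio; Kurtosis is non-excess
    (a Gaussian scores ~3); both are defined as 0 for a constant region.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    lv = np.asarray(levels).ravel()
    counts = np.bincount(lv)[1:]
    p = counts[counts > 0] / x.size

    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        centered = x - mean
        m2 = var
        skew = float((centered**3).mean() / m2**1.5)
        kurt = float((centered**4).mean() / m2**2)
    else:
        skew = 0.0
        kurt = 0.0
    energy = float((x**2).sum())

    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume) * energy,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(median),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
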