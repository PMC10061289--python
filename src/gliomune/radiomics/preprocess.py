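"""Intensity and grid preprocessing ahead of feature extraction."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

__all__ = ["z_normalize", "resample_isotropic", "discretize"]


def z_normalize(image: np.ndarray) -> np.ndarray:
    """Per-volume z-score; a constant volume maps to zeros."""
    mu = image.mean()
    sd = image.std()
    if sd == 0:
        return np.zeros_like(image, dtype=np.float64)
    return (image - mu) / sd


def resample_isotropic(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    target: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an image/mask pair to an isotropic grid.

    The image is interpolated trilinearly, the mask nearest-neighbor (it stays
    binary).  ``target`` is the output voxel edge in mm.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if min(image.shape) < 2:
        raise ValueError("cannot resample a degenerate (single-voxel-axis) volume")
    factors = tuple(s / target for s in spacing)
    out_img = ndimage.zoom(image.astype(np.float64), factors, order=1)
    out_mask = ndimage.zoom(mask.astype(np.uint8), factors, order=0) > 0
    return out_img, out_mask


def discretize(
    intensities: np.ndarray, n_bins: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize in-mask intensities into equal-width bins.

    Returns integer levels in 1..n_bins (the maximum lands in the top bin)
    and the bin edges.  Note the binning rescales [min, max], so levels are
    NOT invariant to monotone intensity transforms — a property to keep in
    mind when comparing cohorts with different intensity scales.  A constant
    region maps entirely to level 1 with a warning.
    """
    v = np.asarray(intensities, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant region: all voxels assigned level 1", stacklevel=2)
        return np.ones(v.shape, dtype=np.int64), np.array([lo, lo])
    edges = np.linspace(lo, hi, n_bins + 1)
    levels = np.floor((v - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    np.clip(levels, 1, n_bins, out=levels)
    return levels, edges
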