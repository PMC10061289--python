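"""Per-patient assembly of the full radiomic feature vector.

Per MR sequence: 14 shape + 18 first-order + 75 texture features on the
original image (107) and 18 + 75 = 93 on each of the 8 stationary Haar
subbands (744), i.e. 851 features; over the four sequences (T1, T2, FLAIR,
T1c) a patient yields 3404 named values.  Feature names follow
``<channel>__<original|wavelet-XYZ>__<family>__<feature>``.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .firstorder import firstorder_features
from .preprocess import discretize, z_normalize
from .shape import shape_features
from .texture import TEXTURE_FAMILIES, texture_features
from .wavelet import haar_subbands

__all__ = ["CHANNEL_NAMES", "channel_features", "extract_feature_vector"]

CHANNEL_NAMES = ("T1", "T2", "FLAIR", "T1c")

_BBOX_MARGIN = 4  # voxels of context kept around the mask for filtering


def _crop_to_mask(
    image: np.ndarray, mask: np.ndarray, margin: int = _BBOX_MARGIN
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image[sl], mask[sl]


def _intensity_and_texture(
    image: np.ndarray,
    mask: np.ndarray,
    n_bins: int,
    voxel_volume: float,
) -> OrderedDict[str, float]:
    values = image[mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant subbands are expected
        levels_flat, _ = discretize(values, n_bins=n_bins)
    level_volume = np.zeros(mask.shape, dtype=np.int64)
    level_volume[mask] = levels_flat
    out: OrderedDict[str, float] = OrderedDict()
    for name, value in firstorder_features(values, levels_flat, voxel_volume).items():
        out[f"firstorder__{name}"] = value
    for family in TEXTURE_FAMILIES:
        for name, value in texture_features(level_volume, family, n_bins).items():
            out[f"{family}__{name}"] = value
    return out


def channel_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_bins: int = 32,
    channel: str = "T1",
    normalize: bool = False,
) -> OrderedDict[str, float]:
    """The 851 features of one MR sequence (shape + original + 8 subbands)."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask) > 0
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    if normalize:
        image = z_normalize(image)
    voxel_volume = float(np.prod(spacing))

    out: OrderedDict[str, float] = OrderedDict()
    for name, value in shape_features(mask, spacing).items():
        out[f"{channel}__original__shape__{name}"] = value

    cropped, cmask = _crop_to_mask(image, mask)
    for name, value in _intensity_and_texture(
        cropped, cmask, n_bins, voxel_volume
    ).items():
        out[f"{channel}__original__{name}"] = value
    for sub_name, sub_img in haar_subbands(cropped).items():
        for name, value in _intensity_and_texture(
            sub_img, cmask, n_bins, voxel_volume
        ).items():
            out[f"{channel}__wavelet-{sub_name}__{name}"] = value
    return out


def extract_feature_vector(
    channels: Mapping[str, np.ndarray],
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_bins: int = 32,
    normalize: bool = False,
) -> pd.Series:
    """Concatenate the per-sequence feature vectors of one patient.

    ``channels`` maps sequence names (conventionally T1, T2, FLAIR, T1c) to
    3D volumes sharing the mask grid.  Any non-finite feature value raises,
    naming the offending feature.
    """
    out: OrderedDict[str, float] = OrderedDict()
    for channel, image in channels.items():
        out.update(
            channel_features(
                image,
                mask,
                spacing=spacing,
                n_bins=n_bins,
                channel=channel,
                normalize=normalize,
            )
        )
    vec = pd.Series(out, dtype=np.float64)
    bad = vec.index[~np.isfinite(vec.to_numpy())]
    if len(bad):
        raise ValueError(f"non-finite feature values: {list(bad[:5])}")
    return vec
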