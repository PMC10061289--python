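"""Single-level undecimated (stationary) Haar decomposition of a 3D image.

Each axis is filtered with either the Haar scaling filter L = (1, 1)/sqrt(2)
or the detail filter H = (-1, 1)/sqrt(2) without downsampling, yielding 8
same-shape subbands named by the per-axis letters in x, y, z order
(LLL, HLL, ..., HHH).  Boundaries are handled periodically.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

__all__ = ["SUBBAND_NAMES", "haar_subbands"]

_LO = np.array([1.0, 1.0]) / np.sqrt(2.0)
_HI = np.array([-1.0, 1.0]) / np.sqrt(2.0)

SUBBAND_NAMES = tuple("".join(c) for c in product("LH", repeat=3))


def haar_subbands(image: np.ndarray) -> dict[str, np.ndarray]:
    """Return the 8 stationary Haar subbands of a 3D image.

    A constant image has all detail subbands identically zero and
    LLL = constant * 2**(3/2) (the cubed scaling-filter gain).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected a 3D image")
    if min(image.shape) < 2:
        raise ValueError("every axis must have at least 2 voxels")
    out: dict[str, np.ndarray] = {}
    for name in SUBBAND_NAMES:
        arr = image
        for axis, letter in enumerate(name):
            weights = _LO if letter == "L" else _HI
            arr = ndimage.correlate1d(arr, weights, axis=axis, mode="wrap")
        out[name] = arr
    return out
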