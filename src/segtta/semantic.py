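"""Fusion of dis-augmented probability maps for semantic segmentation.

Per-view soft predictions are combined by element-wise averaging and only
then binarized, so a single threshold pass produces the final mask.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["merge_probmaps", "binarize"]


def _check_probmap(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError(f"probability map must be 2-D, got shape {m.shape}")
    if m.size and (m.min() < 0.0 or m.max() > 1.0):
        raise ValueError("probability map values must lie in [0, 1]")
    return m


def merge_probmaps(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of probability maps.

    All maps must share the same shape and hold values in [0, 1]; the
    result does too.  Merging is permutation-invariant and idempotent on
    identical inputs.
    """
    if len(maps) == 0:
        raise ValueError("need at least one probability map to merge")
    arrs = [_check_probmap(m) for m in maps]
    shape = arrs[0].shape
    for i, a in enumerate(arrs[1:], start=1):
        if a.shape != shape:
            raise ValueError(f"probability map {i} has shape {a.shape}, expected {shape}")
    # accumulate in extended precision: for a handful of maps the sum is then
    # exact, which makes averaging idempotent on identical inputs and
    # independent of map order
    total = np.zeros(shape, dtype=np.longdouble)
    for a in arrs:
        total += a
    out = (total / len(arrs)).astype(np.float64)
    return np.clip(out, 0.0, 1.0)


def binarize(probmap: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a boolean foreground mask.

    A pixel is foreground iff its value is >= ``threshold``, so an exact
    tie (e.g. 3 of 6 views voting foreground) resolves to foreground,
    consistent with the pixel-vote tie rule used in instance fusion.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    probmap = _check_probmap(probmap)
    return probmap >= threshold
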