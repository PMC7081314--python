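"""File I/O for images, masks and probability maps.

Conventions: labeled instance masks are 16-bit PNG/TIFF with 0 background
and labels 1..K; probability maps are 32-bit float single-channel TIFF;
binary masks are 8-bit PNG with values 0/255.  An optional run-length
encoder writes the DSB submission dialect (column-major, 1-based indices,
alternating "start length" pairs).
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .instances import InstanceSet

__all__ = [
    "read_image",
    "read_labels",
    "write_labels",
    "read_probmap",
    "write_probmap",
    "read_binary_mask",
    "write_binary_mask",
    "rle_encode",
    "write_rle_csv",
]

_TIFF_SUFFIXES = (".tif", ".tiff")


def read_image(path) -> np.ndarray:
    """Read a grayscale or RGB image as a numpy array."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return tifffile.imread(path)
    return iio.imread(path)


def read_labels(path) -> np.ndarray:
    """Read a labeled instance mask (any integer dtype, 0 = background)."""
    arr = read_image(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: labeled mask must be single-channel, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: labeled mask must be integer-typed, got {arr.dtype}")
    return arr


def write_labels(path, labels: np.ndarray) -> None:
    """Write a labeled mask as 16-bit PNG or TIFF (by file suffix)."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    data = labels.astype(np.uint16)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_probmap(path) -> np.ndarray:
    """Read a float probability map from TIFF; clip tiny excursions."""
    arr = tifffile.imread(Path(path)).astype(np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{path}: probability map must be 2-D, got shape {arr.shape}")
    return np.clip(arr, 0.0, 1.0)


def write_probmap(path, probmap: np.ndarray) -> None:
    """Write a probability map as 32-bit float single-channel TIFF."""
    tifffile.imwrite(Path(path), np.asarray(probmap, dtype=np.float32))


def read_binary_mask(path) -> np.ndarray:
    """Read a binary mask; any nonzero pixel is foreground."""
    return np.asarray(read_image(path)) > 0


def write_binary_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def rle_encode(mask: np.ndarray) -> list[int]:
    """Run-length encode one mask: column-major, 1-based, start/length pairs."""
    flat = np.asarray(mask, dtype=bool).flatten(order="F")
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts = edges[0::2] + 1  # 1-based
    lengths = edges[1::2] - edges[0::2]
    out: list[int] = []
    for s, l in zip(starts, lengths):
        out.extend((int(s), int(l)))
    return out


def write_rle_csv(path, instances: InstanceSet, image_id: str) -> None:
    """Write an instance set in the DSB submission CSV dialect."""
    path = Path(path)
    new = not path.exists()
    with open(path, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(["ImageId", "EncodedPixels"])
        for mask in instances.masks:
            writer.writerow([image_id, " ".join(map(str, rle_encode(mask)))])
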