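"""Invertible dihedral transforms for test-time augmentation.

The augmentation set consists of six axis-aligned, interpolation-free
transforms: identity, horizontal flip, vertical flip and rotations by 90,
180 and 270 degrees.  Because no interpolation is involved, applying a
transform followed by its inverse reproduces the input bit-exactly on any
grid (intensity image, probability map or labeled mask).

Coordinate convention (fixed): arrays are row-major with the origin at the
top-left.  ``hflip`` reverses column order, ``vflip`` reverses row order,
and ``rot90`` rotates counter-clockwise (``numpy.rot90`` semantics on the
two leading spatial axes).  A trailing channel axis, if present, is left
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TRANSFORM_NAMES",
    "Transform",
    "AugmentationSet",
    "apply",
    "disaugment",
    "default_augmentation_set",
]

#: Canonical ordering of the built-in transform names.
TRANSFORM_NAMES: tuple[str, ...] = (
    "identity",
    "hflip",
    "vflip",
    "rot90",
    "rot180",
    "rot270",
)

_INVERSE = {
    "identity": "identity",
    "hflip": "hflip",
    "vflip": "vflip",
    "rot90": "rot270",
    "rot180": "rot180",
    "rot270": "rot90",
}

_SPATIAL_AXES = (0, 1)


@dataclass(frozen=True)
class Transform:
    """One member of the dihedral augmentation set.

    Parameters
    ----------
    name : str
        One of ``identity, hflip, vflip, rot90, rot180, rot270``.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in _INVERSE:
            raise ValueError(
                f"unknown transform {self.name!r}; "
                f"expected one of {', '.join(TRANSFORM_NAMES)}"
            )

    @property
    def inverse(self) -> "Transform":
        """The transform that exactly undoes this one."""
        return Transform(_INVERSE[self.name])

    @property
    def swaps_axes(self) -> bool:
        """True for the quarter-turn rotations, which exchange H and W."""
        return self.name in ("rot90", "rot270")

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        return apply(self, grid)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def apply(t: Transform | str, grid: np.ndarray) -> np.ndarray:
    """Apply a transform to a 2-D or 3-D (H, W[, C]) pixel grid.

    The pixel multiset is preserved; only positions change.  Quarter-turn
    rotations swap the spatial dimensions, which is permitted on
    rectangular grids.

    Returns a contiguous copy so the result owns its memory.
    """
    t = Transform(t) if isinstance(t, str) else t
    grid = np.asarray(grid)
    if grid.ndim < 2:
        raise ValueError(f"grid must have >=2 spatial dimensions, got shape {grid.shape}")
    name = t.name
    if name == "identity":
        out = grid
    elif name == "hflip":
        out = np.flip(grid, axis=1)
    elif name == "vflip":
        out = np.flip(grid, axis=0)
    elif name == "rot90":
        out = np.rot90(grid, k=1, axes=_SPATIAL_AXES)
    elif name == "rot180":
        out = np.rot90(grid, k=2, axes=_SPATIAL_AXES)
    else:  # rot270
        out = np.rot90(grid, k=3, axes=_SPATIAL_AXES)
    return np.ascontiguousarray(out)


def transformed_shape(t: Transform | str, shape: Sequence[int]) -> tuple[int, ...]:
    """Spatial shape of ``apply(t, grid)`` for a grid of the given shape."""
    t = Transform(t) if isinstance(t, str) else t
    shape = tuple(shape)
    if t.swaps_axes:
        return (shape[1], shape[0]) + shape[2:]
    return shape


def disaugment(t: Transform | str, prediction, original_shape: Sequence[int] | None = None):
    """Revert a prediction made on a transformed view to the original frame.

    ``prediction`` may be a bare array (image / probability map / labeled
    mask) or any object exposing ``transform(t)`` (e.g.
    :class:`segtta.instances.InstanceSet`); in the latter case object order
    and labels are preserved.

    Parameters
    ----------
    t : Transform
        The transform that was applied *before* prediction.
    prediction : ndarray or InstanceSet
        Prediction in the transformed frame.
    original_shape : optional
        Spatial shape (H, W) of the original canvas.  When given, the
        prediction's shape is checked for consistency with ``apply(t, ·)``.
    """
    t = Transform(t) if isinstance(t, str) else t
    if original_shape is not None:
        expect = transformed_shape(t, tuple(original_shape)[:2])
        got = tuple(prediction.shape)[:2]
        if got != expect:
            raise ValueError(
                f"prediction shape {got} inconsistent with transform {t.name} "
                f"of original canvas {tuple(original_shape)[:2]} (expected {expect})"
            )
    if hasattr(prediction, "transform"):
        return prediction.transform(t.inverse)
    return apply(t.inverse, prediction)


class AugmentationSet:
    """An ordered, duplicate-free list of transforms; identity comes first.

    The identity element represents the "original" (un-augmented) view and
    must be present at index 0.  All voting denominators downstream use
    ``len(set)``.
    """

    def __init__(self, transforms: Iterable[Transform | str]):
        ts = [Transform(t) if isinstance(t, str) else t for t in transforms]
        if not ts:
            raise ValueError("augmentation set must contain at least one transform")
        names = [t.name for t in ts]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate transforms in augmentation set: {names}")
        if names[0] != "identity":
            raise ValueError("the first transform must be the identity (original view)")
        self.transforms: list[Transform] = ts

    def __len__(self) -> int:
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)

    def __getitem__(self, i: int) -> Transform:
        return self.transforms[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AugmentationSet)
            and [t.name for t in self] == [t.name for t in other]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AugmentationSet([{', '.join(t.name for t in self)}])"

    @classmethod
    def from_names(cls, names: str | Iterable[str]) -> "AugmentationSet":
        """Build from a comma-separated string or iterable of names."""
        if isinstance(names, str):
            names = [n.strip() for n in names.split(",") if n.strip()]
        return cls(names)


def default_augmentation_set() -> AugmentationSet:
    """The full six-view set: identity, both flips and three rotations."""
    return AugmentationSet(TRANSFORM_NAMES)
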