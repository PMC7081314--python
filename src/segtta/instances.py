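"""Instance-aware fusion of per-view segmentations.

Objects are matched across views by mask IoU (greedy best match per seed,
minimum IoU 0.5), kept when present in a strict majority of views, and
their masks fused by per-pixel majority voting over the matched objects.

Seeding proceeds in rounds: round 0 seeds from the original (identity)
view; round r (r = 1 .. floor(N/2)) seeds from objects of view r that no
earlier group consumed.  A group seeded later than floor(N/2) could never
reach strict majority, so seeding stops there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .geometry import Transform

__all__ = [
    "InstanceSet",
    "MatchGroup",
    "mask_iou",
    "find_best_match",
    "merge_instances",
]


class InstanceSet:
    """An ordered collection of binary object masks over one canvas.

    Raw detector outputs may contain mutually overlapping objects; merged
    outputs produced by :func:`merge_instances` are guaranteed disjoint.

    Parameters
    ----------
    masks : sequence of 2-D arrays
        One boolean mask per object; each must be non-empty and share the
        canvas shape.
    shape : tuple, optional
        Canvas (H, W); required when ``masks`` is empty.
    view_id : optional
        Identifier of the view that produced this set.
    """

    def __init__(
        self,
        masks: Sequence[np.ndarray] = (),
        shape: tuple[int, int] | None = None,
        view_id=None,
    ):
        bool_masks: list[np.ndarray] = []
        for i, m in enumerate(masks):
            m = np.asarray(m)
            if m.ndim != 2:
                raise ValueError(f"object {i}: mask must be 2-D, got shape {m.shape}")
            if m.dtype != bool:
                # soft per-object masks are binarized at 0.5 so IoU is set-based
                m = np.asarray(m, dtype=np.float64) >= 0.5
            if not m.any():
                raise ValueError(f"object {i}: mask is empty")
            bool_masks.append(m)
        if bool_masks:
            shapes = {m.shape for m in bool_masks}
            if len(shapes) > 1:
                raise ValueError(f"inconsistent canvas shapes among objects: {shapes}")
            inferred = bool_masks[0].shape
            if shape is not None and tuple(shape) != inferred:
                raise ValueError(f"declared shape {tuple(shape)} != mask shape {inferred}")
            shape = inferred
        if shape is None:
            raise ValueError("shape is required for an empty InstanceSet")
        self.masks: list[np.ndarray] = bool_masks
        self.shape: tuple[int, int] = (int(shape[0]), int(shape[1]))
        self.view_id = view_id

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.masks[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, InstanceSet):
            return NotImplemented
        return (
            self.shape == other.shape
            and len(self) == len(other)
            and all(np.array_equal(a, b) for a, b in zip(self.masks, other.masks))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InstanceSet(n={len(self)}, shape={self.shape}, view_id={self.view_id})"

    def transform(self, t: Transform | str) -> "InstanceSet":
        """Apply a geometric transform to every object mask (order kept)."""
        from . import geometry

        t = Transform(t) if isinstance(t, str) else t
        new_shape = geometry.transformed_shape(t, self.shape)
        return InstanceSet(
            [geometry.apply(t, m) for m in self.masks],
            shape=new_shape[:2],
            view_id=self.view_id,
        )

    def foreground(self) -> np.ndarray:
        """Union of all object masks as one boolean canvas."""
        out = np.zeros(self.shape, dtype=bool)
        for m in self.masks:
            out |= m
        return out

    def is_disjoint(self) -> bool:
        counts = np.zeros(self.shape, dtype=np.int32)
        for m in self.masks:
            counts += m
        return bool((counts <= 1).all())

    def to_labels(self, dtype=np.uint16) -> np.ndarray:
        """Render as a labeled mask image: 0 background, labels 1..K.

        Objects must be disjoint; later objects would otherwise overwrite
        earlier ones, so overlap raises instead.
        """
        if not self.is_disjoint():
            raise ValueError("cannot render overlapping objects as a labeled mask")
        if len(self) >= np.iinfo(dtype).max:
            raise ValueError(f"too many objects ({len(self)}) for dtype {np.dtype(dtype)}")
        out = np.zeros(self.shape, dtype=dtype)
        for label, m in enumerate(self.masks, start=1):
            out[m] = label
        return out

    @classmethod
    def from_labels(cls, labels: np.ndarray, view_id=None) -> "InstanceSet":
        """Build from a labeled mask (0 = background), one object per label.

        Objects are ordered by ascending label value; label values need not
        be contiguous.
        """
        labels = np.asarray(labels)
        if labels.ndim != 2:
            raise ValueError(f"labeled mask must be 2-D, got shape {labels.shape}")
        values = np.unique(labels)
        values = values[values != 0]
        return cls([labels == v for v in values], shape=labels.shape, view_id=view_id)


@dataclass
class MatchGroup:
    """One seed object and its best IoU match (if any) from each other view.

    ``matches`` maps view index -> (object index, IoU); the seed's own view
    is recorded with IoU 1.0.  ``support`` counts contributing views,
    including the seed's.
    """

    seed_view: int
    seed_object: int
    matches: dict[int, tuple[int, float]] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.matches)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks on the same canvas."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return inter / union


def find_best_match(
    seed: np.ndarray,
    candidates: Sequence[np.ndarray],
    min_iou: float = 0.5,
    exclude: Iterable[int] = (),
) -> Optional[tuple[int, float]]:
    """Best-IoU candidate for a seed mask, or None below ``min_iou``.

    Ties are broken by the lowest candidate index.  Indices in ``exclude``
    (already consumed by another group) are skipped.
    """
    excluded = set(exclude)
    best: Optional[tuple[int, float]] = None
    for i, cand in enumerate(candidates):
        if i in excluded:
            continue
        iou = mask_iou(seed, cand)
        if iou >= min_iou and (best is None or iou > best[1]):
            best = (i, iou)
    return best


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


class _FastMasks:
    """Per-view mask cache with bounding boxes for cheap IoU pruning."""

    def __init__(self, instance_set: InstanceSet):
        self.masks = instance_set.masks
        self.bboxes = [_bbox(m) for m in self.masks]
        self.areas = [int(m.sum()) for m in self.masks]

    def iou(self, i: int, seed_mask, seed_bbox, seed_area) -> float:
        r0a, r1a, c0a, c1a = seed_bbox
        r0b, r1b, c0b, c1b = self.bboxes[i]
        r0, r1 = max(r0a, r0b), min(r1a, r1b)
        c0, c1 = max(c0a, c0b), min(c1a, c1b)
        if r0 >= r1 or c0 >= c1:
            return 0.0
        inter = int(np.count_nonzero(
            seed_mask[r0:r1, c0:c1] & self.masks[i][r0:r1, c0:c1]
        ))
        if inter == 0:
            return 0.0
        return inter / (seed_area + self.areas[i] - inter)

    def best_match(self, seed_mask, seed_bbox, seed_area, min_iou, excluded):
        best = None
        for i in range(len(self.masks)):
            if i in excluded:
                continue
            iou = self.iou(i, seed_mask, seed_bbox, seed_area)
            if iou >= min_iou and (best is None or iou > best[1]):
                best = (i, iou)
        return best


def _vote_mask(group: MatchGroup, views: Sequence[InstanceSet]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel vote counts and the majority mask for one group.

    A pixel is foreground when at least half of the group's matched masks
    contain it (ties resolve to foreground).
    """
    shape = views[0].shape
    votes = np.zeros(shape, dtype=np.int32)
    for view_idx, (obj_idx, _) in group.matches.items():
        votes += views[view_idx][obj_idx]
    mask = votes * 2 >= group.support
    return votes, mask


def merge_instances(
    views: Sequence[InstanceSet],
    min_iou: float = 0.5,
    return_groups: bool = False,
):
    """Merge per-view instance segmentations into one consensus set.

    Parameters
    ----------
    views : sequence of InstanceSet
        Dis-augmented predictions, one per view; ``views[0]`` is the
        original (identity) view.
    min_iou : float
        Minimum IoU for two objects to be considered the same (default 0.5).
    return_groups : bool
        Also return the kept :class:`MatchGroup` records.

    Returns
    -------
    InstanceSet (and optionally list of MatchGroup)
        Non-overlapping consensus objects.  An object is kept iff its
        support is a strict majority (> N/2) of the N views.

    Notes
    -----
    Overlaps between consensus masks (possible when vote masks of distinct
    groups intersect) are resolved deterministically: a contested pixel
    goes to the group with the greater vote fraction there, ties to the
    larger vote-mask area, then to the lower output index.  Groups emptied
    by this resolution are dropped.
    """
    views = list(views)
    if not views:
        raise ValueError("need at least one view to merge")
    shape = views[0].shape
    for i, v in enumerate(views):
        if not isinstance(v, InstanceSet):
            raise TypeError(f"view {i}: expected InstanceSet, got {type(v).__name__}")
        if v.shape != shape:
            raise ValueError(f"view {i} canvas {v.shape} differs from view 0 canvas {shape}")
    n_views = len(views)

    consumed: list[set[int]] = [set() for _ in views]
    groups: list[MatchGroup] = []
    fast = [_FastMasks(v) for v in views]

    max_seed_round = n_views // 2
    for r in range(min(max_seed_round, n_views - 1) + 1):
        for obj_idx in range(len(views[r])):
            if obj_idx in consumed[r]:
                continue
            seed = views[r][obj_idx]
            seed_bbox = fast[r].bboxes[obj_idx]
            seed_area = fast[r].areas[obj_idx]
            group = MatchGroup(seed_view=r, seed_object=obj_idx)
            group.matches[r] = (obj_idx, 1.0)
            consumed[r].add(obj_idx)
            for v in range(n_views):
                if v == r:
                    continue
                hit = fast[v].best_match(seed, seed_bbox, seed_area, min_iou, consumed[v])
                if hit is not None:
                    group.matches[v] = hit
                    consumed[v].add(hit[0])
            groups.append(group)

    kept = [g for g in groups if 2 * g.support > n_views]

    voted = [_vote_mask(g, views) for g in kept]

    # resolve overlaps: greater vote fraction, then larger area, then lower index
    winner = np.full(shape, -1, dtype=np.int32)
    best_frac = np.zeros(shape, dtype=np.float64)
    best_area = np.zeros(shape, dtype=np.int64)
    for idx, (votes, mask) in enumerate(voted):
        area = int(mask.sum())
        support = kept[idx].support
        frac = votes / support
        claim = mask & (
            (winner < 0)
            | (frac > best_frac)
            | ((frac == best_frac) & (area > best_area))
        )
        winner[claim] = idx
        best_frac[claim] = frac[claim]
        best_area[claim] = area

    out_masks: list[np.ndarray] = []
    out_groups: list[MatchGroup] = []
    for idx, group in enumerate(kept):
        final = winner == idx
        if final.any():
            out_masks.append(final)
            out_groups.append(group)

    merged = InstanceSet(out_masks, shape=shape, view_id="merged")
    if return_groups:
        return merged, out_groups
    return merged
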