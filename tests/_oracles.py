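"""Independent reference implementations used only by the tests.

These deliberately avoid the package's algorithms: group discovery is done
by exhaustive pairwise IoU + connected components, mAP matching by
brute-force assignment enumeration, and the paired test by sign-flip
permutation.
"""

import itertools

import numpy as np

from segtta.instances import InstanceSet


def brute_iou(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# instance-merge oracle (unambiguous IoU-separated regime)

def oracle_merge_groups(views, min_iou=0.5):
    """Connected components of the cross-view IoU >= min_iou graph.

    Valid only in the unambiguous regime (each component holds at most one
    object per view).  Returns (kept_components, vote_masks) where each
    component is a frozenset of (view, object) pairs with strict-majority
    support.
    """
    nodes = [(v, i) for v, vs in enumerate(views) for i in range(len(vs))]
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for (va, ia), (vb, ib) in itertools.combinations(nodes, 2):
        if va == vb:
            continue
        if brute_iou(views[va][ia], views[vb][ib]) >= min_iou:
            union((va, ia), (vb, ib))

    comps = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)

    n_views = len(views)
    kept, masks = [], []
    for members in comps.values():
        views_in = [v for v, _ in members]
        assert len(set(views_in)) == len(views_in), "ambiguous scene: duplicate view in component"
        if 2 * len(members) <= n_views:
            continue
        votes = np.zeros(views[0].shape, dtype=int)
        for v, i in members:
            votes += views[v][i]
        kept.append(frozenset(members))
        masks.append(votes * 2 >= len(members))
    return kept, masks


def make_unambiguous_views(seed, n_views=6, canvas=(96, 96), max_objects=5):
    """Random scene in the IoU-separated regime.

    Base objects are well-separated discs; per view each object is present
    with probability 0.75 as a copy shifted by at most one pixel along one
    axis (pairwise IoU of true correspondences >= 0.7); occasional spurious
    objects are placed in per-view-distinct spots (pairwise IoU 0).
    """
    rng = np.random.default_rng(seed)
    h, w = canvas
    yy, xx = np.ogrid[:h, :w]

    def disc(cy, cx, r):
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    n_obj = int(rng.integers(1, max_objects + 1))
    centers, radii = [], []
    attempts = 0
    while len(centers) < n_obj and attempts < 500:
        attempts += 1
        r = int(rng.integers(8, 11))
        cy = int(rng.integers(r + 2, h - r - 2))
        cx = int(rng.integers(r + 2, w - r - 2))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 6) ** 2 for (y, x), rr in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append(r)
    n_obj = len(centers)

    views = []
    for v in range(n_views):
        masks = []
        for (cy, cx), r in zip(centers, radii):
            if rng.random() < 0.75:
                if rng.random() < 0.5:
                    cy2, cx2 = cy + int(rng.integers(-1, 2)), cx
                else:
                    cy2, cx2 = cy, cx + int(rng.integers(-1, 2))
                masks.append(disc(cy2, cx2, r))
        if rng.random() < 0.3:
            # spurious blob in a view-specific corner slot; never recurs
            masks.append(disc(5 + 12 * v, 5, 4))
        views.append(InstanceSet(masks, shape=canvas, view_id=v))
    return views


# ---------------------------------------------------------------------------
# mAP matching oracle

def oracle_dsb_map(pred, gt, thresholds):
    """Per-threshold maximum-TP assignment by exhaustive enumeration."""
    if len(pred) == 0 and len(gt) == 0:
        return 1.0
    if len(pred) == 0 or len(gt) == 0:
        return 0.0
    n_p, n_g = len(pred), len(gt)
    table = np.array([[brute_iou(p, g) for g in gt.masks] for p in pred.masks])
    total = 0.0
    for t in thresholds:
        ok = table > t
        best_tp = 0
        k = min(n_p, n_g)
        preds = range(n_p)
        for size in range(k, 0, -1):
            if best_tp:
                break
            for p_subset in itertools.combinations(preds, size):
                for g_subset in itertools.permutations(range(n_g), size):
                    if all(ok[p, g] for p, g in zip(p_subset, g_subset)):
                        best_tp = size
                        break
                if best_tp:
                    break
        total += best_tp / (n_p + n_g - best_tp)
    return total / len(thresholds)


# ---------------------------------------------------------------------------
# paired-test oracle

def permutation_sign_test(deltas, n_resamples=2000, seed=0):
    """Two-sided sign-flip permutation p-value for mean(delta) = 0."""
    rng = np.random.default_rng(seed)
    deltas = np.asarray(deltas, dtype=float)
    observed = abs(deltas.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, deltas.size))
    stats = np.abs((signs * deltas).mean(axis=1))
    return (1 + (stats >= observed).sum()) / (1 + n_resamples)
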