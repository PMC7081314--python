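"""Seeded simulator of nuclei-like scenes and imperfect per-view predictions.

``generate_scene`` packs disjoint filled ellipses onto a canvas (default
512 x 512) as ground truth.  ``corrupt_instances`` emulates an imperfect
detector: objects are randomly dropped, their boundaries dilated or eroded,
and spurious objects added away from the ground truth.
``make_equivariant_predictor`` wraps both into a predictor usable by the
TTA engine, with noise drawn independently per view (the regime where
merging helps) or shared across views (a negative control where merging
provably cannot help).

All randomness flows through ``numpy.random.default_rng`` seeded from
explicit integers, and instance-mode corruption uses integer-grid
morphology only, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .geometry import Transform, apply
from .instances import InstanceSet

__all__ = [
    "SceneSpec",
    "NoiseSpec",
    "SceneGenerationError",
    "generate_scene",
    "corrupt_instances",
    "render_probmap",
    "SimulatedPredictor",
    "make_equivariant_predictor",
]

_MIN_OBJECT_AREA = 20


class SceneGenerationError(RuntimeError):
    """Raised when a feasible object packing cannot be found."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic ground-truth scene.

    ``axis_range`` bounds the ellipse semi-axes in pixels; ``min_gap`` is
    the minimum pixel separation between objects.
    """

    canvas: tuple[int, int] = (512, 512)
    n_objects: int = 25
    axis_range: tuple[float, float] = (8.0, 20.0)
    min_gap: int = 3
    seed: int = 0
    max_tries_per_object: int = 200

    def __post_init__(self):
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        lo, hi = self.axis_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid axis_range {self.axis_range}")


@dataclass(frozen=True)
class NoiseSpec:
    """Detector-imperfection parameters for one simulated predictor.

    ``p_missed`` — probability an object is absent from a view;
    ``spurious_rate`` — expected count of false objects per view;
    ``jitter_radius`` — maximum boundary dilation/erosion in pixels;
    ``prob_blur_sigma`` / ``prob_noise_std`` — softening and additive pixel
    noise for probability-map output.
    """

    p_missed: float = 0.0
    spurious_rate: float = 0.0
    jitter_radius: int = 0
    prob_blur_sigma: float = 0.0
    prob_noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_missed <= 1.0:
            raise ValueError("p_missed must be in [0, 1]")
        if self.spurious_rate < 0 or self.jitter_radius < 0:
            raise ValueError("rates and radii must be >= 0")
        if self.prob_blur_sigma < 0 or self.prob_noise_std < 0:
            raise ValueError("sigma and noise std must be >= 0")


def _place_ellipse(rng, canvas, axis_range, blocked, max_tries, min_area=_MIN_OBJECT_AREA):
    """Sample one ellipse mask disjoint from ``blocked``; None on failure."""
    h, w = canvas
    lo, hi = axis_range
    for _ in range(max_tries):
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        angle = rng.uniform(0.0, np.pi)
        margin = float(max(a, b)) + 2.0
        if 2 * margin >= h or 2 * margin >= w:
            continue
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=canvas, rotation=angle)
        if rr.size < min_area:
            continue
        mask = np.zeros(canvas, dtype=bool)
        mask[rr, cc] = True
        if (mask & blocked).any():
            continue
        return mask
    return None


def generate_scene(spec: SceneSpec) -> InstanceSet:
    """Generate a ground-truth scene of disjoint filled ellipses.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`SceneGenerationError` when the packing is infeasible within the
    retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = tuple(int(c) for c in spec.canvas)
    blocked = np.zeros(canvas, dtype=bool)
    gap = ndimage.generate_binary_structure(2, 2)  # 8-connected unit dilation
    masks = []
    for i in range(spec.n_objects):
        mask = _place_ellipse(
            rng, canvas, spec.axis_range, blocked, spec.max_tries_per_object
        )
        if mask is None:
            raise SceneGenerationError(
                f"could not place object {i + 1}/{spec.n_objects} within "
                f"{spec.max_tries_per_object} tries"
            )
        masks.append(mask)
        zone = mask
        if spec.min_gap > 0:
            zone = ndimage.binary_dilation(mask, structure=gap, iterations=spec.min_gap)
        blocked |= zone
    return InstanceSet(masks, shape=canvas, view_id="gt")


def _jitter(mask: np.ndarray, radius: int, rng) -> np.ndarray:
    """Randomly dilate or erode a mask by up to ``radius`` steps.

    Erosion that would empty the mask falls back to the original.
    """
    if radius == 0:
        return mask
    k = int(rng.integers(-radius, radius + 1))
    if k == 0:
        return mask
    struct = ndimage.generate_binary_structure(2, 1)
    if k > 0:
        return ndimage.binary_dilation(mask, structure=struct, iterations=k)
    out = ndimage.binary_erosion(mask, structure=struct, iterations=-k)
    return out if out.any() else mask


def corrupt_instances(
    gt: InstanceSet, noise: NoiseSpec, view_seed: int, spurious_gap: int = 10
) -> InstanceSet:
    """Emulate one view's imperfect instance prediction of ``gt``.

    Each object is dropped with probability ``p_missed``; survivors get
    boundary jitter; ``Poisson(spurious_rate)`` fake objects are added at
    least ``spurious_gap`` pixels from any ground-truth object (so they can
    never IoU-match a true object group).  Deterministic per
    ``(noise.seed, view_seed)``.
    """
    rng = np.random.default_rng([noise.seed, view_seed])
    out = []
    for mask in gt.masks:
        u = rng.random()
        jittered = _jitter(mask, noise.jitter_radius, rng)
        if u < noise.p_missed:
            continue
        out.append(jittered)
    n_spurious = int(rng.poisson(noise.spurious_rate)) if noise.spurious_rate > 0 else 0
    if n_spurious:
        blocked = gt.foreground()
        pad = spurious_gap + noise.jitter_radius
        if pad > 0 and blocked.any():
            blocked = ndimage.binary_dilation(
                blocked,
                structure=ndimage.generate_binary_structure(2, 2),
                iterations=pad,
            )
        for m in out:  # avoid stacking fakes on already-emitted objects
            blocked = blocked | m
        for _ in range(n_spurious):
            fake = _place_ellipse(rng, gt.shape, (3.0, 7.0), blocked, max_tries=50)
            if fake is None:
                continue
            out.append(fake)
            blocked = blocked | fake
    return InstanceSet(out, shape=gt.shape, view_id=f"view{view_seed}")


def render_probmap(instances: InstanceSet, noise: NoiseSpec, rng=None) -> np.ndarray:
    """Render an instance set as a soft foreground probability map.

    The binary foreground is blurred with ``prob_blur_sigma`` and, when an
    ``rng`` is given, perturbed with Gaussian pixel noise of std
    ``prob_noise_std``; the result is clipped to [0, 1].
    """
    fg = instances.foreground().astype(np.float64)
    if noise.prob_blur_sigma > 0:
        fg = ndimage.gaussian_filter(fg, sigma=noise.prob_blur_sigma)
    if rng is not None and noise.prob_noise_std > 0:
        fg = fg + rng.normal(0.0, noise.prob_noise_std, size=fg.shape)
    return np.clip(fg, 0.0, 1.0)


class SimulatedPredictor:
    """A stand-in for a segmentation network during TTA.

    Given the transformed test image, the view index and the transform, it
    transforms the hidden ground truth into the view's frame, corrupts it
    with view-specific randomness and returns either an
    :class:`InstanceSet` or a probability map in that frame, ready for
    dis-augmentation.

    With ``shared_noise=True`` the corruption is drawn once in the original
    frame and merely transformed per view — a perfectly equivariant
    predictor, under which TTA merging is the identity.
    """

    def __init__(
        self,
        gt: Union[InstanceSet, np.ndarray],
        noise: NoiseSpec,
        mode: str = "instance",
        shared_noise: bool = False,
    ):
        if mode not in ("instance", "semantic"):
            raise ValueError(f"unknown output mode {mode!r}")
        if not isinstance(gt, InstanceSet):
            gt = np.asarray(gt)
            masks = [gt.astype(bool)] if gt.any() else []
            gt = InstanceSet(masks, shape=gt.shape, view_id="gt")
        self.gt = gt
        self.noise = noise
        self.mode = mode
        self.shared_noise = shared_noise
        self._shared_cache: InstanceSet | None = None
        self._shared_prob: np.ndarray | None = None

    def _shared_instances(self) -> InstanceSet:
        if self._shared_cache is None:
            self._shared_cache = corrupt_instances(self.gt, self.noise, view_seed=0)
        return self._shared_cache

    def predict(self, image: np.ndarray, view_index: int, transform: Transform):
        image = np.asarray(image)
        if self.shared_noise:
            inst = self._shared_instances()
            if self.mode == "instance":
                return inst.transform(transform)
            if self._shared_prob is None:
                rng = np.random.default_rng([self.noise.seed, 10_000])
                self._shared_prob = render_probmap(inst, self.noise, rng)
            return apply(transform, self._shared_prob)
        # independent mode: corrupt in the *transformed* frame so per-view
        # errors stay independent after dis-augmentation
        gt_t = self.gt.transform(transform)
        inst = corrupt_instances(gt_t, self.noise, view_seed=view_index)
        if self.mode == "instance":
            return inst
        rng = np.random.default_rng([self.noise.seed, view_index, 10_000])
        return render_probmap(inst, self.noise, rng)

    __call__ = predict


def make_equivariant_predictor(
    gt: Union[InstanceSet, np.ndarray],
    noise: NoiseSpec,
    mode: str = "instance",
    shared_noise: bool = False,
) -> SimulatedPredictor:
    """Build a :class:`SimulatedPredictor` for the given ground truth."""
    return SimulatedPredictor(gt, noise, mode=mode, shared_noise=shared_noise)
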