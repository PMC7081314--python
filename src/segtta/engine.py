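"""Orchestration of the four-step TTA loop: augment, predict, dis-augment, merge.

The engine never inspects pixel content itself; it drives a pluggable
predictor once per view and hands the dis-augmented predictions to the
fusion modules.  Two predictor adapters are provided: an in-process
callable wrapper and a subprocess adapter that shells out to an external
command, so real network predictions can be merged without this package
importing any deep-learning stack.
"""

from __future__ import annotations

import json
import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Protocol, runtime_checkable

import numpy as np
import pandas as pd
import tifffile

from . import io as seg_io
from .geometry import AugmentationSet, Transform, apply, default_augmentation_set, disaugment
from .instances import InstanceSet, merge_instances
from .metrics import compare, dsb_map, pixel_iou
from .semantic import binarize, merge_probmaps

__all__ = [
    "PredictorContract",
    "FunctionPredictor",
    "SubprocessPredictor",
    "ContractViolation",
    "RunConfig",
    "TTAResult",
    "tta_predict",
    "run_batch",
]

log = logging.getLogger("segtta")


class ContractViolation(RuntimeError):
    """A predictor returned output of the wrong kind or shape for a view."""


@runtime_checkable
class PredictorContract(Protocol):
    """What the engine requires of a predictor.

    ``mode`` declares the output kind; ``predict`` receives the already
    transformed image plus the view index and transform, and must return a
    prediction in the same frame as its input.
    """

    mode: str

    def predict(self, image: np.ndarray, view_index: int, transform: Transform): ...


class FunctionPredictor:
    """Wrap a plain ``image -> prediction`` callable as a predictor."""

    def __init__(self, fn: Callable[[np.ndarray], object], mode: str):
        if mode not in ("semantic", "instance"):
            raise ValueError(f"unknown predictor mode {mode!r}")
        self.fn = fn
        self.mode = mode

    def predict(self, image, view_index, transform):
        return self.fn(image)


class SubprocessPredictor:
    """Run an external command per view: ``cmd <input image> <output mask>``.

    Semantic mode expects the command to write a float TIFF probability
    map; instance mode a 16-bit labeled mask.
    """

    def __init__(self, command: list[str], mode: str, workdir: Optional[Path] = None):
        if mode not in ("semantic", "instance"):
            raise ValueError(f"unknown predictor mode {mode!r}")
        self.command = list(command)
        self.mode = mode
        self.workdir = Path(workdir) if workdir else None

    def predict(self, image, view_index, transform):
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            tmp = Path(tmp)
            in_path = tmp / f"view_{view_index}.tif"
            suffix = ".tif" if self.mode == "semantic" else ".png"
            out_path = tmp / f"pred_{view_index}{suffix}"
            tifffile.imwrite(in_path, np.asarray(image))
            subprocess.run(
                [*self.command, str(in_path), str(out_path)], check=True
            )
            if self.mode == "semantic":
                return seg_io.read_probmap(out_path)
            return InstanceSet.from_labels(seg_io.read_labels(out_path))


@dataclass
class RunConfig:
    """Run settings; the defaults reproduce the reference method exactly:
    six views, IoU match threshold 0.5, semantic threshold 0.5."""

    augmentations: AugmentationSet = field(default_factory=default_augmentation_set)
    mode: str = "instance"
    min_iou: float = 0.5
    threshold: float = 0.5
    seed: int = 0
    keep_views: bool = False

    def __post_init__(self):
        if isinstance(self.augmentations, (str, list, tuple)):
            self.augmentations = AugmentationSet.from_names(self.augmentations)
        if self.mode not in ("semantic", "instance"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class TTAResult:
    """Output of one TTA run.

    ``merged`` is the fused prediction; ``original`` is the identity
    view's raw prediction (the no-TTA baseline for delta reporting).  In
    semantic mode ``merged``/``original`` are probability maps and
    ``merged_mask``/``original_mask`` their binarizations; in instance
    mode they are :class:`InstanceSet` objects and the mask fields alias
    them.
    """

    merged: object
    original: object
    merged_mask: object
    original_mask: object
    views: Optional[list] = None


def _check_view_output(pred, mode: str, expected_shape, view_index: int, t: Transform):
    if mode == "semantic":
        if isinstance(pred, InstanceSet) or np.asarray(pred).ndim != 2:
            raise ContractViolation(
                f"view {view_index} ({t.name}): semantic predictor must return a 2-D "
                f"probability map"
            )
        pred = np.asarray(pred, dtype=np.float64)
        shape = pred.shape
    else:
        if not isinstance(pred, InstanceSet):
            raise ContractViolation(
                f"view {view_index} ({t.name}): instance predictor must return an "
                f"InstanceSet, got {type(pred).__name__}"
            )
        shape = pred.shape
    if tuple(shape) != tuple(expected_shape):
        raise ContractViolation(
            f"view {view_index} ({t.name}): prediction canvas {tuple(shape)} does not "
            f"match the transformed image canvas {tuple(expected_shape)}"
        )
    return pred


def tta_predict(
    image: np.ndarray,
    predictor: PredictorContract,
    config: RunConfig | None = None,
) -> TTAResult:
    """Run the full TTA loop on one image.

    For each transform in the augmentation set the image is transformed,
    predicted on, and the prediction reverted to the original frame; the
    per-view predictions are then merged by probability averaging
    (semantic) or IoU matching and majority voting (instance).
    """
    config = config or RunConfig()
    mode = config.mode
    if getattr(predictor, "mode", mode) != mode:
        raise ContractViolation(
            f"predictor mode {predictor.mode!r} does not match run mode {mode!r}"
        )
    image = np.asarray(image)
    canvas = image.shape[:2]

    reverted = []
    for view_index, t in enumerate(config.augmentations):
        aug = apply(t, image)
        pred = predictor.predict(aug, view_index, t)
        pred = _check_view_output(pred, mode, aug.shape[:2], view_index, t)
        reverted.append(disaugment(t, pred, original_shape=canvas))

    original = reverted[0]
    if mode == "semantic":
        merged = merge_probmaps(reverted)
        result = TTAResult(
            merged=merged,
            original=original,
            merged_mask=binarize(merged, config.threshold),
            original_mask=binarize(original, config.threshold),
        )
    else:
        merged = merge_instances(reverted, min_iou=config.min_iou)
        result = TTAResult(
            merged=merged, original=original, merged_mask=merged, original_mask=original
        )
    if config.keep_views:
        result.views = reverted
    return result


_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


def _find_images(directory: Path) -> list[Path]:
    return sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES and p.is_file()
    )


def run_batch(
    image_dir,
    predictor: PredictorContract,
    config: RunConfig,
    out_dir,
    gt_dir=None,
) -> pd.DataFrame:
    """Run TTA over a directory of images; optionally evaluate against GT.

    Images pair with ground-truth mask files by filename stem.  Writes
    merged and original predictions, a per-image CSV
    (image_id, original, merged, delta) and a JSON summary.  Returns the
    per-image table (empty when no GT is supplied).
    """
    image_dir = Path(image_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt_dir = Path(gt_dir) if gt_dir is not None else None

    images = _find_images(image_dir)
    if not images:
        log.warning("no images found in %s", image_dir)

    gt_index: dict[str, Path] = {}
    if gt_dir is not None:
        gt_index = {p.stem: p for p in _find_images(gt_dir)}

    ids, originals, mergeds = [], [], []
    for img_path in images:
        stem = img_path.stem
        image = seg_io.read_image(img_path)
        result = tta_predict(image, predictor, config)

        if config.mode == "semantic":
            seg_io.write_probmap(out_dir / f"{stem}_merged.tif", result.merged)
            seg_io.write_binary_mask(out_dir / f"{stem}_merged.png", result.merged_mask)
            seg_io.write_binary_mask(out_dir / f"{stem}_original.png", result.original_mask)
        else:
            seg_io.write_labels(out_dir / f"{stem}_merged.png", result.merged.to_labels())
            orig = result.original
            if orig.is_disjoint():
                seg_io.write_labels(out_dir / f"{stem}_original.png", orig.to_labels())
            log.info(
                "%s: %d objects in original view, %d kept after merge",
                stem, len(orig), len(result.merged),
            )

        if gt_dir is not None:
            gt_path = gt_index.get(stem)
            if gt_path is None:
                log.warning("no ground-truth mask for %s; skipped from evaluation", stem)
                continue
            if config.mode == "semantic":
                gt_mask = seg_io.read_binary_mask(gt_path)
                o = pixel_iou(result.original_mask, gt_mask)
                m = pixel_iou(result.merged_mask, gt_mask)
            else:
                gt_set = InstanceSet.from_labels(seg_io.read_labels(gt_path))
                o = dsb_map(result.original, gt_set)
                m = dsb_map(result.merged, gt_set)
            ids.append(stem)
            originals.append(o)
            mergeds.append(m)

    table = pd.DataFrame(
        {
            "image_id": ids,
            "original": originals,
            "merged": mergeds,
            "delta": np.asarray(mergeds) - np.asarray(originals)
            if ids
            else np.array([]),
        }
    )
    table.to_csv(out_dir / "scores.csv", index=False)

    summary: dict = {"n_images": len(images), "n_evaluated": len(ids)}
    if ids:
        cmp = compare(originals, mergeds, ids)
        summary.update(
            mean_original=float(np.mean(originals)),
            mean_merged=float(np.mean(mergeds)),
            mean_delta=cmp.mean_delta,
            median_delta=cmp.median_delta,
            wilcoxon_p=cmp.p_value,
            degenerate=cmp.degenerate,
        )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return table
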