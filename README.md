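# segtta

Predictor-agnostic **test-time augmentation (TTA)** for microscopy
segmentation. The pipeline has four stages: *augment* a test image with
invertible dihedral transforms, *predict* on every view with a pluggable
predictor, *dis-augment* (revert) each prediction to the original frame,
and *merge* the per-view predictions into one output:

- **Semantic mode** (U-Net-style probability maps): element-wise averaging
  of the dis-augmented maps, then a single binarization at 0.5.
- **Instance mode** (Mask R-CNN-style labeled masks): objects are matched
  across views by mask IoU (threshold 0.5, greedy best match, seeded in
  rounds starting from the original view), kept when present in a strict
  majority of views, and fused by per-pixel majority voting over the
  matched masks.

The package also ships the two evaluation metrics used to quantify the TTA
benefit — the DSB-style per-image mAP over IoU thresholds 0.50–0.95 and
pixel-level IoU — plus a paired Wilcoxon comparison of merged-vs-original
scores, and a seeded synthetic-scene simulator so the whole method can be
exercised and tested without trained networks or datasets.

## Library usage

```python
import numpy as np
from segtta import (
    SceneSpec, NoiseSpec, RunConfig,
    generate_scene, make_equivariant_predictor, tta_predict,
)
from segtta.metrics import dsb_map

scene = generate_scene(SceneSpec(canvas=(512, 512), n_objects=25, seed=1))
noise = NoiseSpec(p_missed=0.15, spurious_rate=0.5, jitter_radius=2, seed=2)
predictor = make_equivariant_predictor(scene, noise, mode="instance")

result = tta_predict(np.zeros((512, 512), np.uint8), predictor, RunConfig(mode="instance"))
print(dsb_map(result.original, scene), "->", dsb_map(result.merged, scene))
```

Any object with a `mode` attribute (`"semantic"` or `"instance"`) and a
`predict(image, view_index, transform)` method works as a predictor;
`FunctionPredictor` adapts a plain `image -> prediction` callable and
`SubprocessPredictor` shells out to an external command per view, so real
network predictions can be merged without this package importing a deep
learning stack.

## Command line

The console script is `tta` (see `tta --help` and each subcommand's
`--help` for all options):

```bash
# synthetic scenes + per-view noisy predictions (already dis-augmented)
tta simulate --out sim/ --n-scenes 3 --n-objects 25 --seed 1

# merge-only reruns on directories of per-view files
tta merge-instance --views sim_views/ --out merged.png --min-iou 0.5
tta merge-semantic --views prob_views/ --out merged.png --threshold 0.5

# full TTA loop around an external predictor command
tta predict --images imgs/ --gt gt/ --out out/ \
    --predictor-cmd "python my_model.py" --mode instance

# score original vs merged predictions against ground truth
tta evaluate --gt gt/ --original orig/ --merged merged/ --mode instance --out eval/
```

File conventions: labeled instance masks are 16-bit PNG/TIFF (0 =
background), probability maps 32-bit float TIFF, binary masks 8-bit PNG;
reports are CSV (per image) and JSON (summary). A DSB-dialect run-length
CSV writer is available in `segtta.io`.

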