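import hashlib

import numpy as np
import pytest

from segtta import (
    FunctionPredictor,
    InstanceSet,
    NoiseSpec,
    RunConfig,
    SceneSpec,
    generate_scene,
    make_equivariant_predictor,
    run_batch,
    tta_predict,
)
from segtta import io as seg_io
from segtta.engine import ContractViolation
from segtta.geometry import AugmentationSet, default_augmentation_set


class RecordingPredictor:
    """Mock: returns the transformed gt foreground; records every call."""

    def __init__(self, gt, mode="semantic"):
        self.gt = gt
        self.mode = mode
        self.calls = []

    def predict(self, image, view_index, transform):
        self.calls.append((view_index, transform.name, image.shape))
        if self.mode == "semantic":
            return self.gt.transform(transform).foreground().astype(float)
        return self.gt.transform(transform)


class TestRunConfig:
    def test_defaults_match_reference_settings(self):
        cfg = RunConfig()
        assert len(cfg.augmentations) == 6
        assert cfg.min_iou == 0.5
        assert cfg.threshold == 0.5

    def test_augmentations_from_string(self):
        cfg = RunConfig(augmentations="identity,hflip")
        assert len(cfg.augmentations) == 2

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            RunConfig(mode="both")


class TestTtaPredict:
    def test_one_call_per_transform(self, small_scene):
        predictor = RecordingPredictor(small_scene)
        tta_predict(np.zeros(small_scene.shape, np.uint8), predictor,
                    RunConfig(mode="semantic"))
        assert [c[0] for c in predictor.calls] == list(range(6))
        assert [c[1] for c in predictor.calls] == [
            t.name for t in default_augmentation_set()
        ]
        assert all(c[2] == small_scene.shape for c in predictor.calls)

    def test_rectangular_image_shapes_passed_transformed(self, make_disk_set):
        gt = make_disk_set((64, 96), [(32, 48, 10)])
        predictor = RecordingPredictor(gt)
        tta_predict(np.zeros((64, 96), np.uint8), predictor, RunConfig(mode="semantic"))
        shapes = {name: shape for _, name, shape in predictor.calls}
        assert shapes["identity"] == (64, 96)
        assert shapes["rot90"] == (96, 64)

    def test_identity_only_merged_equals_original(self, small_scene, default_noise):
        cfg = RunConfig(mode="instance", augmentations=AugmentationSet(["identity"]))
        predictor = make_equivariant_predictor(small_scene, default_noise)
        res = tta_predict(np.zeros(small_scene.shape, np.uint8), predictor, cfg)
        assert res.merged == res.original

    def test_mode_mismatch_rejected(self, small_scene):
        predictor = RecordingPredictor(small_scene, mode="instance")
        with pytest.raises(ContractViolation, match="mode"):
            tta_predict(np.zeros(small_scene.shape, np.uint8), predictor,
                        RunConfig(mode="semantic"))

    def test_wrong_output_kind_names_view(self, small_scene):
        class Bad:
            mode = "instance"

            def predict(self, image, view_index, transform):
                return np.zeros(image.shape[:2])  # probmap, not InstanceSet

        with pytest.raises(ContractViolation, match="view 0"):
            tta_predict(np.zeros(small_scene.shape, np.uint8), Bad(),
                        RunConfig(mode="instance"))

    def test_wrong_shape_names_view(self, small_scene):
        class OffByOne:
            mode = "semantic"

            def predict(self, image, view_index, transform):
                return np.zeros((image.shape[0] + 1, image.shape[1]))

        with pytest.raises(ContractViolation, match="view 0"):
            tta_predict(np.zeros(small_scene.shape, np.uint8), OffByOne(),
                        RunConfig(mode="semantic"))

    def test_keep_views(self, small_scene):
        predictor = RecordingPredictor(small_scene)
        res = tta_predict(np.zeros(small_scene.shape, np.uint8), predictor,
                          RunConfig(mode="semantic", keep_views=True))
        assert res.views is not None and len(res.views) == 6

    def test_function_predictor_adapter(self, small_scene):
        fg = small_scene.foreground().astype(float)

        def fn(image):
            # equivariant only for the identity; restrict the set
            return fg

        cfg = RunConfig(mode="semantic", augmentations=AugmentationSet(["identity"]))
        res = tta_predict(np.zeros(small_scene.shape, np.uint8),
                          FunctionPredictor(fn, "semantic"), cfg)
        assert np.array_equal(res.merged, fg)

    def test_golden_instance_regression(self):
        scene = generate_scene(
            SceneSpec(canvas=(128, 128), n_objects=10, axis_range=(5, 9), seed=42)
        )
        noise = NoiseSpec(p_missed=0.15, spurious_rate=0.5, jitter_radius=2, seed=7)
        predictor = make_equivariant_predictor(scene, noise)
        res = tta_predict(np.zeros((128, 128), np.uint8), predictor,
                          RunConfig(mode="instance"))
        labels = res.merged.to_labels()
        assert len(res.merged) == 8
        assert (
            hashlib.sha256(labels.tobytes()).hexdigest()
            == "f613df2b434ca0fa16524814c8b348e55a3cdace8163e7e0f86eeab1e51a5c0e"
        )


def _write_scene_files(tmp_path, n=3, mode="instance"):
    images = tmp_path / "images"
    gts = tmp_path / "gt"
    images.mkdir()
    gts.mkdir()
    scenes = []
    for i in range(n):
        scene = generate_scene(
            SceneSpec(canvas=(96, 96), n_objects=5, axis_range=(5, 8), seed=100 + i)
        )
        scenes.append(scene)
        seg_io.write_labels(images / f"img_{i}.png", np.zeros((96, 96), np.uint16))
        if mode == "instance":
            seg_io.write_labels(gts / f"img_{i}.png", scene.to_labels())
        else:
            seg_io.write_binary_mask(gts / f"img_{i}.png", scene.foreground())
    return images, gts, scenes


class ScenePredictor:
    """Per-image predictor for batch tests: keyed off the call counter."""

    def __init__(self, scenes, noise, mode="instance"):
        self.mode = mode
        self.scenes = scenes
        self.noise = noise
        self.image_idx = -1
        self.view_count = 0

    def predict(self, image, view_index, transform):
        if view_index == 0:
            self.image_idx += 1
        inner = make_equivariant_predictor(
            self.scenes[self.image_idx], self.noise, mode=self.mode
        )
        return inner.predict(image, view_index, transform)


class TestRunBatch:
    def test_empty_directory(self, tmp_path):
        (tmp_path / "images").mkdir()
        predictor = RecordingPredictor(InstanceSet([], shape=(8, 8)))
        table = run_batch(tmp_path / "images", predictor,
                          RunConfig(mode="semantic"), tmp_path / "out")
        assert len(table) == 0
        assert (tmp_path / "out" / "summary.json").exists()

    def test_three_image_batch_with_gt(self, tmp_path, default_noise):
        images, gts, scenes = _write_scene_files(tmp_path)
        predictor = ScenePredictor(scenes, default_noise)
        table = run_batch(images, predictor, RunConfig(mode="instance"),
                          tmp_path / "out", gt_dir=gts)
        assert len(table) == 3
        assert set(table.columns) == {"image_id", "original", "merged", "delta"}
        assert (tmp_path / "out" / "scores.csv").exists()
        for i in range(3):
            assert (tmp_path / "out" / f"img_{i}_merged.png").exists()

    def test_unpaired_gt_skipped_but_predicted(self, tmp_path, default_noise, caplog):
        images, gts, scenes = _write_scene_files(tmp_path)
        (gts / "img_2.png").unlink()
        predictor = ScenePredictor(scenes, default_noise)
        table = run_batch(images, predictor, RunConfig(mode="instance"),
                          tmp_path / "out", gt_dir=gts)
        assert len(table) == 2
        assert (tmp_path / "out" / "img_2_merged.png").exists()

    def test_rerun_is_deterministic(self, tmp_path, default_noise):
        images, gts, scenes = _write_scene_files(tmp_path, n=2)
        t1 = run_batch(images, ScenePredictor(scenes, default_noise),
                       RunConfig(mode="instance"), tmp_path / "out1", gt_dir=gts)
        t2 = run_batch(images, ScenePredictor(scenes, default_noise),
                       RunConfig(mode="instance"), tmp_path / "out2", gt_dir=gts)
        assert t1.equals(t2)
        a = (tmp_path / "out1" / "img_0_merged.png").read_bytes()
        b = (tmp_path / "out2" / "img_0_merged.png").read_bytes()
        assert a == b

    def test_semantic_batch(self, tmp_path, default_noise):
        images, gts, scenes = _write_scene_files(tmp_path, mode="semantic")
        predictor = ScenePredictor(scenes, default_noise, mode="semantic")
        table = run_batch(images, predictor, RunConfig(mode="semantic"),
                          tmp_path / "out", gt_dir=gts)
        assert len(table) == 3
        assert ((table.original >= 0) & (table.original <= 1)).all()
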