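import numpy as np
import pytest

from segtta import InstanceSet, NoiseSpec, SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene():
    """A deterministic 10-object ground-truth scene on a 128x128 canvas."""
    return generate_scene(
        SceneSpec(canvas=(128, 128), n_objects=10, axis_range=(5, 9), seed=42)
    )


@pytest.fixture
def default_noise():
    return NoiseSpec(
        p_missed=0.15, spurious_rate=0.5, jitter_radius=2,
        prob_blur_sigma=1.0, prob_noise_std=0.05, seed=7,
    )


def disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture
def make_disk_set():
    """Factory for InstanceSets of circles: make_disk_set(shape, [(cy,cx,r), ...])."""

    def _make(shape, disks, view_id=None):
        return InstanceSet(
            [disk_mask(shape, (cy, cx), r) for cy, cx, r in disks],
            shape=shape,
            view_id=view_id,
        )

    return _make
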