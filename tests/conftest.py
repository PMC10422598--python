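import numpy as np
import pytest

from soyemerge import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def dense_scene():
    """One realistic-density mixed-stage scene with its ground truth."""
    cfg = SceneConfig(seed=11, stage_mix=(0.5, 0.3, 0.2))
    return generate_scene(cfg)


def make_solid_crops(rng, labels_counts, noise=25.0):
    """Trivially separable crops: one base colour per class plus pixel noise."""
    bases = np.array([[190, 70, 70], [70, 190, 70], [70, 70, 190]])
    xs, ys = [], []
    for label, n in labels_counts:
        block = bases[label][None, None, None, :] + rng.normal(0, noise, (n, 255, 255, 3))
        xs.append(np.clip(block, 0, 255).astype(np.uint8))
        ys.append(np.full(n, label, dtype=np.int64))
    return np.concatenate(xs), np.concatenate(ys)
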