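import numpy as np
import pytest

import reefquad as rq


@pytest.fixture(scope="session")
def coral_sand_scene():
    """Frameless 50/50 coral-sand scene with exact ground-truth counts."""
    spec = rq.SceneSpec(
        width_px=360,
        height_px=360,
        class_fractions={"SC": 0.5, "SAND": 0.5},
        frame_present=False,
        seed=42,
    )
    return rq.render_quadrat(spec)


@pytest.fixture(scope="session")
def coral_sand_30_70():
    spec = rq.SceneSpec(
        width_px=360,
        height_px=360,
        class_fractions={"SC": 0.3, "SAND": 0.7},
        frame_present=False,
        seed=7,
    )
    return rq.render_quadrat(spec)


@pytest.fixture(scope="session")
def rotated_frame_scene():
    spec = rq.SceneSpec(frame_rotation_deg=7.0, seed=1)
    return rq.render_quadrat(spec)


def finalize_with_truth(points, truth, accuracy=0.85, seed=0, threshold=0.5):
    """Run the full machine + manual annotation workflow against truth."""
    drafts = rq.simulated_classifier(points, truth, accuracy=accuracy, seed=seed)
    auto, queue = rq.gate_annotations(drafts, threshold)
    return auto + rq.manual_from_truth(queue, truth)


@pytest.fixture
def finalize():
    return finalize_with_truth


def make_uniform_image(value=100, shape=(64, 64)):
    return np.full(shape + (3,), value, dtype=np.uint8)
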