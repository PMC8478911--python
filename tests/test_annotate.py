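"""Point generation, confidence gating and the simulated annotator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import reefquad as rq
from reefquad.annotate import PointAnnotation


def test_forced_single_pixel():
    assert rq.generate_points((1, 1), 1, seed=0) == [(0, 0)]


def test_25_points_distinct_and_in_bounds(coral_sand_scene):
    img, _ = coral_sand_scene
    pts = rq.generate_points(img, 25, seed=1)
    assert len(set(pts)) == 25
    assert all(0 <= r < img.shape[0] and 0 <= c < img.shape[1] for r, c in pts)


def test_too_many_points_rejected():
    with pytest.raises(ValueError):
        rq.generate_points((4, 4), 17, seed=0)


def test_point_sampling_binomial_oracle(coral_sand_scene):
    """1e5 uniform points over a 50/50 scene land on coral with frequency
    0.5 within 3 binomial SE."""
    img, truth = coral_sand_scene
    pts = rq.generate_points(img, 100_000, seed=3)
    frac = np.mean([truth.label_at(r, c) == "SC" for r, c in pts])
    sigma = np.sqrt(0.25 / 100_000)
    assert abs(frac - truth.class_fractions_interior["SC"]) <= 3 * sigma


def test_point_sampling_uniform_chi_square(coral_sand_scene):
    """Counts pooled over seeds in a 4x4 grid of cells pass a chi-square
    goodness-of-fit test at alpha=0.01."""
    img, _ = coral_sand_scene
    h, w = img.shape[:2]
    counts = np.zeros((4, 4))
    for seed in range(5):
        for r, c in rq.generate_points(img, 10_000, seed=seed):
            counts[min(r * 4 // h, 3), min(c * 4 // w, 3)] += 1
    _, p = stats.chisquare(counts.ravel())
    assert p > 0.01


def _draft(conf, label="SC"):
    return PointAnnotation("img", 0, 0, machine_label=label, machine_confidence=conf)


def test_gate_rule_with_tie_at_threshold():
    drafts = [_draft(0.6), _draft(0.4), _draft(0.5)]
    auto, queue = rq.gate_annotations(drafts, threshold=0.5)
    assert [p.machine_confidence for p in auto] == [0.6, 0.5]
    assert [p.machine_confidence for p in queue] == [0.4]
    assert all(p.status == "auto" and p.final_label == "SC" for p in auto)


def test_gate_certain_classifier_empty_queue():
    auto, queue = rq.gate_annotations([_draft(1.0)] * 5)
    assert len(auto) == 5 and not queue


def test_gate_manual_only_mode():
    auto, queue = rq.gate_annotations([_draft(0.99), _draft(0.3)], threshold=1.0)
    assert not auto and len(queue) == 2


def test_gate_missing_confidence_errors():
    with pytest.raises(ValueError, match="confidence"):
        rq.gate_annotations([PointAnnotation("img", 0, 0, machine_label="SC")])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_gate_partition_exhaustive_and_exclusive(confs):
    auto, queue = rq.gate_annotations([_draft(c) for c in confs])
    assert len(auto) + len(queue) == len(confs)


def test_perfect_classifier_matches_truth_exactly(coral_sand_30_70):
    img, truth = coral_sand_30_70
    pts = rq.generate_points(img, 500, seed=5)
    drafts = rq.simulated_classifier(pts, truth, accuracy=1.0, seed=0)
    auto, queue = rq.gate_annotations(drafts)
    labels = [p.final_label for p in auto] + [
        truth.label_at(p.row, p.col) for p in queue
    ]
    want = [truth.label_at(r, c) for r, c in pts]
    assert sorted(labels) == sorted(want)
    assert all(p.final_label == truth.label_at(p.row, p.col) for p in auto)


def test_classifier_accuracy_binomial_oracle(coral_sand_30_70):
    img, truth = coral_sand_30_70
    pts = rq.generate_points(img, 10_000, seed=6)
    drafts = rq.simulated_classifier(pts, truth, accuracy=0.8, seed=1)
    agree = np.mean(
        [p.machine_label == truth.label_at(p.row, p.col) for p in drafts]
    )
    sigma = np.sqrt(0.8 * 0.2 / 10_000)
    assert abs(agree - 0.8) <= 3 * sigma


def test_classifier_deterministic(coral_sand_scene):
    img, truth = coral_sand_scene
    pts = rq.generate_points(img, 50, seed=2)
    a = rq.simulated_classifier(pts, truth, accuracy=0.7, seed=9)
    b = rq.simulated_classifier(pts, truth, accuracy=0.7, seed=9)
    assert a == b


def test_overall_confidence_rules():
    manual = PointAnnotation(
        "i", 0, 0, manual_label="SC", final_label="SC", status="manual"
    )
    auto = PointAnnotation(
        "i", 0, 1, machine_label="SC", machine_confidence=0.8,
        final_label="SC", status="auto",
    )
    assert rq.overall_confidence([manual, manual]) == 1.0
    assert rq.overall_confidence([auto, manual]) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        rq.overall_confidence([])
    with pytest.raises(ValueError, match="finalized"):
        rq.overall_confidence([_draft(0.6)])


def test_annotation_csv_round_trip(tmp_path, coral_sand_scene, finalize):
    img, truth = coral_sand_scene
    pts = rq.generate_points(img, 25, seed=8)
    finalized = finalize(pts, truth, seed=4)
    path = tmp_path / "ann.csv"
    rq.write_annotation_csv(finalized, path)
    back = rq.read_annotation_csv(path)
    orig = {(p.image_id, p.row, p.col): (p.final_label, p.status) for p in finalized}
    got = {(p.image_id, p.row, p.col): (p.final_label, p.status) for p in back}
    assert orig == got
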