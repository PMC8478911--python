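"""Point generation and confidence-gated annotation.

Cover is estimated by classifying the benthos under randomly placed
points.  A machine annotator proposes a label and a confidence for each
point; points at or above the confidence threshold (default 0.5) are
scored automatically and the rest are queued for a human.  The overall
confidence of a finished image is the mean machine confidence with
manually scored points counted at 1.0.

A simulated classifier stands in for a real CNN annotator: it reproduces
ground-truth labels at a configurable accuracy, drawing confidences from
separate beta distributions for correct and incorrect calls, so the whole
workflow can be exercised end-to-end with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .schema import DEFAULT_SCHEMA, LabelSchema
from .synthetic import GroundTruth

ANNOTATION_COLUMNS = ["Name", "Row", "Column", "Label", "Machine confidence"]


@dataclass(frozen=True)
class PointAnnotation:
    """One sampled point.  Drafts carry machine output only; finalized
    points have ``final_label`` set and ``status`` of "auto" (machine
    confidence at/above the gate) or "manual" (human scored)."""

    image_id: str
    row: int
    col: int
    machine_label: str | None = None
    machine_confidence: float | None = None
    manual_label: str | None = None
    final_label: str | None = None
    status: str | None = None

    @property
    def finalized(self) -> bool:
        return self.final_label is not None and self.status in ("auto", "manual")


def generate_points(
    img, n_points: int = 25, seed: int = 0
) -> list[tuple[int, int]]:
    """Draw ``n_points`` pixel positions uniformly without replacement.

    ``img`` may be an image array or an ``(height, width)`` pair.
    """
    if hasattr(img, "shape"):
        h, w = img.shape[:2]
    else:
        h, w = img
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_points > h * w:
        raise ValueError("more points than pixels requested")
    rng = np.random.default_rng(seed)
    flat = rng.choice(h * w, size=n_points, replace=False)
    return [(int(f // w), int(f % w)) for f in flat]


class SimulatedPointClassifier(BaseEstimator):
    """Test stand-in for a trained machine annotator.

    Predicts the ground-truth label with probability ``accuracy`` and a
    uniformly chosen wrong benthic label otherwise.  Confidence is drawn
    from Beta(*correct_conf*) for correct calls and Beta(*incorrect_conf*)
    for wrong ones.  The defaults describe a classifier that is confident
    when right and uncertain when wrong, so the mixed auto/manual workflow
    runs at roughly 92% overall confidence — the operating point of a
    trained machine annotator in routine reef monitoring.
    """

    def __init__(
        self,
        accuracy: float = 0.85,
        correct_conf: tuple[float, float] = (28.0, 2.0),
        incorrect_conf: tuple[float, float] = (4.0, 4.0),
        schema: LabelSchema = DEFAULT_SCHEMA,
        seed: int = 0,
    ):
        self.accuracy = accuracy
        self.correct_conf = correct_conf
        self.incorrect_conf = incorrect_conf
        self.schema = schema
        self.seed = seed

    def fit(self, X=None, y=None) -> "SimulatedPointClassifier":
        if not 0 < self.accuracy <= 1:
            raise ValueError("accuracy must lie in (0, 1]")
        return self

    def predict(
        self,
        points: list[tuple[int, int]],
        truth: GroundTruth,
        image_id: str = "image",
    ) -> list[PointAnnotation]:
        """Attach machine labels and confidences to raw point positions."""
        self.fit()
        rng = np.random.default_rng(self.seed)
        benthic = self.schema.benthic_codes
        out = []
        for row, col in points:
            true_label = truth.label_at(row, col) or "UNID"
            correct = rng.random() < self.accuracy
            if correct or true_label not in benthic:
                label = true_label
            else:
                others = [c for c in benthic if c != true_label]
                label = others[rng.integers(len(others))]
            a, b = self.correct_conf if correct else self.incorrect_conf
            conf = float(rng.beta(a, b))
            out.append(
                PointAnnotation(
                    image_id=image_id,
                    row=row,
                    col=col,
                    machine_label=label,
                    machine_confidence=conf,
                )
            )
        return out


def simulated_classifier(
    points,
    truth: GroundTruth,
    accuracy: float = 0.85,
    seed: int = 0,
    image_id: str = "image",
    **kwargs,
) -> list[PointAnnotation]:
    """Functional wrapper over :class:`SimulatedPointClassifier`."""
    clf = SimulatedPointClassifier(accuracy=accuracy, seed=seed, **kwargs)
    return clf.predict(points, truth, image_id=image_id)


def gate_annotations(
    points: list[PointAnnotation], threshold: float = 0.5
) -> tuple[list[PointAnnotation], list[PointAnnotation]]:
    """Partition drafts into auto-scored points and a manual queue.

    Points with confidence at or above the threshold are finalized with
    their machine label (ties go to the machine); the rest await a human.
    The partition is exhaustive and exclusive.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    auto, queue = [], []
    for p in points:
        if p.machine_confidence is None:
            raise ValueError(f"point ({p.row}, {p.col}) has no machine confidence")
        if p.machine_confidence >= threshold:
            auto.append(replace(p, final_label=p.machine_label, status="auto"))
        else:
            queue.append(p)
    return auto, queue


def apply_manual_labels(
    queue: list[PointAnnotation], labels: list[str]
) -> list[PointAnnotation]:
    """Finalize queued points with human-assigned labels."""
    if len(labels) != len(queue):
        raise ValueError("one label per queued point required")
    return [
        replace(p, manual_label=lab, final_label=lab, status="manual")
        for p, lab in zip(queue, labels)
    ]


def manual_from_truth(
    queue: list[PointAnnotation], truth: GroundTruth
) -> list[PointAnnotation]:
    """Finalize a queue using ground truth as the (perfect) human scorer."""
    return apply_manual_labels(
        queue, [truth.label_at(p.row, p.col) or "UNID" for p in queue]
    )


def overall_confidence(points: list[PointAnnotation]) -> float:
    """Mean machine confidence with manual points counted at 1.0."""
    if not points:
        raise ValueError("no points given")
    vals = []
    for p in points:
        if not p.finalized:
            raise ValueError("all points must be finalized first")
        vals.append(1.0 if p.status == "manual" else float(p.machine_confidence))
    return float(np.mean(vals))


# --------------------------------------------------------------------- CSV


def points_to_frame(points: list[PointAnnotation]) -> pd.DataFrame:
    """Annotation table in the common machine-annotation export dialect
    (Name, Row, Column, Label, Machine confidence)."""
    return pd.DataFrame(
        {
            "Name": [p.image_id for p in points],
            "Row": [p.row for p in points],
            "Column": [p.col for p in points],
            "Label": [p.final_label if p.final_label else p.machine_label for p in points],
            "Machine confidence": [p.machine_confidence for p in points],
        }
    )


def write_annotation_csv(points: list[PointAnnotation], path) -> None:
    points_to_frame(points).to_csv(path, index=False, encoding="utf-8")


def read_annotation_csv(path, threshold: float = 0.5) -> list[PointAnnotation]:
    """Read an annotation CSV back into finalized points.

    The dialect does not persist auto/manual status; it is inferred from
    the gate: confidence at/above ``threshold`` (or absent) reads as auto,
    below as manual.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ANNOTATION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV missing columns: {missing}")
    out = []
    for _, r in df.iterrows():
        conf = r.get("Machine confidence")
        conf = None if pd.isna(conf) else float(conf)
        manual = conf is not None and conf < threshold
        out.append(
            PointAnnotation(
                image_id=str(r["Name"]),
                row=int(r["Row"]),
                col=int(r["Column"]),
                machine_label=None if manual else str(r["Label"]),
                machine_confidence=conf,
                manual_label=str(r["Label"]) if manual else None,
                final_label=str(r["Label"]),
                status="manual" if manual else "auto",
            )
        )
    return out
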