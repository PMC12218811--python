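"""Evaluation metrics: NME_iod keypoint error, video-level classification
scores, and overlap-based event-detection confusion counts.

The keypoint metric is the inter-ocular-distance–normalized mean error

    NME_iod = 1/(M·N) Σ_i Σ_j ||x_i^j − x'_i^j|| / iod_i,

with M landmarks, N images and iod_i the distance between the outer eye
corners of image i.  The printed convention uses the 1-norm of the per-point
coordinate error; the Euclidean norm is available as a switch.  Values are
reported multiplied by 100 (i.e. percent of IOD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .annotations import AnnotatedImage
from .errors import MalformedInputError, ParameterError, VocabularyError
from .scheme import LandmarkScheme
from .series import EMOTION_CLASSES

log = logging.getLogger(__name__)


@dataclass
class NMEReport:
    """Normalized-mean-error breakdown, all values on the ×100 (percent-of-IOD) scale."""

    overall: float
    per_landmark: np.ndarray
    per_region: dict[str, float]
    n_images: int


@dataclass
class OverlapConfusion:
    """Section-level confusion counts with unweighted precision/recall/F1."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def nme_iod(
    pred: list[np.ndarray],
    gt: list[AnnotatedImage],
    scheme: LandmarkScheme,
    norm: str = "l1",
) -> NMEReport:
    """Compute NME_iod over aligned predicted/ground-truth landmark sets.

    Parameters
    ----------
    pred : list of (n_landmarks, 2) arrays, image-aligned with ``gt``.
    gt : ground-truth annotations; each image's IOD comes from the scheme's
        eye-corner pair on its ground-truth points.
    norm : "l1" (printed convention, |dx|+|dy|) or "l2" (Euclidean).

    Images with IOD = 0 are excluded with a warning; if all are excluded the
    computation fails.
    """
    if len(pred) != len(gt):
        raise ParameterError(f"{len(pred)} predictions for {len(gt)} images")
    if norm not in ("l1", "l2"):
        raise ParameterError(f"norm must be 'l1' or 'l2', got {norm!r}")
    per_image: list[np.ndarray] = []
    for p, g in zip(pred, gt):
        p = np.asarray(p, dtype=float)
        if p.shape != g.points.shape:
            raise ParameterError(
                f"image {g.image_id}: prediction shape {p.shape} != {g.points.shape}"
            )
        iod = g.iod(scheme)
        if iod == 0.0:
            log.warning("image %s has zero IOD; excluded from NME", g.image_id)
            continue
        diff = p - g.points
        if norm == "l1":
            err = np.abs(diff).sum(axis=1)
        else:
            err = np.linalg.norm(diff, axis=1)
        per_image.append(err / iod)
    if not per_image:
        raise MalformedInputError("all images excluded (zero IOD); cannot compute NME")
    per_landmark = 100.0 * np.mean(per_image, axis=0)
    per_region = {
        name: float(np.mean(per_landmark[list(scheme.region_indices(name))]))
        for name in scheme.regions
    }
    return NMEReport(
        overall=float(per_landmark.mean()),
        per_landmark=per_landmark,
        per_region=per_region,
        n_images=len(per_image),
    )


def video_metrics(
    true_labels: list[str],
    pred_labels: list[str],
    positive_class: str = "positive",
) -> dict[str, float]:
    """Binary accuracy/precision/recall/F1 over aligned per-video labels.

    Zero-denominator cases (e.g. no positive predictions) score 0.
    """
    if not true_labels or len(true_labels) != len(pred_labels):
        raise ParameterError("need equal-length, non-empty label lists")
    for lab in (*true_labels, *pred_labels):
        if lab not in EMOTION_CLASSES:
            raise VocabularyError(f"label {lab!r} not in {EMOTION_CLASSES}")
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(pred_labels)
    p, r, f1, _ = precision_recall_fscore_support(
        y_true,
        y_pred,
        labels=[positive_class],
        average="binary",
        pos_label=positive_class,
        zero_division=0,
    )
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f1),
    }


def overlap_confusion(truth, predicted) -> OverlapConfusion:
    """Section-level confusion between coded sections and predicted sequences.

    Overlap means at least one shared frame (intervals are inclusive).  Each
    truth section counts one TP if it overlaps any predicted sequence and
    one FN otherwise; each predicted sequence overlapping no truth section
    counts one FP.  Counting is by section, not by overlapping pair.
    """
    truth_iv = [_as_interval(t) for t in truth]
    pred_iv = [_as_interval(p) for p in predicted]
    pred_tree = IntervalTree()
    for s, e in pred_iv:
        pred_tree.addi(s, e + 1)  # half-open internally
    truth_tree = IntervalTree()
    for s, e in truth_iv:
        truth_tree.addi(s, e + 1)
    tp = sum(1 for s, e in truth_iv if pred_tree.overlap(s, e + 1))
    fn = len(truth_iv) - tp
    fp = sum(1 for s, e in pred_iv if not truth_tree.overlap(s, e + 1))
    return OverlapConfusion(tp=tp, fp=fp, fn=fn)


def _as_interval(obj) -> tuple[int, int]:
    if hasattr(obj, "start_frame"):
        s, e = int(obj.start_frame), int(obj.end_frame)
    else:
        s, e = int(obj[0]), int(obj[1])
    if e < s:
        raise MalformedInputError(f"malformed interval ({s}, {e})")
    return s, e
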