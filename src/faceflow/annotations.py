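"""Keypoint image annotations in a COCO-keypoints JSON dialect.

Supports the evaluation side of the toolkit: ground-truth landmark
annotations (one category with ``n_landmarks`` keypoints, a face bounding
box per image) are read into :class:`AnnotatedImage` records for the
normalized-mean-error evaluator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError
from .scheme import LandmarkScheme


@dataclass
class AnnotatedImage:
    """One annotated face image: bounding box, landmarks, per-point visibility."""

    image_id: str
    face_bbox: tuple[float, float, float, float]  # (x, y, w, h), pixels
    points: np.ndarray  # (n_landmarks, 2)
    visibility: np.ndarray = field(default=None)  # per-point flag

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.visibility is None:
            self.visibility = np.ones(len(self.points), dtype=int)
        self.visibility = np.asarray(self.visibility, dtype=int)
        x, y, w, h = self.face_bbox
        if w <= 0 or h <= 0:
            raise SchemaError(f"image {self.image_id}: bbox w,h must be positive")
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise SchemaError(f"image {self.image_id}: points must be (N, 2)")

    def iod(self, scheme: LandmarkScheme) -> float:
        """Inter-ocular distance from the scheme's eye-corner pair."""
        a, b = scheme.iod_pair
        return float(np.linalg.norm(self.points[a] - self.points[b]))


def read_keypoint_annotations(path, scheme: LandmarkScheme) -> list[AnnotatedImage]:
    """Read COCO-style keypoint annotations, one record per image, order kept.

    Expects ``images`` and ``annotations`` arrays; each annotation carries
    ``bbox`` [x, y, w, h] and flat ``keypoints`` [x, y, v] * n_landmarks.
    """
    with open(path) as fh:
        doc = json.load(fh)
    try:
        images = doc["images"]
        annotations = doc["annotations"]
    except KeyError as exc:
        raise SchemaError(f"{path}: missing top-level key {exc}") from None
    by_image = {ann["image_id"]: ann for ann in annotations}
    out: list[AnnotatedImage] = []
    for img in images:
        image_id = img["id"]
        try:
            ann = by_image[image_id]
        except KeyError:
            raise SchemaError(f"image {image_id!r} has no annotation") from None
        kp = np.asarray(ann["keypoints"], dtype=float)
        if kp.size != 3 * scheme.n_landmarks:
            raise SchemaError(
                f"image {image_id!r} has {kp.size // 3} keypoints, "
                f"expected {scheme.n_landmarks}"
            )
        kp = kp.reshape(-1, 3)
        out.append(
            AnnotatedImage(
                image_id=str(image_id),
                face_bbox=tuple(float(v) for v in ann["bbox"]),
                points=kp[:, :2],
                visibility=kp[:, 2].astype(int),
            )
        )
    return out


def write_keypoint_annotations(
    images: list[AnnotatedImage], scheme: LandmarkScheme, path
) -> None:
    """Write annotations in the dialect read by :func:`read_keypoint_annotations`."""
    doc = {
        "images": [{"id": im.image_id} for im in images],
        "annotations": [
            {
                "image_id": im.image_id,
                "category_id": 1,
                "bbox": list(im.face_bbox),
                "keypoints": np.column_stack([im.points, im.visibility])
                .reshape(-1)
                .tolist(),
            }
            for im in images
        ],
        "categories": [
            {"id": 1, "name": "dog_face", "keypoints": list(scheme.names)}
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
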