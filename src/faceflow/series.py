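"""Landmark time series: container, I/O and per-frame normalization.

The central object is :class:`LandmarkSeries`: per-frame ``(T, N, 2)``
coordinates plus a per-frame detection confidence.  Frames where no face was
detected carry zero confidence and all-zero coordinates ("empty frames");
they are deliberately kept in place, never interpolated, and downstream
windowing skips any window touching them.

Serialization is a plain CSV (``frame,conf,x1,y1,...,xN,yN``) with a YAML
sidecar carrying video/animal identifiers, frame rate, the optional emotion
label and the normalization flag.  Coordinates are written with shortest
round-trip float formatting, so read(write(s)) reproduces the array exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import MalformedInputError, ParameterError, SchemaError, VocabularyError
from .scheme import CATEGORIES, LandmarkScheme

log = logging.getLogger(__name__)

EMOTION_CLASSES = ("positive", "negative")


@dataclass
class LandmarkSeries:
    """Per-frame facial landmarks with confidence for one video.

    Attributes
    ----------
    video_id, animal_id : str
        Provenance identifiers; LOAO cross-validation folds on ``animal_id``.
    fps : float
        Frame rate of the source video (frames / second, > 0).
    coords : ndarray, shape (T, n_landmarks, 2)
        Pixel coordinates in raw state (origin top-left, x right, y down);
        dimensionless after normalization.
    confidence : ndarray, shape (T,)
        Landmark-verifier confidence in [0, 1]; exactly 0 marks an empty
        frame whose coordinates are all zero.
    label : str or None
        Optional emotion class, "positive" or "negative".
    normalized : bool
        Whether :func:`normalize_series` has been applied.
    """

    video_id: str
    animal_id: str
    fps: float
    coords: np.ndarray
    confidence: np.ndarray
    label: str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.fps <= 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise SchemaError(f"coords must be (T, N, 2), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise MalformedInputError("series must have at least one frame")
        if self.confidence.shape != (self.coords.shape[0],):
            raise SchemaError("confidence must have one value per frame")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise MalformedInputError("confidence values must lie in [0, 1]")
        if self.label is not None and self.label not in EMOTION_CLASSES:
            raise VocabularyError(f"label must be one of {EMOTION_CLASSES}")
        empty = self.confidence == 0
        if np.any(self.coords[empty] != 0):
            bad = int(np.flatnonzero(empty & np.any(self.coords != 0, axis=(1, 2)))[0])
            raise MalformedInputError(
                f"frame {bad} has zero confidence but nonzero coordinates"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def empty_frames(self) -> np.ndarray:
        """Boolean mask of frames with no detected landmarks."""
        return self.confidence == 0

    def flat_coords(self) -> np.ndarray:
        """Coordinates as (T, 2·N) with x,y interleaved per landmark."""
        return self.coords.reshape(self.n_frames, -1)


@dataclass(frozen=True, order=True)
class EventAnnotation:
    """A coded DogFACS section: variable, category and an inclusive frame span."""

    start_frame: int
    end_frame: int
    variable: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if self.category and self.category not in CATEGORIES:
            raise VocabularyError(
                f"unknown DogFACS category {self.category!r}; known: {CATEGORIES}"
            )
        if not (0 <= self.start_frame <= self.end_frame):
            raise MalformedInputError(
                f"bad interval [{self.start_frame}, {self.end_frame}]"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def overlaps(self, start: int, end: int) -> bool:
        """Whether this section shares at least one frame with [start, end]."""
        return self.start_frame <= end and start <= self.end_frame


# ---------------------------------------------------------------------------
# normalization and region selection
# ---------------------------------------------------------------------------


def normalize_series(series: LandmarkSeries, scheme: LandmarkScheme) -> LandmarkSeries:
    """Translate/scale-normalize every non-empty frame.

    Each non-empty frame is translated so the landmark centroid sits at the
    origin and scaled so the inter-ocular distance (scheme ``iod_pair``)
    equals 1, making downstream windows invariant to face position and
    scale.  Rotation is deliberately retained: facial events can involve
    rotations of face parts.  Empty frames stay all-zero.  Frames with a
    degenerate IOD of 0 are demoted to empty with a warning rather than
    failing the series.  Idempotent.
    """
    a, b = scheme.iod_pair
    coords = series.coords.copy()
    conf = series.confidence.copy()
    for t in range(series.n_frames):
        if conf[t] == 0:
            continue
        frame = coords[t]
        iod = float(np.linalg.norm(frame[a] - frame[b]))
        if iod == 0.0:
            log.warning(
                "series %s frame %d has zero inter-ocular distance; "
                "demoting to empty frame",
                series.video_id,
                t,
            )
            coords[t] = 0.0
            conf[t] = 0.0
            continue
        centroid = frame.mean(axis=0)
        coords[t] = (frame - centroid) / iod
    return replace(series, coords=coords, confidence=conf, normalized=True)


def select_region(obj, region: str, scheme: LandmarkScheme):
    """Restrict a series or an ``(L, 2N)`` window matrix to one face region.

    Columns are kept in scheme order; selecting the same region twice is the
    identity on the second call's input.
    """
    idx = scheme.region_indices(region)
    if isinstance(obj, LandmarkSeries):
        return replace(obj, coords=obj.coords[:, idx, :])
    mat = np.asarray(obj, dtype=float)
    full, reduced = 2 * scheme.n_landmarks, 2 * len(idx)
    if mat.shape[-1] == reduced and reduced != full:
        return mat  # already reduced to this region: idempotent
    if mat.shape[-1] != full:
        raise SchemaError(f"window has {mat.shape[-1]} columns, expected {full}")
    return mat[..., scheme.region_columns(region)]


# ---------------------------------------------------------------------------
# series I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_series(series: LandmarkSeries, path) -> None:
    """Write a series as CSV plus a YAML metadata sidecar.

    Coordinates use shortest round-trip decimal formatting (exact for
    float64), so the file re-reads to an identical series and re-writing
    yields a byte-identical file.
    """
    path = Path(path)
    n = series.n_landmarks
    cols = ["frame", "conf"]
    for j in range(1, n + 1):
        cols += [f"x{j}", f"y{j}"]
    flat = series.flat_coords()
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for t in range(series.n_frames):
            values = [str(t), repr(float(series.confidence[t]))]
            values.extend(repr(float(v)) for v in flat[t])
            fh.write(",".join(values) + "\n")
    meta = {
        "video_id": series.video_id,
        "animal_id": series.animal_id,
        "fps": float(series.fps),
        "label": series.label,
        "normalized": bool(series.normalized),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_series(
    path,
    scheme: LandmarkScheme,
    *,
    video_id: str | None = None,
    animal_id: str | None = None,
    fps: float | None = None,
    label: str | None = None,
) -> LandmarkSeries:
    """Read a landmark-series CSV (``frame,conf,x1,y1,...``).

    Metadata comes from the YAML sidecar next to the file when present;
    keyword arguments override it.  Frame indices must be contiguous from 0;
    zero-confidence rows must be entirely zero.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    expected = 2 + 2 * scheme.n_landmarks
    if df.shape[1] != expected:
        raise SchemaError(
            f"{path}: {df.shape[1]} columns, expected {expected} "
            f"(frame, conf, and {scheme.n_landmarks} coordinate pairs)"
        )
    frames = df["frame"].to_numpy()
    if len(frames) == 0:
        raise MalformedInputError(f"{path}: no frames")
    dup = pd.Series(frames).duplicated()
    if dup.any():
        raise MalformedInputError(
            f"{path}: duplicate frame index {int(frames[dup.argmax()])}"
        )
    want = np.arange(len(frames))
    if not np.array_equal(frames, want):
        missing = int(want[frames != want][0])
        raise MalformedInputError(f"{path}: frame indices not contiguous at {missing}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    conf = df["conf"].to_numpy(dtype=float)
    coords = df.iloc[:, 2:].to_numpy(dtype=float).reshape(len(frames), -1, 2)
    return LandmarkSeries(
        video_id=video_id or meta.get("video_id", path.stem),
        animal_id=animal_id or meta.get("animal_id", path.stem),
        fps=float(fps if fps is not None else meta.get("fps", 25.0)),
        coords=coords,
        confidence=conf,
        label=label if label is not None else meta.get("label"),
        normalized=bool(meta.get("normalized", False)),
    )


# ---------------------------------------------------------------------------
# event-annotation I/O (BORIS-like CSV export)
# ---------------------------------------------------------------------------

_EPS = 1e-9


def seconds_to_frames(start_s: float, end_s: float, fps: float) -> tuple[int, int]:
    """Convert a second-based interval to inclusive frames.

    Uses floor(start_s·fps) and ceil(end_s·fps)−1 for conservative coverage,
    with a tiny epsilon guarding against binary-float artefacts.
    """
    start = math.floor(start_s * fps + _EPS)
    end = math.ceil(end_s * fps - _EPS) - 1
    return start, end


def read_events(path, fps: float | None = None) -> list[EventAnnotation]:
    """Read coded events from CSV.

    Accepts either frame-based columns ``variable,category,start_frame,
    end_frame`` or second-based ``variable,category,start_s,end_s`` (the
    latter requires ``fps``).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    out: list[EventAnnotation] = []
    if {"start_frame", "end_frame"} <= cols:
        for row in df.itertuples(index=False):
            out.append(
                EventAnnotation(
                    start_frame=int(row.start_frame),
                    end_frame=int(row.end_frame),
                    variable=str(row.variable),
                    category=str(row.category),
                )
            )
    elif {"start_s", "end_s"} <= cols:
        if fps is None:
            raise ParameterError("fps is required to convert second-based events")
        for row in df.itertuples(index=False):
            if row.end_s < row.start_s:
                raise MalformedInputError(
                    f"event {row.variable!r}: end_s {row.end_s} < start_s {row.start_s}"
                )
            start, end = seconds_to_frames(float(row.start_s), float(row.end_s), fps)
            out.append(
                EventAnnotation(
                    start_frame=start,
                    end_frame=end,
                    variable=str(row.variable),
                    category=str(row.category),
                )
            )
    else:
        raise SchemaError(
            f"{path}: need columns start_frame/end_frame or start_s/end_s"
        )
    return out


def write_events(events: list[EventAnnotation], path) -> None:
    """Write events as frame-based CSV, re-readable by :func:`read_events`."""
    df = pd.DataFrame(
        {
            "variable": [e.variable for e in events],
            "category": [e.category for e in events],
            "start_frame": [e.start_frame for e in events],
            "end_frame": [e.end_frame for e in events],
        }
    )
    df.to_csv(path, index=False)
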