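"""Sliding and sparse window construction over landmark series.

A window is an ``(L, D)`` slice of the flattened coordinate series
(``D = 2·N`` landmarks).  Sparse windows keep the same row count but sample
rows at a reduced effective frame rate, covering a longer time span without
increasing dimensionality.  Any window touching an empty frame (no detected
landmarks) is rejected outright — missing frames are never interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .scheme import LandmarkScheme
from .series import LandmarkSeries

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry: length, stride, optional sparse rate and region.

    ``target_fps`` below the native frame rate makes the window sparse: row
    ``i`` of the window is taken from source offset round(i·native/target).
    """

    L: int = 5
    step: int = 1
    target_fps: float | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ParameterError(f"L must be >= 1, got {self.L}")
        if self.step < 1:
            raise ParameterError(f"step must be >= 1, got {self.step}")


@dataclass
class WindowSet:
    """A stack of windows with per-window provenance.

    Attributes
    ----------
    windows : ndarray (n, L, D)
    starts : ndarray (n,) — start frame of each window in its source series.
    labels : list or None — per-window emotion class.
    video_ids, animal_ids : per-window provenance.
    spec : WindowSpec shared by all windows.
    """

    windows: np.ndarray
    starts: np.ndarray
    spec: WindowSpec
    labels: list | None = None
    video_ids: list = field(default_factory=list)
    animal_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return self.windows.shape[0]

    @staticmethod
    def empty(spec: WindowSpec, L: int, D: int) -> "WindowSet":
        return WindowSet(
            windows=np.empty((0, L, D)),
            starts=np.empty(0, dtype=int),
            spec=spec,
            labels=[],
            video_ids=[],
            animal_ids=[],
        )

    def take(self, idx: np.ndarray) -> "WindowSet":
        """Subset by window index, preserving provenance alignment."""
        idx = np.asarray(idx, dtype=int)
        return WindowSet(
            windows=self.windows[idx],
            starts=self.starts[idx],
            spec=self.spec,
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            video_ids=[self.video_ids[i] for i in idx] if self.video_ids else [],
            animal_ids=[self.animal_ids[i] for i in idx] if self.animal_ids else [],
        )

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s) > 0]
        if not sets:
            raise ParameterError("cannot concatenate zero non-empty WindowSets")
        spec = sets[0].spec
        labels = None
        if all(s.labels is not None for s in sets):
            labels = [lab for s in sets for lab in s.labels]
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            starts=np.concatenate([s.starts for s in sets]),
            spec=spec,
            labels=labels,
            video_ids=[v for s in sets for v in s.video_ids],
            animal_ids=[a for s in sets for a in s.animal_ids],
        )


def save_windows(ws: WindowSet, prefix) -> None:
    """Persist a WindowSet as ``<prefix>.npz`` plus a ``<prefix>.csv`` manifest.

    The npz holds the window array; the CSV manifest carries starts, labels
    and provenance with the window spec echoed in its header comment.
    """
    import pandas as pd
    from pathlib import Path

    prefix = Path(prefix)
    np.savez_compressed(prefix.with_suffix(".npz"), windows=ws.windows)
    df = pd.DataFrame(
        {
            "start": ws.starts,
            "label": ws.labels if ws.labels is not None else [""] * len(ws),
            "video_id": ws.video_ids or [""] * len(ws),
            "animal_id": ws.animal_ids or [""] * len(ws),
        }
    )
    spec = ws.spec
    header = (f"# L={spec.L} step={spec.step} "
              f"target_fps={spec.target_fps} region={spec.region}\n")
    with open(prefix.with_suffix(".csv"), "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def load_windows(prefix) -> WindowSet:
    """Load a WindowSet written by :func:`save_windows`."""
    import pandas as pd
    from pathlib import Path

    prefix = Path(prefix)
    windows = np.load(prefix.with_suffix(".npz"))["windows"]
    with open(prefix.with_suffix(".csv")) as fh:
        header = fh.readline().lstrip("# ").strip()
        df = pd.read_csv(fh, keep_default_na=False)
    fields = dict(item.split("=", 1) for item in header.split())
    spec = WindowSpec(
        L=int(fields["L"]),
        step=int(fields["step"]),
        target_fps=None if fields["target_fps"] == "None"
        else float(fields["target_fps"]),
        region=None if fields["region"] == "None" else fields["region"],
    )
    labels = df["label"].tolist()
    return WindowSet(
        windows=windows,
        starts=df["start"].to_numpy(dtype=int),
        spec=spec,
        labels=None if all(lab == "" for lab in labels) else labels,
        video_ids=df["video_id"].tolist(),
        animal_ids=df["animal_id"].tolist(),
    )


def sparse_stride(native_fps: float, target_fps: float, L: int) -> np.ndarray:
    """Within-window source-row offsets for a sparse window.

    Row ``i`` (0..L−1) maps to offset round(i·native/target); for integer
    rate ratios this skips (ratio − 1) rows between consecutive samples.
    Half-way cases round up, deterministically.
    """
    if target_fps is None:
        return np.arange(L)
    if not (0 < target_fps <= native_fps):
        raise ParameterError(
            f"target_fps must satisfy 0 < target <= native ({native_fps}), "
            f"got {target_fps}"
        )
    i = np.arange(L)
    return np.floor(i * (native_fps / target_fps) + 0.5).astype(int)


def window_span_seconds(L: int, fps: float) -> float:
    """Time span captured by an L-row window sampled at ``fps``: L / fps."""
    if L < 1 or fps <= 0:
        raise ParameterError("need L >= 1 and fps > 0")
    return L / fps


def slide_windows(
    series: LandmarkSeries, spec: WindowSpec, scheme: LandmarkScheme
) -> WindowSet:
    """Build all valid windows of a normalized series.

    Window starts run 0, step, 2·step, …; a window survives only if every
    sampled row lies inside the series and none is an empty frame.  The
    series label is inherited by each window; region selection is applied
    when the spec names one.
    """
    offsets = sparse_stride(series.fps, spec.target_fps, spec.L)
    span = int(offsets[-1]) + 1
    flat = series.flat_coords()
    if spec.region is not None:
        cols = scheme.region_columns(spec.region)
        flat = flat[:, cols]
    empty = series.empty_frames
    T, D = flat.shape

    windows, starts = [], []
    for s in range(0, max(T - span + 1, 0), spec.step):
        rows = s + offsets
        if empty[rows].any():
            continue
        windows.append(flat[rows])
        starts.append(s)
    if not windows:
        log.info(
            "series %s produced no windows (T=%d, span=%d)",
            series.video_id,
            T,
            span,
        )
        return WindowSet.empty(spec, spec.L, D)
    n = len(windows)
    return WindowSet(
        windows=np.stack(windows),
        starts=np.asarray(starts, dtype=int),
        spec=spec,
        labels=None if series.label is None else [series.label] * n,
        video_ids=[series.video_id] * n,
        animal_ids=[series.animal_id] * n,
    )


def balance_by_downsampling(ws: WindowSet, seed: int) -> WindowSet:
    """Downsample every class to the minority-class count, without replacement.

    Selection is reproducible for a given seed; surviving windows keep their
    original relative order.
    """
    if ws.labels is None:
        raise ParameterError("balance_by_downsampling requires labeled windows")
    labels = np.asarray(ws.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("balancing requires at least two classes")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.extend(idx.tolist())
    return ws.take(np.sort(np.asarray(keep)))


def split_windows(
    ws: WindowSet, proportions: tuple[float, float, float], seed: int
) -> tuple[WindowSet, WindowSet, WindowSet]:
    """Random disjoint train/validation/test partition of a WindowSet.

    Validation and test sizes are floor(n·p); the remainder goes to train.
    The assignment is a seeded permutation, so the three parts are an
    exhaustive, pairwise-disjoint partition.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (3,):
        raise ParameterError("proportions must be a (train, val, test) triple")
    if np.any(p < 0):
        raise ParameterError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError(f"proportions must sum to 1, got {p.sum()}")
    n = len(ws)
    n_val = int(np.floor(n * p[1]))
    n_test = int(np.floor(n * p[2]))
    n_train = n - n_val - n_test
    perm = np.random.default_rng(seed).permutation(n)
    return (
        ws.take(np.sort(perm[:n_train])),
        ws.take(np.sort(perm[n_train : n_train + n_val])),
        ws.take(np.sort(perm[n_train + n_val :])),
    )
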