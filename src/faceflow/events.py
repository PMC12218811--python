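"""DogFACS event detection as time-series anomaly detection.

One model per DogFACS variable: a bidirectional-LSTM autoencoder is trained
to reconstruct L=15 windows of the variable's face region drawn from
"normal" data (windows free of that variable), so windows containing the
unseen movement reconstruct poorly.  The per-channel mean absolute
reconstruction error is spread over each window's frames (averaging across
covering windows), smoothed with
an exponential weighted moving average, compared against per-channel 3σ
thresholds estimated on the training errors, masked near scored-segment
edges, merged into contiguous anomalous sequences, and finally pruned by the
relative drop of sorted peak scores (p = 0.13).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .errors import DataLeakError, ParameterError
from .metrics import OverlapConfusion, overlap_confusion
from .scheme import LandmarkScheme, VARIABLE_CATEGORY
from .series import EventAnnotation, LandmarkSeries
from .windowing import WindowSet, WindowSpec, slide_windows

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorConfig:
    """Configuration of one per-variable anomaly detector.

    ``region`` defaults to the face region of the variable's DogFACS
    category.  Windows are dense L=15, step 1.  The encoder/decoder each
    stack two bidirectional LSTM layers with ReLU activation and recurrent
    dropout; widths are sized for CPU training.  Post-processing: EWMA
    weight ``ewma_alpha``, per-channel mean + ``sigma_k``·sd thresholds,
    edge masking over ``edge_margin`` frames (default L−1), and peak-drop
    pruning at ``prune_p``.
    """

    variable: str = "Blink (AU145)"
    region: str | None = None
    L: int = 15
    step: int = 1
    encoder_units: tuple[int, int] = (32, 16)
    decoder_units: tuple[int, int] = (16, 32)
    recurrent_dropout: float = 0.2
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    ewma_alpha: float = 0.3
    sigma_k: float = 3.0
    prune_p: float = 0.13
    edge_margin: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ParameterError("L must be >= 1")
        if not (0 < self.ewma_alpha <= 1):
            raise ParameterError("ewma_alpha must be in (0, 1]")
        if not (0 <= self.prune_p < 1):
            raise ParameterError("prune_p must be in [0, 1)")
        if self.variable not in VARIABLE_CATEGORY:
            raise ParameterError(f"unknown DogFACS variable {self.variable!r}")

    @staticmethod
    def fast(variable: str, seed: int = 0, **overrides) -> "DetectorConfig":
        """Reduced profile (fewer epochs, narrower layers) for CPU runs."""
        base = dict(
            variable=variable,
            epochs=60,
            encoder_units=(16, 8),
            decoder_units=(8, 16),
            seed=seed,
        )
        base.update(overrides)
        return DetectorConfig(**base)

    def resolve_region(self, scheme: LandmarkScheme) -> str:
        return self.region or scheme.region_for_variable(self.variable)

    def window_spec(self, scheme: LandmarkScheme) -> WindowSpec:
        return WindowSpec(L=self.L, step=self.step, region=self.resolve_region(scheme))

    def resolved_edge_margin(self) -> int:
        return self.L - 1 if self.edge_margin is None else self.edge_margin


@dataclass
class ScoreTrack:
    """Per-frame anomaly scores of one series under one detector.

    ``channel_errors[t, c]`` is the mean reconstruction MAE of channel ``c``
    over the windows covering frame ``t``; frames covered by no surviving
    window have ``scored[t] == False`` and carry no meaning.  After thresholds are
    set, ``aggregate[t]`` is the maximum per-channel exceedance ratio
    (error − threshold)/threshold, so any positive value flags the frame.
    """

    channel_errors: np.ndarray  # (T, D)
    scored: np.ndarray  # (T,) bool
    thresholds: np.ndarray | None = None  # (D,)
    aggregate: np.ndarray | None = None  # (T,)
    variable: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.scored)

    def segments(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive scored frames, inclusive."""
        return _runs(self.scored)

    def flags(self) -> np.ndarray:
        if self.aggregate is None:
            raise ParameterError("thresholds not yet applied")
        return self.scored & (self.aggregate > 0)


@dataclass(frozen=True)
class AnomalySequence:
    """A predicted anomalous frame interval with its peak aggregate score."""

    start_frame: int
    end_frame: int
    peak_score: float
    variable: str = ""

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ParameterError("sequence end before start")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    start = idx[0]
    for b in breaks:
        out.append((int(start), int(idx[b])))
        start = idx[b + 1]
    out.append((int(start), int(idx[-1])))
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class EventDetector:
    """A trained per-variable autoencoder plus its error thresholds."""

    def __init__(
        self,
        model: nn.Sequential,
        config: DetectorConfig,
        n_features: int,
        thresholds: np.ndarray,
        validation_error: float,
    ):
        self.model = model
        self.config = config
        self.n_features = n_features
        self.thresholds = thresholds
        self.validation_error = validation_error

    def reconstruct(self, windows: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(windows, dtype=float))

    def window_errors(self, windows: np.ndarray) -> np.ndarray:
        """Per-window, per-channel MAE between input and reconstruction."""
        windows = np.asarray(windows, dtype=float)
        recon = self.reconstruct(windows)
        return np.abs(windows - recon).mean(axis=1)


def _build_autoencoder(config: DetectorConfig, L: int, n_features: int, rng):
    e1, e2 = config.encoder_units
    d1, d2 = config.decoder_units
    kw = dict(
        activation="relu", recurrent_dropout=config.recurrent_dropout, rng=rng
    )
    return nn.Sequential(
        [
            nn.Bidirectional(n_features, e1, return_sequences=True, **kw),
            nn.Bidirectional(2 * e1, e2, return_sequences=False, **kw),
            nn.RepeatVector(L),
            nn.Bidirectional(2 * e2, d1, return_sequences=True, **kw),
            nn.Bidirectional(2 * d1, d2, return_sequences=True, **kw),
            nn.Dense(2 * d2, n_features, rng=rng),
        ]
    )


def train_autoencoder(
    normal_windows: WindowSet,
    config: DetectorConfig,
    *,
    validation_windows: WindowSet | None = None,
    truth: list[EventAnnotation] | None = None,
) -> EventDetector:
    """Train the reconstruction autoencoder on normal windows.

    ``normal_windows`` must be region-reduced and free of the target
    variable; when ground truth is supplied, any training window overlapping
    a section of the target variable raises a data-leak error.  Thresholds
    are the per-channel mean + sigma_k·sd (population) of the training
    reconstruction errors; the held-out validation error is recorded.
    """
    if truth is not None:
        sections = [t for t in truth if t.variable == config.variable]
        span = config.L
        for s in normal_windows.starts:
            for sec in sections:
                if sec.overlaps(int(s), int(s) + span - 1):
                    raise DataLeakError(
                        f"training window at frame {int(s)} overlaps a "
                        f"{config.variable!r} section [{sec.start_frame}, "
                        f"{sec.end_frame}]"
                    )
    x = np.asarray(normal_windows.windows, dtype=float)
    if len(x) == 0:
        raise ParameterError("no training windows")
    rng = np.random.default_rng(config.seed)
    model = _build_autoencoder(config, x.shape[1], x.shape[2], rng)
    history = model.fit(
        x,
        x,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        rng=rng,
    )
    detector = EventDetector(model, config, x.shape[2], None, float("nan"))
    train_errors = detector.window_errors(x)
    detector.thresholds = compute_thresholds(train_errors, config.sigma_k)
    if validation_windows is not None and len(validation_windows) > 0:
        detector.validation_error = float(
            detector.window_errors(validation_windows.windows).mean()
        )
    log.info(
        "trained %r autoencoder on %d windows: mse %.5f -> %.5f, val MAE %.5f",
        config.variable,
        len(x),
        history[0],
        history[-1],
        detector.validation_error,
    )
    return detector


def compute_thresholds(train_errors: np.ndarray, sigma_k: float) -> np.ndarray:
    """Per-channel anomaly thresholds mean + sigma_k·sd (population sd).

    Degenerate channels with zero spread get a floor of mean + 1e-8 so a
    constant error never flags everything.
    """
    e = np.asarray(train_errors, dtype=float)
    if e.ndim != 2 or e.shape[0] < 2:
        raise ParameterError("need >= 2 error samples per channel")
    mean = e.mean(axis=0)
    sd = e.std(axis=0)  # population
    return np.maximum(mean + sigma_k * sd, mean + 1e-8)


# ---------------------------------------------------------------------------
# scoring chain
# ---------------------------------------------------------------------------


def score_series(
    detector: EventDetector, series: LandmarkSeries, scheme: LandmarkScheme
) -> ScoreTrack:
    """Per-frame, per-channel reconstruction errors for one normalized series.

    Windows are built with the detector's L/step/region; each window's
    per-channel MAE is credited to every frame the window covers, and a
    frame's error is the mean over all windows covering it.  This centers
    the response on the event instead of lagging it by the window length.
    Frames covered by no surviving window stay unscored.
    """
    config = detector.config
    ws = slide_windows(series, config.window_spec(scheme), scheme)
    T = series.n_frames
    errors = np.zeros((T, detector.n_features))
    coverage = np.zeros(T)
    if len(ws) > 0:
        werr = detector.window_errors(ws.windows)
        for start, err in zip(ws.starts, werr):
            sl = slice(int(start), int(start) + config.L)
            errors[sl] += err
            coverage[sl] += 1.0
    scored = coverage > 0
    errors[scored] /= coverage[scored, None]
    return ScoreTrack(
        channel_errors=errors, scored=scored, variable=config.variable
    )


def smooth_scores(track: ScoreTrack, alpha: float) -> ScoreTrack:
    """EWMA-smooth per-channel errors: s'_t = α·s_t + (1−α)·s'_{t−1}.

    The recursion runs independently within each contiguous scored segment
    (gaps reset it) and restarts from the segment's first value.
    """
    if not (0 < alpha <= 1):
        raise ParameterError("alpha must be in (0, 1]")
    errors = track.channel_errors.copy()
    for s, e in track.segments():
        for t in range(s + 1, e + 1):
            errors[t] = alpha * errors[t] + (1 - alpha) * errors[t - 1]
    return replace(track, channel_errors=errors)


def apply_thresholds(track: ScoreTrack, thresholds: np.ndarray) -> ScoreTrack:
    """Attach thresholds and compute the per-frame aggregate score.

    The aggregate is the maximum per-channel exceedance ratio
    (error − threshold)/threshold: positive iff any channel exceeds its
    threshold, which suits localized facial events that move few channels.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    agg = np.zeros(track.n_frames)
    if track.scored.any():
        ratios = (track.channel_errors[track.scored] - thresholds) / thresholds
        agg[track.scored] = ratios.max(axis=1)
    return replace(track, thresholds=thresholds, aggregate=agg)


def mask_edges(track: ScoreTrack, margin: int) -> ScoreTrack:
    """Suppress the first/last ``margin`` frames of every scored segment.

    Reconstruction-based scores are unreliable where window coverage begins
    or ends; masked frames take the track's minimum aggregate score.
    """
    if margin < 0:
        raise ParameterError("margin must be >= 0")
    if track.aggregate is None:
        raise ParameterError("apply thresholds before edge masking")
    if margin == 0 or not track.scored.any():
        return track
    agg = track.aggregate.copy()
    floor = agg[track.scored].min()
    for s, e in track.segments():
        hi = min(s + margin, e + 1)
        agg[s:hi] = floor
        lo = max(e + 1 - margin, s)
        agg[lo : e + 1] = floor
    return replace(track, aggregate=agg)


def detect_sequences(track: ScoreTrack, config: DetectorConfig) -> list[AnomalySequence]:
    """Merge flagged frames into anomalous sequences and prune them.

    Frames with positive aggregate score are anomaly instances; maximal runs
    of consecutive flagged frames become sequences whose peak is the maximal
    aggregate inside the run.  Peak-drop pruning (``prune_p``) then removes
    the low-scoring tail.
    """
    flags = track.flags()
    seqs = [
        AnomalySequence(
            start_frame=s,
            end_frame=e,
            peak_score=float(track.aggregate[s : e + 1].max()),
            variable=track.variable,
        )
        for s, e in _runs(flags)
    ]
    return prune_sequences(seqs, config.prune_p)


def prune_sequences(
    sequences: list[AnomalySequence], prune_p: float
) -> list[AnomalySequence]:
    """Drop the low-peak tail of the sorted peak-score curve.

    Sort peaks descending and compute the relative decreases
    d(i) = (s(i−1) − s(i))/s(i−1).  The maximal suffix in which every
    decrease stays below ``prune_p`` — i.e. everything after the last
    meaningful drop — is reclassified normal: true anomalies stand out by a
    sharp drop to the error floor, while a gently decaying tail is noise.
    The highest-peak sequence always survives; surviving sequences return
    in positional order.
    """
    if len(sequences) <= 1 or prune_p == 0:
        return list(sequences)
    ranked = sorted(sequences, key=lambda q: q.peak_score, reverse=True)
    keep = len(ranked)
    for i in range(len(ranked) - 1, 0, -1):
        prev, cur = ranked[i - 1].peak_score, ranked[i].peak_score
        drop = (prev - cur) / prev if prev > 0 else 0.0
        if drop < prune_p:
            keep = i
        else:
            break
    kept = set(id(q) for q in ranked[:keep])
    return [q for q in sequences if id(q) in kept]


def detect_events(
    detectors: dict[str, EventDetector],
    series: LandmarkSeries,
    scheme: LandmarkScheme,
    *,
    variables: list[str] | None = None,
    truth: list[EventAnnotation] | None = None,
) -> tuple[dict[str, list[AnomalySequence]], dict[str, OverlapConfusion] | None]:
    """Run the full per-variable chain on one series.

    score → EWMA smooth → threshold → edge mask → merge → prune, per
    requested variable; when ground truth is given, a section-overlap
    confusion is evaluated per variable.
    """
    if variables is None:
        variables = sorted(detectors)
    sequences: dict[str, list[AnomalySequence]] = {}
    tracks: dict[str, ScoreTrack] = {}
    for var in variables:
        if var not in detectors:
            raise ParameterError(f"no trained detector for variable {var!r}")
        det = detectors[var]
        cfg = det.config
        track = score_series(det, series, scheme)
        track = smooth_scores(track, cfg.ewma_alpha)
        track = apply_thresholds(track, det.thresholds)
        track = mask_edges(track, cfg.resolved_edge_margin())
        sequences[var] = detect_sequences(track, cfg)
        tracks[var] = track
    confusion = None
    if truth is not None:
        confusion = {}
        for var in variables:
            var_truth = [t for t in truth if t.variable == var]
            confusion[var] = overlap_confusion(var_truth, sequences[var])
    return sequences, confusion


def evaluate_variables(
    detectors: dict[str, EventDetector],
    series_list: list[LandmarkSeries],
    truth: dict[str, list[EventAnnotation]],
    scheme: LandmarkScheme,
    *,
    min_occurrences: int = 20,
) -> dict[str, OverlapConfusion]:
    """Pooled per-variable evaluation over a set of series.

    Runs the full chain on every series and pools TP/FP/FN per variable.
    Variables with fewer than ``min_occurrences`` ground-truth sections
    across the set are excluded — too few events for a meaningful rate.
    """
    counts: dict[str, int] = {}
    for sections in truth.values():
        for sec in sections:
            counts[sec.variable] = counts.get(sec.variable, 0) + 1
    variables = [v for v in sorted(detectors)
                 if counts.get(v, 0) >= min_occurrences]
    pooled = {v: [0, 0, 0] for v in variables}
    for series in series_list:
        _, conf = detect_events(
            detectors, series, scheme, variables=variables,
            truth=truth.get(series.video_id, []),
        )
        for v in variables:
            pooled[v][0] += conf[v].tp
            pooled[v][1] += conf[v].fp
            pooled[v][2] += conf[v].fn
    return {v: OverlapConfusion(tp=t, fp=f, fn=n)
            for v, (t, f, n) in pooled.items()}


def score_tracks(
    detectors: dict[str, EventDetector],
    series: LandmarkSeries,
    scheme: LandmarkScheme,
    *,
    variables: list[str] | None = None,
) -> dict[str, ScoreTrack]:
    """Fully post-processed score tracks (for intensity aggregation/plots)."""
    if variables is None:
        variables = sorted(detectors)
    out = {}
    for var in variables:
        det = detectors[var]
        cfg = det.config
        track = score_series(det, series, scheme)
        track = smooth_scores(track, cfg.ewma_alpha)
        track = apply_thresholds(track, det.thresholds)
        out[var] = mask_edges(track, cfg.resolved_edge_margin())
    return out


def aggregate_intensity(tracks: dict[str, ScoreTrack]) -> np.ndarray:
    """Merge per-variable tracks into one per-frame intensity in [0, 1].

    Each track's aggregate score is min–max normalized over its scored
    frames; the merged intensity is the per-frame maximum over variables
    (0 where no variable scored the frame).  Intended for a single overlay
    bar that points an annotator at likely events.
    """
    if not tracks:
        raise ParameterError("need at least one score track")
    T = next(iter(tracks.values())).n_frames
    intensity = np.zeros(T)
    for track in tracks.values():
        if track.aggregate is None or track.n_frames != T:
            raise ParameterError("tracks must share one frame axis and be thresholded")
        if not track.scored.any():
            continue
        vals = track.aggregate[track.scored]
        lo, hi = vals.min(), vals.max()
        norm = np.zeros(T)
        if hi > lo:
            norm[track.scored] = (track.aggregate[track.scored] - lo) / (hi - lo)
        intensity = np.maximum(intensity, norm)
    return intensity


# ---------------------------------------------------------------------------
# training-data assembly
# ---------------------------------------------------------------------------


def normal_windows_for_variable(
    series_list: list[LandmarkSeries],
    truth: dict[str, list[EventAnnotation]],
    config: DetectorConfig,
    scheme: LandmarkScheme,
) -> WindowSet:
    """All windows from ``series_list`` that never touch the target variable.

    Any window overlapping a ground-truth section of the variable at all is
    excluded from the normal pool (strict hygiene against leakage); windows
    containing *other* variables remain, as the detector must treat them as
    normal.
    """
    spec = config.window_spec(scheme)
    keep: list[WindowSet] = []
    for series in series_list:
        ws = slide_windows(series, spec, scheme)
        if len(ws) == 0:
            continue
        sections = [
            t for t in truth.get(series.video_id, []) if t.variable == config.variable
        ]
        if sections:
            ok = np.array(
                [
                    not any(
                        sec.overlaps(int(s), int(s) + config.L - 1)
                        for sec in sections
                    )
                    for s in ws.starts
                ]
            )
            ws = ws.take(np.flatnonzero(ok))
        if len(ws) > 0:
            keep.append(ws)
    if not keep:
        return WindowSet.empty(spec, config.L, 2 * len(scheme.region_indices(config.resolve_region(scheme))))
    return WindowSet.concatenate(keep)
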