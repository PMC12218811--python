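"""Window-level emotion classification with per-video majority voting.

A two-layer bidirectional-LSTM classifier with a narrowing dense head maps
an ``(L, 92)`` landmark window to the probability of the positive class;
training uses MSE loss on the sigmoid output with Adam, on class-balanced
windows.  Video labels come from majority voting over all surviving windows
of the video; evaluation uses leave-one-animal-out (LOAO) cross-validation
so no dog appears in both a fold's training and test sets.

Also houses the landmark-plausibility verifier: a small fully connected
network (128, 32, 1) scoring whether a flattened landmark vector looks like
a coherent face configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from collections import Counter

import numpy as np

from . import nn
from .errors import ParameterError
from .metrics import video_metrics
from .scheme import LandmarkScheme
from .series import EMOTION_CLASSES, LandmarkSeries
from .windowing import WindowSet, WindowSpec, balance_by_downsampling, slide_windows

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Training configuration for the window classifier.

    ``recurrent_units`` are the widths of the two bidirectional LSTM layers;
    ``dense_widths`` the four narrowing dense widths ending in the single
    sigmoid probability output.  Defaults: sparse L=5 windows at an
    effective 14 fps, 300 epochs, batch 16, MSE loss, Adam.
    """

    L: int = 5
    target_fps: float | None = 14.0
    recurrent_units: tuple[int, int] = (64, 32)
    dense_widths: tuple[int, int, int, int] = (64, 32, 16, 1)
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dense_widths) != 4 or self.dense_widths[-1] != 1:
            raise ParameterError("dense_widths must be four widths ending in 1")
        if any(
            a < b for a, b in zip(self.dense_widths, self.dense_widths[1:])
        ):
            raise ParameterError("dense widths must be non-increasing")

    @staticmethod
    def fast(seed: int = 0, **overrides) -> "ClassifierConfig":
        """Reduced profile (fewer epochs, narrower layers) for CPU runs."""
        base = dict(
            epochs=50,
            recurrent_units=(32, 16),
            dense_widths=(32, 16, 8, 1),
            seed=seed,
        )
        base.update(overrides)
        return ClassifierConfig(**base)

    def window_spec(self, step: int = 1, region: str | None = None) -> WindowSpec:
        return WindowSpec(L=self.L, step=step, target_fps=self.target_fps, region=region)


@dataclass
class VideoPrediction:
    """Per-video classification outcome from majority voting."""

    video_id: str
    window_votes: list[str]
    window_probs: np.ndarray
    label: str
    vote_margin: float
    abstained: bool = False


class EmotionClassifier:
    """Trained window classifier: maps (n, L, D) windows to probabilities."""

    def __init__(self, model: nn.Sequential, config: ClassifierConfig, n_features: int):
        self.model = model
        self.config = config
        self.n_features = n_features
        self.history: list[float] = []

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        windows = np.asarray(windows, dtype=float)
        if windows.ndim == 2:
            windows = windows[None]
        if windows.shape[1:] != (self.config.L, self.n_features):
            raise ParameterError(
                f"windows of shape {windows.shape[1:]} do not match "
                f"({self.config.L}, {self.n_features})"
            )
        return self.model.predict(windows)[:, 0]


def _build_classifier(config: ClassifierConfig, n_features: int, rng) -> nn.Sequential:
    r1, r2 = config.recurrent_units
    d1, d2, d3, _ = config.dense_widths
    return nn.Sequential(
        [
            nn.Bidirectional(n_features, r1, return_sequences=True, rng=rng),
            nn.Bidirectional(2 * r1, r2, return_sequences=False, rng=rng),
            nn.Dense(2 * r2, d1, activation="relu", rng=rng),
            nn.Dense(d1, d2, activation="relu", rng=rng),
            nn.Dense(d2, d3, activation="relu", rng=rng),
            nn.Dense(d3, 1, activation="sigmoid", rng=rng),
        ]
    )


def train_classifier(
    train_windows: WindowSet, config: ClassifierConfig, positive_class: str = "positive"
) -> EmotionClassifier:
    """Train the window classifier on balanced, labeled windows.

    Targets are 1 for the positive class and 0 otherwise; training is fully
    seeded from ``config.seed`` and the per-epoch MSE history is retained on
    the returned classifier.
    """
    if train_windows.labels is None:
        raise ParameterError("training windows must be labeled")
    x = np.asarray(train_windows.windows, dtype=float)
    if x.shape[1] != config.L:
        raise ParameterError(
            f"windows have L={x.shape[1]} but config.L={config.L}"
        )
    y = np.asarray(
        [1.0 if lab == positive_class else 0.0 for lab in train_windows.labels]
    )[:, None]
    rng = np.random.default_rng(config.seed)
    model = _build_classifier(config, x.shape[2], rng)
    clf = EmotionClassifier(model, config, x.shape[2])
    clf.history = model.fit(
        x,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        rng=rng,
    )
    log.info(
        "trained classifier on %d windows: mse %.4f -> %.4f",
        len(x),
        clf.history[0],
        clf.history[-1],
    )
    return clf


def classify_video(
    clf: EmotionClassifier,
    series: LandmarkSeries,
    spec: WindowSpec,
    scheme: LandmarkScheme,
    *,
    positive_class: str = "positive",
    fallback: str = "positive",
) -> VideoPrediction:
    """Classify one normalized series by majority vote over its windows.

    Each window votes positive when its probability exceeds 0.5; the video
    takes the majority class.  A vote tie is broken by comparing the mean
    window probability with 0.5.  If no window survives (all frames empty or
    series too short), the prediction abstains and returns ``fallback``.
    """
    negative = next(c for c in EMOTION_CLASSES if c != positive_class)
    ws = slide_windows(series, spec, scheme)
    if len(ws) == 0:
        log.warning(
            "series %s yielded no windows; abstaining with fallback %r",
            series.video_id,
            fallback,
        )
        return VideoPrediction(
            video_id=series.video_id,
            window_votes=[],
            window_probs=np.empty(0),
            label=fallback,
            vote_margin=0.0,
            abstained=True,
        )
    probs = clf.predict_proba(ws.windows)
    votes = [positive_class if p > 0.5 else negative for p in probs]
    counts = Counter(votes)
    n_pos, n_neg = counts[positive_class], counts[negative]
    if n_pos != n_neg:
        label = positive_class if n_pos > n_neg else negative
    else:
        label = positive_class if probs.mean() > 0.5 else negative
    return VideoPrediction(
        video_id=series.video_id,
        window_votes=votes,
        window_probs=probs,
        label=label,
        vote_margin=counts[label] / len(votes),
    )


def loao_cv(
    dataset: list[LandmarkSeries],
    config: ClassifierConfig,
    scheme: LandmarkScheme,
    *,
    step: int = 1,
    test_step: int = 1,
    positive_class: str = "positive",
) -> dict:
    """Leave-one-animal-out cross-validation over labeled, normalized series.

    One fold per animal: the fold's classifier trains on balanced windows
    from all *other* animals and predicts every held-out video by majority
    voting.  Returns per-fold and pooled accuracy/precision/recall/F1.
    """
    labeled = [s for s in dataset if s.label is not None]
    animals = sorted({s.animal_id for s in labeled})
    if len(animals) < 2:
        raise ParameterError("LOAO needs at least two distinct animals")
    if len({s.label for s in labeled}) < 2:
        raise ParameterError("dataset must contain both classes")
    spec = config.window_spec(step=step)
    test_spec = config.window_spec(step=test_step)

    per_fold: dict[str, dict] = {}
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    for fold, animal in enumerate(animals):
        train_series = [s for s in labeled if s.animal_id != animal]
        test_series = [s for s in labeled if s.animal_id == animal]
        ws = WindowSet.concatenate(
            [slide_windows(s, spec, scheme) for s in train_series]
        )
        ws = balance_by_downsampling(ws, seed=config.seed + fold)
        fold_config = replace(config, seed=config.seed + fold)
        clf = train_classifier(ws, fold_config, positive_class=positive_class)
        majority = Counter(lab for s in train_series for lab in [s.label]).most_common(
            1
        )[0][0]
        fold_true, fold_pred = [], []
        for s in test_series:
            pred = classify_video(
                clf,
                s,
                test_spec,
                scheme,
                positive_class=positive_class,
                fallback=majority,
            )
            fold_true.append(s.label)
            fold_pred.append(pred.label)
        per_fold[animal] = video_metrics(fold_true, fold_pred, positive_class)
        pooled_true.extend(fold_true)
        pooled_pred.extend(fold_pred)
    return {
        "per_fold": per_fold,
        "pooled": video_metrics(pooled_true, pooled_pred, positive_class),
        "n_videos": len(pooled_true),
    }


# ---------------------------------------------------------------------------
# landmark-plausibility verifier
# ---------------------------------------------------------------------------


class Verifier:
    """Plausibility scorer for flattened landmark vectors."""

    def __init__(self, model: nn.Sequential, n_features: int):
        self.model = model
        self.n_features = n_features

    def score(self, points: np.ndarray) -> np.ndarray:
        """Plausibility in [0, 1]; accepts (n, D), (D,), or (n, N, 2)."""
        x = np.asarray(points, dtype=float)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], -1)
        if x.ndim == 1:
            return float(self.model.predict(x[None])[0, 0])
        return self.model.predict(x)[:, 0]


def train_verifier(
    positive: np.ndarray,
    negative: np.ndarray,
    seed: int,
    *,
    epochs: int = 100,
    batch_size: int = 16,
) -> Verifier:
    """Train the (128, 32, 1) fully connected landmark verifier.

    ``positive`` are valid face configurations, ``negative`` implausible
    point sets (e.g. random scatter of matched scale), both flattened to
    92-value vectors.  Severe class imbalance (>100:1) is warned about.
    """
    if len(positive) == 0 or len(negative) == 0:
        raise ParameterError("both classes must be non-empty")
    pos = np.asarray(positive, dtype=float).reshape(len(positive), -1)
    neg = np.asarray(negative, dtype=float).reshape(len(negative), -1)
    ratio = max(len(pos), len(neg)) / min(len(pos), len(neg))
    if ratio > 100:
        log.warning("verifier class imbalance %.0f:1", ratio)
    x = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])[:, None]
    rng = np.random.default_rng(seed)
    model = nn.Sequential(
        [
            nn.Dense(x.shape[1], 128, activation="relu", rng=rng),
            nn.Dense(128, 32, activation="relu", rng=rng),
            nn.Dense(32, 1, activation="sigmoid", rng=rng),
        ]
    )
    model.fit(x, y, epochs=epochs, batch_size=batch_size, rng=rng)
    return Verifier(model, x.shape[1])
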