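"""Reproducible end-to-end recovery experiments on synthetic data.

These are the package's reference experiments: they generate data with the
synthetic module under fixed study conditions, run the full pipelines, and
report recovery metrics.  Both the test suite and the reproduction script
call them, so the numbers they produce are always recomputed from scratch.

Problem sizes are chosen for single-CPU runs: the emotion experiment uses
10 animals x 4 videos of 4 s each; the event experiment trains per-variable
detectors on four 8 s clips and evaluates on a 24 s clip.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import emotion as em
from . import events as ev
from .metrics import overlap_confusion
from .scheme import LandmarkScheme, default_scheme
from .series import LandmarkSeries, normalize_series
from .synthetic import (
    EventSpec,
    SimulationConfig,
    canonical_face,
    default_profiles,
    simulate_emotion_dataset,
    simulate_series,
)
from .windowing import split_windows

#: Event repertoire of the two-condition emotion experiment.  Rates are the
#: base occurrences/minute before class multipliers; amplitudes are the
#: generator default (0.25 IOD).  The separation follows the observed motif:
#: ears-adductor marks the positive condition, blink / nose-lick /
#: ears-flattener the negative one.
EMOTION_BASE_EVENTS = (
    EventSpec("Ears Adductor (EAD102)", 90.0),
    EventSpec("Blink (AU145)", 90.0),
    EventSpec("Nose Lick (AD137)", 45.0),
    EventSpec("Ears Flattener (EAD103)", 45.0),
)


def emotion_recovery(
    seed: int = 42,
    *,
    n_animals: int = 10,
    videos_per_animal: int = 4,
    T: int = 100,
    train_step: int = 3,
    include_null: bool = True,
    scheme: LandmarkScheme | None = None,
) -> dict:
    """LOAO emotion-classification recovery under separated class profiles.

    Returns pooled metrics of the real run and, when requested, of a
    shuffled-label null run (labels permuted across videos, pipeline
    otherwise identical).
    """
    scheme = scheme or default_scheme()
    base = SimulationConfig(T=T, events=EMOTION_BASE_EVENTS, missing_rate=0.02,
                            seed=seed)
    data, _ = simulate_emotion_dataset(
        n_animals, videos_per_animal, default_profiles(), base, seed, scheme
    )
    data = [normalize_series(s, scheme) for s in data]
    cfg = em.ClassifierConfig.fast(seed=seed)
    result = {
        "pooled": em.loao_cv(data, cfg, scheme, step=train_step)["pooled"],
        "n_videos": len(data),
    }
    if include_null:
        rng = np.random.default_rng(seed + 1)
        labels = [s.label for s in data]
        perm = rng.permutation(len(labels))
        null_data = [replace(s, label=labels[perm[i]]) for i, s in enumerate(data)]
        result["null_pooled"] = em.loao_cv(null_data, cfg, scheme,
                                           step=train_step)["pooled"]
    return result


def _train_detector(
    variable: str,
    train_series: list[LandmarkSeries],
    truth: dict,
    scheme: LandmarkScheme,
    seed: int,
    config: ev.DetectorConfig | None = None,
) -> ev.EventDetector:
    cfg = config or ev.DetectorConfig(variable=variable, seed=seed)
    ws = ev.normal_windows_for_variable(train_series, truth, cfg, scheme)
    train, val, _ = split_windows(ws, (0.80, 0.15, 0.05), seed=seed)
    return ev.train_autoencoder(train, cfg, validation_windows=val)


def _permuted_null_f1(
    truth, sequences, T: int, rng: np.random.Generator, n_perm: int = 20
) -> float:
    """Mean F1 after relocating each predicted interval uniformly in [0, T)."""
    f1s = []
    for _ in range(n_perm):
        shuffled = []
        for q in sequences:
            length = q.end_frame - q.start_frame
            start = int(rng.integers(0, max(T - length, 1)))
            shuffled.append((start, start + length))
        f1s.append(overlap_confusion(truth, shuffled).f1)
    return float(np.mean(f1s)) if f1s else 0.0


def event_detection_recovery(
    seed: int = 77,
    *,
    noise_sd: float = 0.02,
    amplitude_factor: float = 4.0,
    n_train_series: int = 4,
    T_train: int = 200,
    T_eval: int = 600,
    point_variable: str = "Blink (AU145)",
    trend_variable: str = "Ears Flattener (EAD103)",
    trend_duration: int = 150,
    fast: bool = False,
    scheme: LandmarkScheme | None = None,
) -> dict:
    """Point-event and long-state recovery of the full anomaly-detection chain.

    One face template throughout (the detector operates within one video
    pool).  Training clips carry only an out-of-region variable, so the
    target variables never leak into the normal pools; the point evaluation
    clip has rare 5-frame events of amplitude ``amplitude_factor`` x the
    landmark jitter, the trend clip long states of the same amplitude
    covering about half its frames.
    """
    scheme = scheme or default_scheme()
    amplitude = amplitude_factor * noise_sd
    template = canonical_face(scheme, seed=seed)

    train_cfg = SimulationConfig(
        T=T_train,
        events=(EventSpec("Jaw Drop (AU26)", 20.0),),
        noise_sd=noise_sd,
        missing_rate=0.02,
        seed=seed,
    )
    train_series, truth = [], {}
    for k in range(n_train_series):
        s, evts = simulate_series(
            replace(train_cfg, seed=seed + k),
            template,
            scheme,
            video_id=f"train-{k}",
            rng=np.random.default_rng(seed + k),
        )
        train_series.append(normalize_series(s, scheme))
        truth[f"train-{k}"] = evts

    def _cfg(variable):
        if fast:
            return ev.DetectorConfig.fast(variable, seed=seed)
        return ev.DetectorConfig(variable=variable, seed=seed)

    out: dict = {}
    rng = np.random.default_rng(seed + 1000)

    # point events: ~10 rare 5-frame sections in the evaluation clip
    point_rate = 10.0 * 60.0 * 25.0 / T_eval
    point_cfg = SimulationConfig(
        T=T_eval,
        events=(EventSpec(point_variable, point_rate, amplitude=amplitude),),
        noise_sd=noise_sd,
        missing_rate=0.0,
        seed=seed + 500,
    )
    eval_point, truth_point = simulate_series(
        point_cfg, template, scheme, video_id="eval-point",
        rng=np.random.default_rng(seed + 500),
    )
    eval_point = normalize_series(eval_point, scheme)
    det_point = _train_detector(point_variable, train_series, truth, scheme,
                                seed, _cfg(point_variable))
    seqs, conf = ev.detect_events({point_variable: det_point}, eval_point,
                                  scheme, truth=truth_point)
    c = conf[point_variable]
    out["point"] = {
        "n_sections": len(truth_point),
        "n_sequences": len(seqs[point_variable]),
        "precision": c.precision,
        "recall": c.recall,
        "f1": c.f1,
    }
    out["point"]["null_f1"] = _permuted_null_f1(
        truth_point, seqs[point_variable], T_eval, rng
    )

    # long states of equal amplitude covering about half the clip
    trend_rate = 10.0 * 60.0 * 25.0 / T_eval
    trend_cfg = SimulationConfig(
        T=T_eval,
        events=(EventSpec(trend_variable, trend_rate, amplitude=amplitude,
                          duration_frames=trend_duration),),
        noise_sd=noise_sd,
        missing_rate=0.0,
        seed=seed + 600,
    )
    eval_trend, truth_trend = simulate_series(
        trend_cfg, template, scheme, video_id="eval-trend",
        rng=np.random.default_rng(seed + 600),
    )
    eval_trend = normalize_series(eval_trend, scheme)
    det_trend = _train_detector(trend_variable, train_series, truth, scheme,
                                seed, _cfg(trend_variable))
    seqs_t, conf_t = ev.detect_events({trend_variable: det_trend}, eval_trend,
                                      scheme, truth=truth_trend)
    ct = conf_t[trend_variable]
    covered = sum(t.n_frames for t in truth_trend)
    out["trend"] = {
        "n_sections": len(truth_trend),
        "coverage": covered / T_eval,
        "precision": ct.precision,
        "recall": ct.recall,
        "f1": ct.f1,
    }
    return out
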