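"""Synthetic landmark-sequence generator.

Emulates the statistical structure the analysis pipelines assume, so every
stage is testable without video data: a 46-point face template under smooth
global similarity motion (random-walk translation / rotation / log-scale),
short localized facial events that displace one face region's landmarks
along a fixed per-variable direction with a ramped amplitude, per-landmark
Gaussian jitter, and frame dropouts (zero-confidence empty frames).

Events are emitted as ground truth the way human coders record them: in
consecutive 5-frame sections (0.2 s at 25 fps), so a long-lasting state
becomes a run of adjacent sections while a point event is a single section.
The event motifs are geometric stand-ins — a fixed displacement direction
per DogFACS variable — not anatomically validated renderings of real dog
facial actions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .annotations import AnnotatedImage
from .scheme import LandmarkScheme, VARIABLE_CATEGORY
from .series import EventAnnotation, LandmarkSeries

SECTION_FRAMES = 5  # one coding section = 5 frames (0.2 s at 25 fps)


@dataclass(frozen=True)
class EventSpec:
    """One simulated DogFACS variable: rate, amplitude and duration.

    Amplitude is in IOD units (the template has IOD = 1); duration must be a
    whole number of coding sections.
    """

    variable: str
    rate_per_min: float
    amplitude: float = 0.25
    duration_frames: int = SECTION_FRAMES

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ParameterError("event rate must be >= 0")
        if self.duration_frames < 1:
            raise ParameterError("event duration must be >= 1 frame")
        if self.duration_frames % SECTION_FRAMES:
            raise ParameterError(
                f"duration must be a multiple of {SECTION_FRAMES} frames"
            )


@dataclass(frozen=True)
class MotionModel:
    """Global similarity-motion parameters.

    Translation follows a random walk (position in frame is unconstrained
    and is removed by normalization anyway).  Orientation and log-scale are
    mean-reverting (Ornstein–Uhlenbeck) around the front-facing pose: a
    recorded dog's head pose fluctuates around facing the camera rather than
    drifting without bound, and rotation survives normalization, so its
    stationary spread must not grow with clip length.

    ``rotation_sd`` / ``log_scale_sd`` are the *stationary* standard
    deviations; the ``*_tau`` values are reversion timescales in frames.
    """

    translation_sd: float = 1.0  # pixels / frame (random-walk step)
    rotation_sd: float = 0.05  # radians, stationary sd (~3 degrees)
    rotation_tau: float = 40.0  # frames
    log_scale_sd: float = 0.03  # log-units, stationary sd
    log_scale_tau: float = 60.0  # frames


@dataclass(frozen=True)
class RegionDrift:
    """Slow natural variation of one region along a variable's direction.

    Emulates sustained-state variability that is present in *normal*
    footage: a dog's ear carriage, for example, wanders continuously even
    when no event is coded, so sustained ear configurations are part of the
    normal manifold.  ``sd`` is the stationary standard deviation of the
    Ornstein–Uhlenbeck displacement (IOD units), ``tau`` its reversion
    timescale in frames.
    """

    variable: str
    sd: float = 0.05
    tau: float = 80.0


def default_drift() -> tuple[RegionDrift, ...]:
    """Normal-state drift of the trend-prone ear variables."""
    return (
        RegionDrift("Ears Flattener (EAD103)", sd=0.05, tau=80.0),
        RegionDrift("Ears Forward (EAD101)", sd=0.05, tau=80.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of one simulated video.

    Defaults mirror the recording conditions the pipelines target: 25 fps
    video, ~10 s clips, faces around 50 px inter-ocular distance with smooth
    head motion, 2% landmark jitter (of IOD) and occasional whole-frame
    detection dropouts.
    """

    fps: float = 25.0
    T: int = 250
    motion: MotionModel = field(default_factory=MotionModel)
    noise_sd: float = 0.02  # per-landmark jitter, IOD units
    missing_rate: float = 0.02  # probability a frame is empty
    missing_burst: float = 0.0  # continuation prob of a dropout run (0 = i.i.d.)
    events: tuple[EventSpec, ...] = ()
    drift: tuple[RegionDrift, ...] = field(default_factory=default_drift)
    base_scale: float = 50.0  # pixels per IOD unit
    base_center: tuple[float, float] = (128.0, 128.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or self.fps <= 0:
            raise ParameterError("need T >= 1 and fps > 0")
        if not (0 <= self.missing_rate < 1):
            raise ParameterError("missing_rate must be in [0, 1)")
        for ev in self.events:
            if ev.duration_frames > self.T:
                raise ParameterError(
                    f"event {ev.variable!r} duration exceeds series length"
                )


@dataclass(frozen=True)
class ClassProfile:
    """Per-class event-rate multipliers for the two emotion conditions.

    The default profiles follow the generative motif that the ears-adductor
    action is elevated in the positive condition while blinking, nose licks
    and ear flattening are elevated in the negative condition.
    """

    name: str
    rate_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, m in self.rate_multipliers.items():
            if m < 0:
                raise ParameterError(f"multiplier for {v!r} must be >= 0")

    def scaled_events(self, events: tuple[EventSpec, ...]) -> tuple[EventSpec, ...]:
        return tuple(
            replace(ev, rate_per_min=ev.rate_per_min * self.rate_multipliers.get(ev.variable, 1.0))
            for ev in events
        )


def default_profiles() -> tuple[ClassProfile, ClassProfile]:
    positive = ClassProfile(
        "positive",
        {
            "Ears Adductor (EAD102)": 1.0,
            "Blink (AU145)": 0.1,
            "Nose Lick (AD137)": 0.0,
            "Ears Flattener (EAD103)": 0.0,
        },
    )
    negative = ClassProfile(
        "negative",
        {
            "Ears Adductor (EAD102)": 0.0,
            "Blink (AU145)": 1.0,
            "Nose Lick (AD137)": 1.0,
            "Ears Flattener (EAD103)": 1.0,
        },
    )
    return positive, negative


# ---------------------------------------------------------------------------
# face template
# ---------------------------------------------------------------------------


def canonical_face(
    scheme: LandmarkScheme, seed: int, jitter_sd: float = 0.02
) -> np.ndarray:
    """A symmetric 46-point face template with IOD exactly 1.

    Regions are spatially coherent (ears above the eye line, nose/mouth
    below, contour surrounding); per-animal shape jitter of scale
    ``jitter_sd`` (IOD units) is drawn from ``seed`` and the template is
    re-normalized so the eye-corner distance is exactly 1.  Coordinates
    follow the image convention (y grows downward), so "above" means
    smaller y.
    """
    n = scheme.n_landmarks
    pts = np.zeros((n, 2))

    def _arc(indices, center, rx, ry, a0, a1, side=1):
        # side=-1 mirrors the x offsets, keeping left/right symmetric
        angles = np.linspace(a0, a1, len(indices))
        for k, j in enumerate(indices):
            pts[j] = center + np.array(
                [side * rx * np.cos(angles[k]), ry * np.sin(angles[k])]
            )

    eyes = list(scheme.region_indices("eyes"))
    half = len(eyes) // 2
    # outer corner first in each half, then a small ellipse per eye
    for side, idx in ((-1, eyes[:half]), (+1, eyes[half:])):
        pts[idx[0]] = np.array([side * 0.5, 0.0])
        _arc(idx[1:], np.array([side * 0.62, 0.0]), 0.10, 0.06, 0.3, 2 * np.pi - 0.3,
             side=side)

    ears = list(scheme.region_indices("ears"))
    half = len(ears) // 2
    for side, idx in ((-1, ears[:half]), (+1, ears[half:])):
        _arc(idx, np.array([side * 0.75, -0.85]), 0.22, 0.35, -np.pi / 2, np.pi / 2,
             side=side)

    nm = list(scheme.region_indices("nose_mouth"))
    third = len(nm) // 3
    _arc(nm[:third], np.array([0.0, 0.55]), 0.16, 0.10, 0, 2 * np.pi)  # nose
    _arc(nm[third:], np.array([0.0, 0.95]), 0.42, 0.22, 0.2, np.pi - 0.2)  # mouth

    remaining = sorted(set(range(n)) - set(eyes) - set(ears) - set(nm))
    _arc(remaining, np.array([0.0, 0.1]), 1.15, 1.25, -np.pi, 0.0)  # contour/brows

    rng = np.random.default_rng(seed)
    pts = pts + rng.normal(scale=jitter_sd, size=pts.shape)
    a, b = scheme.iod_pair
    iod = np.linalg.norm(pts[a] - pts[b])
    pts = (pts - pts.mean(axis=0)) / iod
    return pts


def _variable_direction(variable: str, n_region: int) -> np.ndarray:
    """Deterministic unit displacement pattern for one DogFACS variable.

    Derived from a hash of the variable name so each variable has a distinct
    but reproducible motion signature over its region's landmarks.
    """
    digest = hashlib.sha256(variable.encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    d = rng.normal(size=(n_region, 2))
    # RMS per-landmark displacement 1, so amplitude = typical landmark motion
    return d / np.sqrt(np.mean(np.sum(d * d, axis=1)))


# ---------------------------------------------------------------------------
# series simulation
# ---------------------------------------------------------------------------


def _draw_event_starts(
    rng: np.random.Generator, spec: EventSpec, T: int, fps: float
) -> list[int]:
    """Poisson-process event starts, non-overlapping for one variable."""
    expected = spec.rate_per_min * T / (fps * 60.0)
    n = rng.poisson(expected)
    starts: list[int] = []
    max_start = T - spec.duration_frames
    if max_start < 0:
        return starts
    candidates = rng.integers(0, max_start + 1, size=n)
    for s in sorted(candidates.tolist()):
        if all(
            s + spec.duration_frames <= t or t + spec.duration_frames <= s
            for t in starts
        ):
            starts.append(int(s))
    return starts


def _ou_path(
    rng: np.random.Generator, T: int, stationary_sd: float, tau: float
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path around 0 (discrete AR(1) form)."""
    if stationary_sd == 0:
        return np.zeros(T)
    rho = np.exp(-1.0 / tau)
    x = np.empty(T)
    x[0] = rng.normal(scale=stationary_sd)
    step_sd = stationary_sd * np.sqrt(1.0 - rho * rho)
    for t in range(1, T):
        x[t] = rho * x[t - 1] + rng.normal(scale=step_sd)
    return x


def _ramp(duration: int) -> np.ndarray:
    """Trapezoidal amplitude envelope: brief onset/offset ramps, full-amplitude
    plateau in between (a coded section shows the movement through most of
    its span, not only at its midpoint)."""
    r = max(1, duration // 4)
    env = np.ones(duration)
    up = (np.arange(1, r + 1)) / (r + 1)
    env[:r] = up
    env[duration - r :] = up[::-1]
    return env


def simulate_series(
    config: SimulationConfig,
    template: np.ndarray,
    scheme: LandmarkScheme,
    *,
    video_id: str = "sim",
    animal_id: str = "animal-0",
    label: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LandmarkSeries, list[EventAnnotation]]:
    """Simulate one raw (pixel-space) landmark series plus its ground truth.

    Per frame: template → per-variable event offsets (region landmarks
    displaced along the variable's direction, amplitude ramped over the
    event) → Gaussian jitter → global similarity transform (smooth random
    walk) → frame dropouts zeroed.  Ground-truth annotations chop each event
    into consecutive 5-frame coding sections.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T, n = config.T, scheme.n_landmarks
    if template.shape != (n, 2):
        raise ParameterError(f"template must be ({n}, 2)")

    offsets = np.zeros((T, n, 2))
    annotations: list[EventAnnotation] = []
    for spec in config.events:
        region = scheme.region_for_variable(spec.variable)
        idx = list(scheme.region_indices(region))
        direction = _variable_direction(spec.variable, len(idx))
        ramp = _ramp(spec.duration_frames)
        for s in _draw_event_starts(rng, spec, T, config.fps):
            for k in range(spec.duration_frames):
                offsets[s + k, idx, :] += spec.amplitude * ramp[k] * direction
            for sec in range(0, spec.duration_frames, SECTION_FRAMES):
                annotations.append(
                    EventAnnotation(
                        start_frame=s + sec,
                        end_frame=s + min(sec + SECTION_FRAMES, spec.duration_frames)
                        - 1,
                        variable=spec.variable,
                        category=VARIABLE_CATEGORY[spec.variable],
                    )
                )

    # slow normal-state drift of trend-prone regions
    for dr in config.drift:
        region = scheme.region_for_variable(dr.variable)
        idx = list(scheme.region_indices(region))
        direction = _variable_direction(dr.variable, len(idx))
        path = _ou_path(rng, T, dr.sd, dr.tau)
        offsets[:, idx, :] += path[:, None, None] * direction[None, :, :]

    # smooth global similarity motion
    m = config.motion
    trans = np.cumsum(rng.normal(scale=m.translation_sd, size=(T, 2)), axis=0)
    angle = _ou_path(rng, T, m.rotation_sd, m.rotation_tau)
    scale = config.base_scale * np.exp(
        _ou_path(rng, T, m.log_scale_sd, m.log_scale_tau)
    )
    center = np.asarray(config.base_center)

    coords = np.empty((T, n, 2))
    for t in range(T):
        frame = template + offsets[t] + rng.normal(scale=config.noise_sd, size=(n, 2))
        ca, sa = np.cos(angle[t]), np.sin(angle[t])
        R = np.array([[ca, -sa], [sa, ca]])
        coords[t] = scale[t] * frame @ R.T + center + trans[t]

    # frame dropouts: i.i.d. by default, optional geometric bursts
    conf = np.ones(T)
    if config.missing_rate > 0:
        if config.missing_burst > 0:
            missing = np.zeros(T, dtype=bool)
            state = False
            for t in range(T):
                p = config.missing_burst if state else config.missing_rate
                state = rng.random() < p
                missing[t] = state
        else:
            missing = rng.random(T) < config.missing_rate
        coords[missing] = 0.0
        conf[missing] = 0.0

    series = LandmarkSeries(
        video_id=video_id,
        animal_id=animal_id,
        fps=config.fps,
        coords=coords,
        confidence=conf,
        label=label,
        normalized=False,
    )
    annotations.sort()
    return series, annotations


def simulate_emotion_dataset(
    n_animals: int,
    videos_per_animal: int,
    profiles: tuple[ClassProfile, ClassProfile],
    base_config: SimulationConfig,
    seed: int,
    scheme: LandmarkScheme,
) -> tuple[list[LandmarkSeries], dict[str, list[EventAnnotation]]]:
    """Simulate a labeled two-condition dataset of ``n_animals`` dogs.

    Each animal keeps one face-shape template across all its videos (so
    identity leaks are detectable in cross-validation tests); video classes
    alternate within an animal, and each video's event rates follow its
    class profile.  Returns the labeled series plus ground-truth events per
    video id.
    """
    if len(profiles) != 2 or profiles[0].name == profiles[1].name:
        raise ParameterError("need two distinct class profiles")
    rng = np.random.default_rng(seed)
    dataset: list[LandmarkSeries] = []
    truth: dict[str, list[EventAnnotation]] = {}
    for a in range(n_animals):
        template = canonical_face(scheme, seed=int(rng.integers(2**31)))
        animal_id = f"dog-{a:02d}"
        for v in range(videos_per_animal):
            profile = profiles[(a + v) % 2]
            cfg = replace(base_config, events=profile.scaled_events(base_config.events))
            video_id = f"{animal_id}/video-{v:02d}"
            series, events = simulate_series(
                cfg,
                template,
                scheme,
                video_id=video_id,
                animal_id=animal_id,
                label=profile.name,
                rng=np.random.default_rng(int(rng.integers(2**31))),
            )
            dataset.append(series)
            truth[video_id] = events
    return dataset, truth


def make_fixture_annotations(
    n_images: int,
    scheme: LandmarkScheme,
    noise_sd: float,
    seed: int,
) -> tuple[list[AnnotatedImage], list[np.ndarray]]:
    """Ground-truth images plus noisy predictions for metric evaluation.

    Ground truth: per-image face templates under random similarity
    transforms (scale 30–80 px, rotation ±20°, random translation).
    Predictions: ground truth plus isotropic Gaussian noise with standard
    deviation ``noise_sd`` *relative to each image's IOD*, so the expected
    L1 NME (×100 scale) is 100·2·noise_sd·sqrt(2/π) independent of image
    scale.
    """
    if n_images < 1:
        raise ParameterError("need n_images >= 1")
    rng = np.random.default_rng(seed)
    gt: list[AnnotatedImage] = []
    preds: list[np.ndarray] = []
    for i in range(n_images):
        template = canonical_face(scheme, seed=int(rng.integers(2**31)))
        s = rng.uniform(30.0, 80.0)
        theta = rng.uniform(-np.pi / 9, np.pi / 9)
        c, si = np.cos(theta), np.sin(theta)
        R = np.array([[c, -si], [si, c]])
        t = rng.uniform(100.0, 400.0, size=2)
        pts = s * template @ R.T + t
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        pad = 0.1 * (hi - lo)
        bbox = (
            float(lo[0] - pad[0]),
            float(lo[1] - pad[1]),
            float(hi[0] - lo[0] + 2 * pad[0]),
            float(hi[1] - lo[1] + 2 * pad[1]),
        )
        img = AnnotatedImage(image_id=f"img-{i:04d}", face_bbox=bbox, points=pts)
        iod = img.iod(scheme)
        gt.append(img)
        preds.append(pts + rng.normal(scale=noise_sd * iod, size=pts.shape))
    return gt, preds
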