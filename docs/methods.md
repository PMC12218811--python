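# Methods

This note documents the models, conventions and design choices behind
`faceflow`, in the order data flows through the package.

## Landmark series and normalization

A series is a `(T, 46, 2)` coordinate array plus a per-frame confidence in
[0, 1].  Coordinates follow the image convention (origin top-left, x right,
y down, pixels).  Confidence exactly 0 marks an *empty frame* — no face
detected — whose coordinates are all zero by invariant.  Empty frames are
never interpolated: imputed landmarks would inject artificial sequences
with no relation to the footage, so downstream windowing simply refuses any
window that touches one.

Normalization is per frame: translate so the 46-landmark centroid is at the
origin, then scale so the inter-ocular distance (IOD, the distance between
the outer eye corners) equals 1.  This makes windows invariant to face
position and size but **not** to rotation — deliberately, since facial
events include rotations of face parts and head pose itself carries signal.
A frame whose IOD is exactly 0 cannot be scaled; it is demoted to an empty
frame with a warning rather than failing the series, mirroring how
undetectable faces are handled.  The operation is idempotent.

Serialization uses shortest round-trip float formatting and a
`float_precision="round_trip"` parser, so write→read is exact for float64
and write→read→write is byte-identical.

Seconds-based event annotations convert to inclusive frames as
floor(start·fps) .. ceil(end·fps)−1 (conservative coverage), with a 1e-9
epsilon guarding against binary-float artefacts (0.6·25 is not exactly 15
in floating point).

## Windowing

Dense windows take L consecutive rows with step S.  Sparse windows keep L
rows but map row *i* to source offset round(*i*·native_fps/target_fps)
(round half up), which for integer rate ratios skips (ratio−1) rows — a
plain sliding window at a reduced frame rate.  Non-integer ratios (e.g. an
effective 14 fps from 25 fps native) are handled by the same rounding map
rather than by resampling, which would interpolate frames.  A window
survives only if all its sampled rows are in range and non-empty.

Class balancing downsamples every class to the minority count without
replacement (seeded).  Train/validation/test splits floor-allocate the
validation and test sizes and give the remainder to train (so 100 windows
at 80:15:5 give exactly 80/15/5, and 7 windows give 6/1/0).

## Emotion classifier

Architecture: two bidirectional LSTM layers (defaults 64, 32 units per
direction) over the (L, 92) window, then four narrowing dense layers
(64, 32, 16, 1) ending in a sigmoid probability of the positive class.
Training: MSE loss on the sigmoid output (kept rather than cross-entropy),
Adam (lr 1e-3), batch 16, 300 epochs by default.  The `fast()` profile
(50 epochs, widths 32/16 and 32/16/8/1) exists so a complete LOAO run fits
in minutes on one CPU; the reference experiments use it.  Default windows
are sparse L=5 at an effective 14 fps.

A video is classified by majority vote over all its windows (vote =
probability > 0.5).  Ties break by comparing the mean window probability
with 0.5.  A video with no surviving window (all frames empty or clip
shorter than the window span) yields an abstention flagged in the result,
with a configurable fallback label (the training-set majority class in
LOAO).

Leave-one-animal-out cross-validation trains each fold only on windows
from other animals (balanced by downsampling, fold-specific seed offset)
and pools every held-out video prediction for the final metrics — identity
leakage across train/test is structurally impossible and is asserted in
tests.

## Event detector

One model per DogFACS variable.  The variable's category determines its
face region (upper-face AUs → eyes, lower-face AUs and action descriptors →
nose/mouth, ear action descriptors → ears), and windows are reduced to that
region's columns: localized movements live in few channels, and the reduced
dimensionality (L=15, step 1) keeps the autoencoder small.

The autoencoder stacks two bidirectional LSTM layers with ReLU activation
and recurrent dropout 0.2 in both encoder and decoder (defaults 32/16
encode, 16/32 decode — sized so the printed 200-epoch training runs on one
CPU; all widths are config-exposed), a repeat-vector bridge from the final
encoder state, and a linear time-distributed output layer.  It trains on
*normal* windows only: windows that overlap a ground-truth section of the
target variable at all are excluded from the pool (strict hygiene; a
data-leak error fires if ground truth is supplied and violated), while
windows containing other variables stay — the detector must treat them as
normal.

Scoring chain, per series:

1. **Window errors.**  Per-channel MAE between each window and its
   reconstruction.  Each window's error vector is credited to every frame
   the window covers, and a frame's error is the mean over covering
   windows.  (A causal last-frame assignment was tried first and rejected:
   it delays the response by up to L−1 frames, so flagged runs
   systematically trail the 5-frame truth sections and overlap-based recall
   collapses.)
2. **EWMA smoothing** per channel, s′ₜ = α·sₜ + (1−α)·s′ₜ₋₁ with α = 0.3 by
   default; unscored gaps reset the recursion.
3. **Thresholds** per channel from the training-window error distribution:
   mean + k·sd with k = 3 (population sd; degenerate channels floor at
   mean + 1e-8).
4. **Aggregate score** per frame: max over channels of
   (error − threshold)/threshold — a frame is anomalous if *any* channel
   exceeds its threshold, which suits events that move few channels.
5. **Edge masking**: the first and last `margin` frames of each contiguous
   scored segment (default L−1) take the track minimum; reconstruction
   scores are unreliable where window coverage starts or ends.
6. **Sequences**: maximal runs of positive aggregate become predicted
   sequences (merge gap 0; "continuous" instances only), each carrying its
   peak score.
7. **Pruning**: sort peaks descending and remove the maximal tail in which
   every successive relative drop stays below p = 0.13 — true anomalies
   stand out by a sharp drop to the error floor.  The highest peak always
   survives.

Dataset-level evaluation (`evaluate_variables`) pools TP/FP/FN per variable
across series and skips variables with fewer than 20 ground-truth sections
in the set — too few events for a meaningful rate.

Evaluation counts by truth *section*: a coded section overlapping ≥1
predicted sequence (≥1 shared frame; no minimum-overlap fraction) is one
TP; an unmatched section one FN; a predicted sequence overlapping no
section one FP.  Precision/recall/F1 are unweighted, with the 0/0 → 0
convention.

The per-frame intensity export min–max-normalizes each variable's
aggregate track over its scored frames and takes the per-frame maximum
across variables — a single [0, 1] bar that points an annotator at likely
events.

## Keypoint metric

NME_iod = 1/(M·N) Σᵢ Σⱼ ‖xᵢʲ − x′ᵢʲ‖₁ / iodᵢ, with the per-image IOD from
the ground-truth eye corners.  The 1-norm of the per-point coordinate error
is the default, matching the printed convention; `norm="l2"` switches to
Euclidean (always ≤ the L1 value, property-tested).  Values are stored and
reported ×100 — i.e. percent of IOD, the scale on which detector benchmarks
quote errors like 6.52 — and images with zero IOD are excluded with a
warning.

## Synthetic generator

The generator emulates the statistical structure the pipelines assume:

- **Template**: a symmetric 46-point face with IOD exactly 1, regions
  spatially coherent; per-animal shape jitter (default sd 0.02 IOD) is
  fixed across an animal's videos so identity leakage is detectable.
- **Global motion**: translation as a random walk (removed by
  normalization); orientation and log-scale as stationary
  Ornstein–Uhlenbeck processes (defaults: rotation sd 0.05 rad, τ = 40
  frames; log-scale sd 0.03, τ = 60).  Mean reversion matters: a recorded
  dog's head pose fluctuates around facing the apparatus, and an unbounded
  rotation walk would drift long clips into orientations a training pool
  never covers, which (since rotation survives normalization) reads as
  wholesale anomaly.
- **Events**: starts drawn from a Poisson process at the configured
  rate/minute, non-overlapping per variable.  An active event displaces the
  variable's region landmarks along a fixed per-variable direction pattern
  (hash-seeded, RMS-normalized so "amplitude" is the typical per-landmark
  displacement, in IOD units; default 0.25) with a trapezoidal envelope —
  brief onset/offset, full amplitude through the section.  Ground truth is
  emitted the way coders record it: consecutive 5-frame sections, so a long
  state becomes a run of sections and a point event a single one.
- **Normal-state drift**: by default the ear region also wanders slowly
  (OU, sd 0.05 IOD, τ = 80) along the directions of the two trend-prone ear
  variables.  This encodes a property of real footage: ear carriage varies
  continuously even when no event is coded, so *sustained* ear
  configurations lie near the normal manifold.  It is what makes the
  detector genuinely trend-blind — long states of the same amplitude as a
  detectable point event are largely reconstructed as normal — rather than
  having that behaviour asserted into the tests.
- **Dropouts**: i.i.d. empty frames at `missing_rate` (default 0.02), with
  an optional geometric burst mode for "dog turned away" stretches.
- **Emotion dataset**: two class profiles multiply the base event rates —
  the positive condition elevates ears-adductor, the negative condition
  blink, nose-lick and ears-flattener (a generative motif, not a biological
  claim).  Classes alternate within each animal.
- **Keypoint fixtures**: templates under random similarity transforms
  (scale 30–80 px, rotation ±20°); predictions add Gaussian noise whose sd
  is specified *relative to each image's IOD*, so the expected L1 NME ×100
  is 100·2·sd·√(2/π) independent of image scale.

What the generator does **not** emulate: real canine facial-action
kinematics (event motifs are geometric stand-ins with fixed directions),
breed morphology, fur, occlusions, correlated detector noise, or the
continuous confidence scores of a real landmark verifier (confidence is
binary here).  Passing recovery tests therefore shows that the pipelines
correctly recover the structure they assume — not that the pipelines reach
any particular accuracy on real video.

## Reference experiments and problem sizes

`faceflow.benchmarks` fixes the two end-to-end experiments:

- **Emotion recovery**: 10 animals × 4 videos of 100 frames (4 s at
  25 fps), strongly separated profiles (base rates 90/90/45/45 events per
  minute), fast training profile, training windows at step 3, LOAO plus an
  identical run with labels shuffled across videos as the chance reference.
  With the shipped seeds this yields pooled accuracy 0.90 against a null of
  0.43.
- **Event recovery**: four 200-frame training clips and one 600-frame
  evaluation clip sharing one face template (the detector operates within
  one video pool; cross-identity transfer is a documented limitation, not a
  supported use).  Point scenario: ~10 rare blink sections at amplitude 4×
  the landmark jitter.  Trend scenario: 150-frame ears-flattener states of
  equal amplitude covering well over half the clip.  With the shipped seeds
  the full chain at defaults reaches point recall 0.90 (F1 0.86 versus a
  permuted-prediction null of 0.31) and trend recall 0.21 — the
  trend-blindness ordering in action.

These sizes were chosen so each experiment runs in a few minutes on a
single CPU while leaving the recovery margins wide.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.Generator` objects seeded from
  explicit integers; training is bit-reproducible for a given seed on a
  given platform (identical weight hashes are asserted in tests).
  Cross-platform bit-exactness is not guaranteed.
- The nn core is float64 throughout, with Glorot-uniform initialization,
  forget-gate bias 1, global gradient-norm clipping at 5, and
  backpropagation verified against finite differences.
- Sparse-stride rounding is floor(x + 0.5) (half up), not banker's
  rounding, for determinism across inputs.
- Zero-denominator metric cases (no positive predictions, empty sequence
  lists, constant intensity tracks) all resolve to 0 rather than NaN.
- `LandmarkScheme` validates region disjointness, IOD-pair membership in
  the eye region, and full category coverage at construction.

## Known limitations

- The shipped 46-point scheme is a synthetic stand-in with the right
  region structure, not the anatomical placement manual; real deployments
  should load their scheme from YAML.
- Detectors do not transfer across face identities; train and apply within
  one pool of clips.
- Long-lasting states are under-detected by design of the method (that is
  the documented trend-blindness), and gaze/head-direction variables are
  out of scope.
- The image-side landmark detector itself (producing the series from
  video) is outside this package; `faceflow` starts at the landmark CSV.
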