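# faceflow

Landmark-based facial behaviour analysis for dogs: emotion classification
and DogFACS action-unit detection from facial-landmark time series.

## The problem

Coding dog facial behaviour — blinks, nose licks, ear movements — with the
Dog Facial Action Coding System (DogFACS) is slow, expert-bound manual work.
A lighter-weight alternative to frame-by-frame video inspection is to track
46 anatomy-based facial landmarks per frame and analyse the resulting
multivariate time series.  `faceflow` implements that analysis layer for
researchers in animal affective computing and canine science:

- **Landmark time series** — per-frame 46×(x, y) coordinates plus a
  detector-confidence value; frames with no detected face are kept as
  explicit zero-confidence "empty frames", never interpolated.  Each
  non-empty frame is normalized by centroid translation and inter-ocular
  distance (IOD) scaling.
- **Windowing** — dense sliding windows of shape (L, 92) with step S, and
  *sparse* windows that sample rows at a reduced effective frame rate
  (row *i* taken from offset round(*i*·native/target)), so a window covers a
  longer span at the same dimensionality.  Windows touching an empty frame
  are discarded.
- **Emotion classification** — a two-layer bidirectional-LSTM window
  classifier with a narrowing dense head (MSE loss on a sigmoid output,
  Adam, batch 16) votes per window; the video takes the majority class.
  Evaluation is leave-one-animal-out (LOAO) so the same dog never appears
  in both training and test.
- **DogFACS event detection** — one detector per DogFACS variable: a
  bidirectional-LSTM autoencoder trained on "normal" windows of the
  variable's face region (eyes / ears / nose-mouth).  Windows containing
  the unseen movement reconstruct poorly; per-channel mean absolute error
  is smoothed (EWMA), thresholded at mean + 3σ of the training errors,
  edge-masked, merged into sequences and pruned by the relative drop of
  sorted peak scores (p = 0.13).
- **Metrics** — the keypoint benchmark metric
  NME_iod = 1/(M·N) Σᵢ Σⱼ ‖xᵢʲ − x′ᵢʲ‖₁ / iodᵢ (reported ×100), and
  section-overlap TP/FP/FN with unweighted precision/recall/F1 for event
  detection.
- **Synthetic data** — a generator producing landmark series with the
  statistical structure the pipelines assume (smooth global similarity
  motion, localized ramped events coded as 5-frame sections, landmark
  jitter, frame dropouts, two emotion conditions differing in event-rate
  profiles), so everything is testable without any video data.

The recurrent models are implemented in a small, gradient-checked numpy
neural-network core (`faceflow.nn`), so the package has no deep-learning
framework dependency and trains its CPU-sized models deterministically.

## Worked example

Simulate a small two-condition dataset, train a blink detector, and detect
events in one clip:

```bash
faceflow simulate --out data/ --seed 7 --n-animals 2 --videos-per-animal 1 --frames 120
faceflow train-events --data data/ --variable "Blink (AU145)" --out model/ --seed 3 --fast
faceflow detect --model model/ --series data/dog-00_video-00.csv --out sequences.csv
```

which prints:

```
wrote 2 series + events to data
trained 'Blink (AU145)': validation MAE 0.02454
1 sequences -> sequences.csv
```

The validation MAE is the mean absolute reconstruction error of the
autoencoder on held-out normal windows (in normalized, IOD-relative
coordinate units); the detected sequence lands in `sequences.csv`:

```
variable,start_frame,end_frame,peak_score
Blink (AU145),44,67,0.99522276644014
```

i.e. one anomalous interval whose strongest channel exceeded its 3σ
threshold by 99.5%.  The generator's coded truth for this clip has a blink
section at frames 51–55, inside the detected interval, so scoring it:

```bash
faceflow eval-events --truth truth.csv --pred sequences.csv
```

prints the section-overlap confusion

```json
{"tp": 1, "fp": 0, "fn": 0, "precision": 1.0, "recall": 1.0, "f1": 1.0}
```

(one true positive under the ≥1-shared-frame overlap rule, no false
alarms).

The same steps are available as library calls; see
`faceflow.benchmarks.event_detection_recovery` for a complete, seeded
train-detect-evaluate experiment and `faceflow.benchmarks.emotion_recovery`
for the LOAO classification experiment.

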