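# Methods

## Scope and model

`blinkwatch` implements the classical image-processing route to driver
drowsiness estimation: locate the eye region, classify each frame's eye
state from the spatial distribution of dark pixels, reduce the state
stream to ocular indicators (blink events, blink frequency, long-blink
counts, PERCLOS), and map window-averaged pixel features to a
drowsiness level with a small neural network. Everything downstream of
the camera is covered; camera capture, alarm hardware, head-pose and
mouth cues are out of scope.

## Per-frame eye-state classifier

Chain: grayscale → gain normalization → Otsu binarization →
morphological cleanup → upper/lower split → ratio decision.

- **Grayscale** uses BT.601 weights, `Y = round(0.299R + 0.587G +
  0.114B)`, so hand-computed examples are exact.
- **Illumination normalization** multiplies the frame by
  `target_mean / mean(frame)` (target 128, then clip to [0, 255] and
  round). For a grayscale frame the HSV value channel equals the
  intensity, so this normalizes mean V. Division by a zero mean raises
  a degenerate-image error.
- **Otsu threshold** maximizes `ω₀(t)ω₁(t)(μ₀(t)−μ₁(t))²` over the
  256-bin histogram with `t ∈ [0, 254]`; the dark class is `≤ t`; ties
  break toward the smallest `t`; a constant image raises. The
  implementation agrees exactly, integer for integer, with an
  exhaustive search and with scikit-image's `threshold_otsu` (checked
  in tests; neither stands behind the implementation).
- **Cleanup** is morphological opening of the dark phase with a 3×3
  cross (scipy.ndimage): it removes isolated dark specks, never adds
  dark pixels, and is idempotent. Note a cross-opening clips the
  corners of square blobs — only unions of cross translates are
  invariant. Closing of the dark phase is available as a config
  alternative (`mode="close_dark"`).
- **Split**: upper half is rows `[0, floor(H/2))`, row 0 at the top;
  odd heights give the extra row to the lower half.
- **Decision**: `compound = upper_ratio / (lower_ratio + 1e-6)`;
  OPEN iff `compound > ratio_threshold` (default 1.0). Ties and
  degenerate (constant) crops classify CLOSED — for a safety monitor
  the ambiguous case must err toward the drowsy interpretation. A
  calibration helper sweeps candidate thresholds on a labeled set and
  picks the maximum balanced accuracy.

Binarization runs on the whole crop before the split, and the ε-guard
keeps the compound ratio finite when the lower half has no dark pixels.

## Eye localization

Integral images (zero-padded (H+1)×(W+1) cumulative-sum tables) give
any rectangle sum in four lookups. Haar features hold weighted
rectangles in base-window coordinates; a feature's score is the sum of
`weight × (rect_sum − rect_area × window_mean)`, divided by
`window_area × window_sd`. Mean-normalizing each rectangle makes every
constant window score exactly 0 at every scale (plain zero-area-sum
weighting breaks under integer rounding of scaled rectangles), and the
sd normalization (from integral images of x and x², floored at 1) is
the standard contrast compensation. A stage passes when its summed
feature contributions reach the stage threshold; evaluation
short-circuits at the first failing stage, which cannot change the
outcome. The scan is multiscale (geometric factor 1.2, step one eighth
of the window by default) and accepted windows merge by ≥ 50%
intersection-over-union; a group's representative box is the member
mean and its confidence the member count.

Cascade training is out of scope. The bundled fixture cascade is a
single center-surround stage (full 16×16 window weight +1, central 8×8
weight −4) that accepts windows whose center is markedly darker than
the surround — a pupil/iris disc detector, with hand-computable scores.
Pre-cropped synthetic sessions default to a fixed-ROI detector.

## Temporal metrics

Frames are 0-based; intervals half-open. A blink is any maximal run of
CLOSED frames, including runs touching either sequence end; its
duration is `(end − start) / fps`. Debouncing absorbs runs shorter than
`min_run_frames` (default 2) into the preceding run before event
extraction, suppressing single-frame classifier flicker; the first run
is exempt. PERCLOS over a window is the fraction of its frames
classified CLOSED (the binary-state variant; eyelid-aperture
refinements such as P70/P80 need more than a binary state). Long blinks
are events with duration ≥ 0.5 s, boundary inclusive — a conventional
microsleep-proximal cut, configurable. Rolling windows default to 300 s
with a 60 s stride; events belong to the window containing their start
frame, so none is double counted. A plotting helper draws the
upper/lower ratio traces with the compound signal multiplied by 3, a
display-only scaling that makes transitions legible at the ratio scale.

## Drowsiness scorer

Architecture `[2, 10, 10, 10, 1]`: three tansig hidden layers (the
layer count and activation are fixed by design; the widths of 10 are a
default, configurable) and a logistic output so the score lives in
[0, 1]. Inputs are the window means of the upper and lower dark-pixel
ratios, z-scored with training-split statistics that are stored in the
model for inference. Training is plain full-batch gradient descent on
MSE — learning rate 0.05, 1000 epochs, seeded uniform(−0.5, 0.5)
initialization, no momentum or adaptive steps — and the training loss
is recorded after every update. Backpropagation is exact (verified
against central finite differences at 1e−6 relative tolerance over 20
seeds). A non-finite loss aborts with the offending epoch. Accuracy
thresholds the continuous output at 0.5; MSE is computed on the raw
output.

## Synthetic data

The generators stand in for driver video, reproducing only the
features the method consumes.

- **Eye crops** are 64×32 by default. OPEN: a dark disc
  (`iris_gray` 40) of radius `0.35 × height` centered at 30% height on
  a light sclera (220), plus a one-pixel parabolic lash arc (60) near
  the top. CLOSED: the upper half filled with a light eyelid (200) and
  a three-row lash band (60) starting at 58% height (three rows so the
  cross opening keeps it). An overall illumination gain multiplies the
  clean image, then zero-mean Gaussian noise (sd 8 intensity units by
  default) is added and the result clipped to [0, 255]. Every image is
  a pure function of (state, params, seed).
- **Blink schedules**: onsets from a Poisson process (default 12
  blinks/min — a typical resting rate), durations truncated normal
  (mean 0.25 s, sd 0.08 s, floor one frame), stretched to ≥ 1.0 s with
  probability 0.05 (long blinks). A drowsiness level `d ∈ [0, 1]`
  scales the duration mean by `1 + 2d` and adds `0.35 d` to the
  long-blink probability; the random draws do not depend on `d`, so
  for a fixed seed the closed-frame set grows monotonically with the
  level. Overlapping blinks merge, which thins the realized event
  count slightly below the onset count. Sessions default to 60 s at
  10 fps, a scale at which the whole pipeline runs in seconds; frames
  get per-frame seeds derived by hashing (session seed, frame index)
  so any frame is reproducible in isolation.
- **Feature benchmark**: 9964 records (the reference corpus size for
  this class of system), balanced between an alert centroid
  (0.32, 0.04) and a drowsy centroid (0.10, 0.12) — window-mean
  (upper, lower) ratios typical of open-eye-dominated versus
  closure-heavy windows of the rendered crops — with isotropic
  Gaussian noise, sd 0.05. The centroids and noise were calibrated
  once so the default benchmark is cleanly learnable by the reference
  network, and then frozen. Labels are 0.0/1.0; 0.5 is the
  classification cut.

What the generator does **not** emulate: head pose, gaze, specular
reflections, eyelid aperture dynamics within a blink, camera blur,
compression artifacts, or rater-assigned drowsiness scales. Passing
tests therefore demonstrate the correctness and internal consistency of
the operators and the learnability of the feature geometry — not
field performance on real drivers.

## Numerical choices and degenerate inputs

- Rounding is `np.rint` (banker's at .5) after every intensity-scale
  operation; images stay uint8 between operators.
- The compound-ratio ε is 1e−6; window sd in the detector is floored
  at 1; feature standardization replaces zero stds with 1.
- `split_dataset` takes `floor(n × fraction)` training records after a
  seeded shuffle: 9964 records give 6974 train / 2990 test.
- Constant crops: classified CLOSED with a logged warning rather than
  erroring, so one blank frame cannot kill a run; a run aborts only
  when the detector misses more than half the frames (configurable).
- Unreadable frame files are skipped with a warning and keep their
  index, preserving downstream timestamps.

## Known limitations

- The binary eye state cannot express partial closure, so PERCLOS here
  is an upper-resolution-limited variant of the eyelid-coverage
  definitions used with aperture tracking.
- The fixture cascade detects dark discs, not eyes in cluttered
  scenes; real use requires an externally trained cascade.
- The drowsiness score is calibrated on window-level centroids; scores
  for mildly drowsy sessions sit well below the 0.5 cut and should be
  read as a monotone index, not a calibrated probability.
- Full-batch gradient descent is adequate at benchmark scale but slow
  for much larger corpora; that trade keeps the optimizer faithful to
  the design rather than performant.
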