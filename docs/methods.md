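# Methods

`swaygrade` estimates the intensity of static standing balance exercises on
the clinical 1–5 scale from body-worn IMU kinematics, and benchmarks the
estimate against the variability of human raters. Because no public dataset
of this kind exists, the package ships a first-class synthetic cohort
generator that reproduces the statistical structure of such a study; every
downstream component is exercised end-to-end on generated cohorts.

## Processing model

1. **Orientation.** Each IMU yields synchronized tri-axial acceleration
   (m/s²) and angular rate (rad/s) at 128 Hz. A static sensor-to-segment
   alignment maps the sensor axes to anatomical axes using the mean gravity
   direction during quiet standing (the minimal rotation carrying it onto
   (0, 0, −g); yaw about gravity is unconstrained and fixed at zero).
   Orientation is tracked with a multiplicative extended Kalman filter:
   quaternion state, 3-dimensional attitude-error covariance, gyro
   integration in the prediction step, accelerometer-as-gravity-reference in
   the update. Yaw is unobservable without a magnetometer and is never used;
   pitch (anterior–posterior tilt, about the left–right axis) and roll
   (medial–lateral tilt, about the forward axis) are extracted by ZYX Euler
   decomposition. Repetitions are clipped to 30 s (3840 samples).

2. **Stabilograms.** Paired (ML, AP) = (roll, pitch) series are z-scored
   with statistics fitted on training-fold data only, then binned into a
   64×64 occupancy grid over ±3.2 sd per axis — the domain holding
   2Φ(3.2)−1 = 99.86 % of a standard-normal axis. Binning is half-open with
   0.1-sd cells; out-of-domain samples are clipped to edge cells so the
   grid always sums to the sample count. Grids enter the model as occupancy
   fractions (counts / n), removing any dependence on duration. Raw
   acceleration and angular-rate stabilograms are available as additional
   channel types; the default model uses orientation only.

3. **Regressor.** The stacked stabilogram channels feed one convolutional
   trunk: conv(3×3, same) → ReLU → maxpool(2×2), twice, then flatten,
   concatenation with eight scalar features (age, sex, height, weight, and
   the ordinal exercise encodings for surface, stance, eyes, head turns),
   two dense layers (default 32 and 8 units) each followed by dropout, one
   linear unit, and the smooth bounded transform y = 0.5 + 5·σ(z), which
   keeps every prediction strictly inside (0.5, 5.5). The network is
   implemented directly on numpy (im2col convolutions, explicit
   backpropagation, Adam at learning rate 0.001); initialization is
   deterministic given a seed, and the output bias starts the mean
   prediction at the scale midpoint 3.0.

4. **Protocol.** Ground truth per repetition is the mean of its PT rating
   panel. Records are weighted inversely to the frequency of their rounded
   label class, normalized to mean weight 1. Cross-validation is stratified
   5-fold at the participant level: participants ranked by mean label are
   dealt round-robin into test folds; the remainder splits ≈80/20 into
   train/validation at evenly spaced ranks (for 47 participants this yields
   test 9–10, train 30–31, validation 7–8). Training minimizes weighted MSE
   for a fixed epoch budget (default 200; the recovery studies use 30) and
   restores the snapshot with the lowest validation RMSE — essential
   because small training sets overfit quickly. Hyperparameters come from a
   full grid search over conv filters {8, 16, 32}, dense sizes {8, 16, 32}
   per layer (searched independently by default, 81 points; optionally tied,
   27) and dropout {0, 0.2, 0.5}, ranked by mean validation RMSE with ties
   broken toward fewer parameters.

5. **Benchmarks.** Model RMSE on pooled test repetitions is reported with a
   1000-replicate percentile bootstrap CI. Reference levels: a dummy
   regressor sampling the training-label marginal p(Y); self-rating RMSE
   against the PT consensus; and the random-PT benchmark — one uniformly
   chosen rating per repetition scored against the mean of the remaining
   ratings (repetitions with a single rating excluded), averaged over 1000
   replicates. Paired two-tailed t-tests (α = 0.05) compare per-repetition
   squared errors: model vs random-PT and self vs random-PT, where the
   random-PT squared error per repetition is its exact over-raters average.
   Rounding predictions half-away-from-zero (clamped to 1–5) yields
   accuracy, macro-F1 (classes absent from both GT and predictions are
   excluded from the macro average) and a 5×5 confusion matrix.

6. **Sensor selection.** A greedy beam-3 sequential forward search: all 13
   single-sensor models first, then each of the top three subsets per size
   is extended with every unused placement, de-duplicated as sets, and
   fully retrained/retuned. Ranking uses validation RMSE averaged over
   folds; ties break toward smaller across-fold variance, then
   lexicographic placement order. A surrogate mode replaces the CNN with a
   deterministic ridge regression on per-grid summary features (RMS radius,
   per-axis spreads, edge mass, entropy), preserving the combinatorial
   behaviour of the search so it can be validated against exhaustive
   enumeration in seconds.

## Synthetic cohort generator

The generator defines the study conditions and is itself tested code.

- **Participants.** Ages from a normal distribution (default 51 ± 18 y)
  truncated to [18, 90]; sex Bernoulli (default 30:17 F:M); sex-conditional
  height/weight; a latent steadiness ability ~ N(0, 0.75). The truncation
  slightly shifts the realized moments; tests check the empirical moments
  against the truncated distribution's exact values rather than the
  nominal parameters.
- **Exercises.** The 4×5×2×3 grid of surface, stance, eyes and head-turn
  categories is ranked by summed demand weight; each participant's
  schedule samples distinct conditions at evenly spaced demand quantiles
  (default 8 exercises × 3 repetitions = 24).
- **Latent intensity.** clamp(1 + Σ w·(encoding − 1) − ability, 1, 5) with
  per-step weights surface 0.5, stance 0.5, eyes 0.4, head turns 0.3 —
  monotone in every encoding, antitone in ability, config-exposed.
- **Sway.** True segment pitch/roll are sums of two band-limited Gaussian
  processes — drift (0.1–0.5 Hz, 70 % of variance) and tremor (0.5–2 Hz) —
  rescaled so the angle RMS grows linearly with intensity (0.3° at
  intensity 1, +0.55°/step, gain 1) and with a per-placement gain map in
  which thighs (1.6) and lumbar (1.5) respond most and feet (0.7) least,
  mirroring hip-strategy compensation. A statistical sway model was chosen
  over an inverted-pendulum ODE deliberately: only the statistical
  structure matters for validating the pipeline, and the spectra stay
  fully controllable. Gyro signals are the exact body angular rates of the
  orientation increments plus white noise; accelerometers read the
  segment-frame gravity vector plus white noise (no linear-acceleration
  term). Optional step-out transients inject a 1-s, 8° half-sine lurch
  above a configurable intensity threshold (off by default; the step-out
  flag is carried in the rating panel but never used as a model input).
- **Ratings.** Each PT rating is clamp(round(I + N(0, pt_sd)), 1, 5) with
  panel sizes uniform on {1..5}; the self-rating adds a default −0.5 bias
  before the same noise, emulating exercisers over-rating their own
  steadiness. The exact category distribution is available in closed form
  for oracle tests.
- **Determinism.** All randomness derives from one master seed through
  named substreams (cohort / schedule / sway / ratings), so identical
  (config, seed) reproduce a bit-identical dataset and individual stages
  can be regenerated independently.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: true musculoskeletal dynamics, linear
accelerations of moving segments, pathology-specific sway signatures,
rater idiosyncrasies beyond i.i.d. noise, or missing/irregular samples.
Recovery results on synthetic cohorts demonstrate that the pipeline is
correct and that the protocol can detect signal when it exists, not that a
given accuracy will transfer to clinical recordings.

## Numerical choices

- EKF noise defaults (gyro 0.005 rad/s, accel 0.05 m/s², initial attitude
  0.1 rad) are engineering values, config-exposed; the filter is run
  batched over recordings (one lock-step pass per chunk) for speed.
- Normalizer standard deviations are floored at 1e−8 with a logged warning
  so constant series cannot divide by zero.
- One rounding rule everywhere: half away from zero, clamped to [1, 5].
- Maxpool ties break to the first index; grid binning is bit-reproducible
  (half-open cells, final cell closed), so stabilogram indices and model
  outputs are deterministic across runs.
- Dropout is inverted and active only during training; two inference
  passes agree bit-for-bit.

## Problem sizes used in the shipped studies

The end-to-end intensity-recovery study runs 40 participants × 8 exercises
× 3 repetitions with rater noise pt_sd = 0.5 on a three-sensor stack
(lumbar + both thighs — a sufficient trio for this task), one
cross-validation fold per seed, 30 epochs, seeds {0, 1, 2}. The
sensor-selection studies run 16 participants × 4 exercises × 2 repetitions
over five placements with the surrogate evaluator, including a
planted-signal variant in which only the lumbar placement's sway carries
intensity information (all other gains zero). These sizes were chosen as
the smallest cohorts at which the effects of interest are unambiguous.

## Known limitations

- The smooth output transform is an affine logistic; any strictly
  increasing smooth map onto (0.5, 5.5) would satisfy the same contract.
- The CNN evaluator inside the full beam search over 13 placements is
  computationally heavy by construction (full retraining and retuning per
  candidate subset); the surrogate mode exists precisely to make the
  search logic testable, and the CNN path remains the default for real
  use.
- Paired t-tests use per-repetition squared errors pooled over test folds;
  with repetition counts in the hundreds the test is conservative about
  fold-level dependence.
- Yaw is never estimated; exercises whose signature is purely rotational
  about gravity would be invisible to the orientation channels.
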