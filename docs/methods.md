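# Methods

This note documents the models, the synthetic-physiology generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Problem setting

During general anesthesia, blood pressure is monitored either
invasively (arterial line: continuous, accurate, risky) or with a
brachial cuff (non-invasive, but one reading every 3–10 minutes).  The
package estimates mean arterial pressure (MAP) at 1 Hz in the interval
between cuff readings, from non-invasive signals only:

* 125 Hz photoplethysmogram (PPG) and ECG waveforms;
* 1 Hz pulse-derived features — heart rate (HR, bpm), perfusion index
  (PI, % pulsatile-to-baseline PPG amplitude), and the dicrotic-notch
  relative amplitude (NRA, in [0, 1]);
* the most recent cuff MAP value, used as calibration.

The unit of inference is the *segment*: all data between two
consecutive cuff readings, half-open `[cuff_i, cuff_{i+1})`, carrying
the opening cuff as calibration.  The natural clinical comparator is
the *carry-forward* baseline that holds the last cuff value until the
next reading.

## Mechanistic model

Treating the circulation as a resistive (Ohm–Poiseuille) circuit, MAP
is proportional to cardiac output times peripheral resistance, giving
the four-parameter form

    MAP = alpha * (ln(1 + 1/PI) + beta) * (NRA + beta') * HR + delta

with alpha a scale (mmHg/bpm), beta and beta' dimensionless offsets and
delta an intercept (mmHg).  `mechanistic_predict` evaluates this
pointwise (PI <= 0 masks the sample; masked inputs mask the output).

### Calibration

`fit_mechanistic` performs bounded nonlinear least squares of the
formula against the trailing five cuff readings (all available when
fewer, flagged `short_history`), with the deterministic initialization
alpha=1, beta=beta'=0, delta=mean cuff and the bounded search box
alpha ∈ [0.01, 10], beta, beta' ∈ [−5, 5], delta ∈ [−100, 200].
Feature values "at" a cuff are means over the preceding 5 s — long
enough to suppress beat-level jitter, short enough to stay consistent
with the instantaneous cuff reading.  Four parameters against at most
five quasi-collinear points are not jointly identifiable, so a weak
quadratic prior (weight 0.05, per-parameter scales 1/1/1/20) pins the
unidentified directions to the previous calibration, and the optimizer
is restarted from both the previous fit and the fixed default, keeping
the lower-cost solution (deterministic).  Degenerate histories
(constant features) fall back to an intercept-only fit.

### Tracking

`mechanistic_track` recalibrates at every cuff event and predicts
forward within the following segment.  Because weakly identified slope
estimates can extrapolate poorly, the tracker

1. accumulates slope information over the whole causal cuff history
   (the coupling parameters are patient constants), while the intercept
   receives a recency-weighted correction from the trailing five
   residuals (time constant 600 s, shrinkage 0.7) to follow slow
   calibration drift;
2. validates itself causally — each arriving cuff is predicted *before*
   refitting — and blends the fitted model with a lightly smoothed
   cuff-hold fallback (0.8 × last + 0.2 × previous cuff) in proportion
   to the validated evidence (conservative exponent 1.5, pseudo-count
   25 mmHg², trust ramp over the first 6 validated cuffs);
3. ramps the model's blend weight with time since calibration (the
   hold arm stales within a segment while the model error stays flat)
   and clips predictions to ±30 mmHg around the latest cuff.

All ingredients are causal: predictions in a segment depend only on
data at or before the prediction instant.

## Network estimator

The deep estimator is a causal multimodal network:

1. **Encoder.**  PPG and ECG pass through L dilated causal convolution
   layers (kernel 15, stride 1, ReLU, dropout 0.2 after each layer),
   dilation doubling per layer with left padding (k−1)·d, giving a
   receptive field of 1 + (k−1)(2^L − 1) samples (3 571 ≈ 28.6 s at
   L = 8).  The 125 Hz output is reduced to 1 Hz by causal average
   pooling over trailing 125-sample windows.
2. **Fusion.**  The 1 Hz embedding is concatenated on the channel axis
   with the z-normalized derived features (HR, PI, NRA).
3. **Cuff-initialized LSTM.**  The LSTM hidden state h0 is seeded with
   the opening cuff MAP, normalized as (cuff − 80)/20 and broadcast to
   every hidden unit of every layer; c0 = 0.  A new cuff reading resets
   the state — recalibration without touching the weights.  The forget
   gate bias is initialized at +5 so the seeded state can persist
   across a whole segment and its gradient does not vanish over
   hundreds of steps.
4. **Head.**  A per-timestep affine map to normalized MAP,
   denormalized to mmHg.  Loss is masked MSE at 1 Hz.

Normalization constants (fixed, recorded in `NetConfig`): MAP
(80, 20) mmHg; PPG (1.0, 0.05); ECG (0, 0.3); HR (75, 15) bpm;
PI (3, 2) %; NRA (0.5, 0.2).

Because no deep-learning framework is part of the package's
dependency set, the layers (dilated causal conv, LSTM, dropout,
pooling, Adam) are implemented directly in NumPy with hand-written
backprop; gradients are verified against central finite differences in
the test suite, and the convolution is evaluated as per-tap batched
BLAS products for speed.

### Training recipe

Adam (lr 2e-3, global-norm clip 5), per-epoch decay ×0.92 after epoch
8, batches of 8 length-bucketed segments, masked MSE, early stopping on
validation MAE.  The final weights are the average of the last four
epochs (tail averaging): the single best-validation epoch is a noisy
minimum of the validation curve, and the averaged weights generalize
measurably better.  All randomness (init, shuffling, dropout) is
seeded.  The *small profile*
used throughout the CPU-scale experiments is L = 4 conv layers,
4 conv channels, LSTM hidden 64; problem sizes for the packaged
experiments are 40 training patients, 6–10 validation and 10 test
patients, one-hour records, cuff interval 300 s — sizes chosen so the
full suite of experiments completes on a single CPU in minutes while
leaving the qualitative conclusions (network below carry-forward,
calibration ablation, interval sweep) stable across seeds.

## Synthetic-physiology generator

The generator is first-class, tested code; it defines the study
conditions for every experiment.

* **MAP trajectory.**  Ornstein–Uhlenbeck mean reversion around a
  patient baseline (reversion 1/300 s⁻¹, volatility 0.5 mmHg/√s,
  excursions soft-bounded at 1.8 stationary sds — sustained extremes
  are treated clinically), plus Poisson-arriving raised-cosine
  hypotension dips (2/hour, 10 mmHg nominal depth scaled by the
  patient's pressure reserve above 50 mmHg), a slow vasomotor
  (Mayer-wave-like) oscillation (period 30 s, amplitude 3 × volatility)
  guaranteeing a floor of within-segment variability, Gaussian
  smoothing (σ = 4 s; arterial MAP has no appreciable sample-to-sample
  roughness at 1 Hz), and clipping to [40, 160] mmHg.  The smoothing
  and volatility were set so that *clean* records satisfy the segment
  quality filter (notably the < 2 mmHg/s gradient rule and the
  > 1 mmHg sd rule) with wide margins, which the filter tests assume.
* **Patient heterogeneity.**  The resting baseline varies across
  patients (sd 10 mmHg, clipped to [66, 105]); the coupling parameters
  are jittered per patient (alpha log-sd 0.10; delta: independent sd
  6 mmHg plus 0.5 × the baseline offset, keeping the NRA inversion
  inside (0, 1)).  Without this heterogeneity the 1 Hz features would
  identify MAP across patients and cuff calibration would carry no
  information, making calibration ablations vacuous.
* **Features.**  HR and PI are smooth free processes (OU, Gaussian
  smoothed; HR around 75 bpm, PI log-normal around 3 %); NRA is solved
  pointwise from the mechanistic identity, so with zero feature noise
  the forward formula reproduces the reference MAP exactly (≤ 1e-9
  mmHg).  Observation noise of sd `feature_noise_sd` (mmHg equivalent)
  is split equally across the three features via their local
  sensitivities.  A slow OU "calibration drift" (stationary sd
  3 × feature_noise_sd, time constant 600 s) separates MAP from the
  feature-explained part; it decays the information content of a cuff
  reading with time, which is what makes estimation quality depend on
  the calibration interval.  Noise-free settings disable the drift.
* **Waveforms.**  Each beat places a two-lobe pulse template (systolic
  lobe, dicrotic notch at relative height NRA, small dicrotic lobe) on
  a DC baseline with the AC amplitude chosen so that
  100 × (peak − foot)/beat-mean equals the target PI; the beat period
  comes from HR.  The ECG is a nuisance channel: a unit R-spike per
  beat over low-amplitude noise.
* **Cuff readings.**  One event at t = 0 and every interval thereafter;
  value = concurrent arterial MAP + N(0, 3.1²) mmHg.
* **Determinism.**  Every component draws from an independent child
  stream of the record seed, so changing the cuff interval leaves the
  physiology bitwise unchanged — calibration-interval sweeps are
  exactly paired.

What the generator does **not** emulate: real pulse-wave morphology
(only the three encoded features are physiological), arrhythmia,
motion artifacts other than the four injectable kinds, device-specific
transfer functions, and any distributional fidelity to real cohorts
beyond first/second moments of MAP.  Passing tests therefore
demonstrate internal correctness and the stated qualitative behaviours
under this model family, not clinical performance.

## Segmentation and quality control

Records are cut at cuff events into half-open segments (gaps shorter
than 60 s are dropped — irregular schedules produce unusable slivers).
Nine criteria screen each segment, all computed on unmasked samples:
MAP mean in (50, 150) mmHg; MAP range < 40 mmHg ("dispersion" read as
range, consistent with extremum-based screening); max |ΔMAP| < 2 mmHg/s
at 1 Hz; MAP sd > 1 mmHg (strict); missing proportions < 20 % for MAP,
PI and HR and < 1 % for the PPG; and > 5 distinct unmasked PI values.
A segment is accepted iff all nine pass; rejections enumerate every
failed criterion.  MAP-based criteria need the arterial reference and
therefore apply at training time; pure inference skips them (flagged).

## Evaluation standards

Error = prediction − reference at 1 Hz on unmasked samples.  ME is the
mean signed error, MAE the mean absolute error; dispersion uses the
population sd (ddof = 0) — fixed convention, asserted in tests.
Study-level results pool errors within each patient first, then
average per-patient summaries (the "± value" reported after a study
metric is the across-patient sd; per-patient tables also carry the
within-patient sd of |error|).  AAMI: |ME| ≤ 5 mmHg, error sd ≤ 8 mmHg,
≥ 85 subjects (inclusive bounds).  BHS: grades A/B/C require cumulative
percentages of absolute errors ≤ 5/10/15 mmHg of at least (60, 85, 95),
(50, 75, 90), (40, 65, 85) respectively; the best grade whose three
thresholds are all met is awarded.  Latency is measured per batch over
≥ 15 batches (mean, sd, per-sample) and is reporting-only.

## Known limitations

* The network's parameter budget and cohort sizes are CPU-scale; the
  architecture is the contribution, not the absolute error level.
* The mechanistic tracker's blend weights are heuristic (validated
  evidence with fixed pseudo-counts), not a full Bayesian treatment.
* Pulse-arrival-time features are deliberately out of scope.
* BHS/AAMI verdicts on synthetic cohorts say nothing about real
  devices; they exercise the scoring machinery only.
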