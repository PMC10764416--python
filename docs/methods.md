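# Methods

`fogdetect` implements a complete window-level freezing-of-gait (FOG)
detection pipeline for multichannel accelerometry: a synthetic cohort
generator, the signal-conditioning and epoching chain, three classifier
families behind one probability interface, and subject-grouped evaluation
with geometric-mean threshold selection and a sensor-placement ablation.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic experiments do and do not establish.

## The detection problem

Input is 3-axis acceleration from up to seven body-worn IMUs (lumbar, both
upper legs, both lower legs, both feet) sampled at 60 or 100 Hz, with FOG
episodes annotated as half-open time intervals. The task is binary
classification of 2-s windows: does this window contain freezing? Detection
quality is summarized by the ROC AUC of the window probabilities and by
sensitivity/specificity/precision/F-score at a fixed operating threshold.

## Synthetic cohorts (`gaitsim`)

No public raw-data deposit backs window-level FOG detection at this scale,
so the pipeline ships with a seeded generator that reproduces the
*statistical structure* the analysis relies on:

- **Walking**: each channel carries a locomotor oscillation at the subject's
  step frequency f0 (uniform 1.2–2.3 Hz per subject) plus a 0.4-amplitude
  first harmonic. Left- and right-side sensors are anti-phase
  (phase offset ~ pi + N(0, 0.15)); leg/foot amplitudes (2.2–4.8 m/s^2)
  exceed the lumbar amplitude (1.0–1.8 m/s^2); the three axes of a sensor
  are scaled (1.0, 0.55, 0.35).
- **Trembling FOG**: locomotor content drops to 15 % and a freeze-band
  sinusoid (3.5–7.5 Hz, 1.8–3.2 m/s^2) is added on the leg channels (a 30 %
  echo on the lumbar sensor). This makes the 3–8 Hz / 0.5–3 Hz band-power
  ratio discriminative, which is the physiological signature the learned
  models are expected to pick up.
- **Akinetic FOG**: the signal collapses to 5 % of its walking amplitude.
  Each episode is akinetic with probability 0.15 (akinesia is the rarer
  phenotype), trembling otherwise.
- **Episode process**: a two-state alternating renewal process. Episode
  durations are log-normal with sigma_log = 0.5 (fixed; FOG durations are
  right-skewed) and arithmetic mean drawn per subject from U(4, 9) s —
  hundreds of episodes over tens of hours pool to a ~6.5 s mean, matching
  the regime of clinical FOG cohorts. Walking gaps are exponential with
  mean chosen so the expected FOG time fraction equals the per-subject
  target, drawn from U(0.06, 0.14) (~10 % of recorded time pooled).
- **Transitions** use 0.25 s raised-cosine crossfades so windows straddling
  an episode boundary contain genuinely mixed signal.
- **Artifacts**: isolated spikes at Poisson times with |a| in 110–150 m/s^2
  (and |omega| in 22–30 rad/s when a gyroscope stream is generated), i.e.
  guaranteed to trip the artifact thresholds below.
- **Noise**: additive Gaussian, per-subject sd in 0.2–0.4 m/s^2.

The entire cohort is a pure function of the `SimConfig` (all randomness
flows through seeds derived by hashing stage/subject/trial tags), so two
runs produce byte-identical files.

`SimConfig.lumbar_carries_fog=False` confines all FOG-related signal change
to the leg channels (the lumbar channel keeps walking statistics
throughout); this is used to verify that the sensor ablation orders
configurations by information content, not by channel count.

**What the generator does not emulate**: task structure (turns, doorways,
stops), gravity/orientation content, sensor drift, inter-rater label noise,
and the gray-zone onset/offset ambiguity of real annotations. Passing
learnability tests on this generator shows the pipeline can extract a
freeze-band signature under realistic epoching, imbalance and
subject-variability conditions — it says nothing about absolute performance
on clinical data.

## Signal conditioning (`preprocess`)

1. **Artifact masking** on the raw stream: a sample is flagged when any
   sensor's 3-axis acceleration norm exceeds 100 m/s^2 or (if present) the
   gyroscope norm exceeds 20 rad/s. The thresholds are stated as scalars
   without an axis convention; the norm is the default and a per-axis
   variant is a config flag. Flags are dilated by a +/-0.25 s guard to
   cover filter ringing. Masked samples never enter a window; masking (not
   splicing) keeps window timing aligned with the annotation clock.
2. **Band-pass**: zero-phase third-order Butterworth, 0.3–15 Hz, applied
   forward-backward (`sosfiltfilt`, odd-reflection padding). The band keeps
   both the locomotor (~0.5–3 Hz) and freeze (~3–8 Hz) spectra and removes
   drift; the forward-backward pass doubles the magnitude response and
   cancels phase, which the tests verify against the analytic |H(f)|^2.
3. **Rate standardization**: 100 Hz streams are polyphase-resampled by 3/5
   to 60 Hz (the 15 Hz filter edge already anti-aliases for the 30 Hz
   Nyquist); 60 Hz streams pass through. The artifact mask is mapped to the
   60 Hz clock by logical OR over contributing source samples.

## Windowing and labels (`windowing`)

Windows are 120 samples (2 s at 60 Hz) with 75 % overlap (0.5 s step), cut
per trial; a stream of L unmasked samples yields floor((L-120)/30)+1
windows. Windows touching any masked sample are dropped whole, so every
window is exactly 120 x C. The FOG fraction rho of a window comes from the
per-sample annotation mask (sample i is FOG iff its midpoint lies in an
interval). Labels: rho >= 0.25 is positive (boundary inclusive), rho = 0
negative, 0 < rho < 0.25 ambiguous and excluded from training. Ambiguous
windows are also excluded from evaluation by default — symmetric semantics —
with an option to score them as negatives instead. No amplitude
normalization is applied; the models see filtered physical units.

## Classifier families (`models`)

All three families expose `predict_proba(windows) -> p in [0,1]`, refuse
channel layouts they were not trained on, and are deterministic functions of
(data, config, seed). The CNN and InceptionTime are implemented on a compact
numpy layer library with explicit backpropagation (im2col convolutions,
max pooling, batch normalization, dropout, AdamW, class-weighted binary
cross-entropy on logits); training at the cohort sizes used here is a
minutes-scale CPU workload. Class weights are w_c = N / (2 N_c) for every
family.

- **CNN**: three blocks of conv(ReLU) -> maxpool(2) -> dropout(0.2) with
  kernel sizes (7, 3, 3), then flatten -> dropout -> dense(10, ReLU) ->
  dense(1, sigmoid). Same-padding maps 120 -> 15 time steps across the
  pooling stages. Filter counts are not pinned by the protocol; the default
  is (16, 16, 16), exposed in config, and the post-flatten dropout reuses
  the 0.2 rate. Training: AdamW (lr 1e-3, weight decay 1e-3), batch 32,
  exactly 30 epochs, no early stopping.
- **InceptionTime**: an ensemble of 5 networks, each 6 inception modules: a
  1x1 bottleneck (width 32) feeding parallel convolutions with kernel sizes
  (2, 4, 8) (reduced from the reference 10/20/40 — on 120-sample windows
  large kernels mostly add parameters), plus a stride-1 max-pool branch
  through a 1x1 conv; concatenate (128 channels), batch-norm, ReLU, and a
  residual shortcut (1x1 conv + BN) every third module; global average
  pooling into one logit. Ensemble probability is the arithmetic mean of
  member sigmoids. Training: Adam (lr 1e-3, no weight decay), 20 epochs,
  batch 64.
- **MiniRocket**: the 84 two-valued length-9 kernels (three +2 taps, six -1
  taps) at exponentially spaced dilations capped at 32 per kernel, PPV
  (proportion-of-positive-values) pooling against biases taken from
  quantiles of convolution outputs on a seeded training subsample, features
  allocated so the 10,000 budget rounds down to 84 x 119 = 9,996. The head
  is a logistic regression on standardized features, trained by Adam
  (lr 1e-3, 10 epochs, batch 256) with the same class weights. Multichannel
  handling: kernels are grouped 14-at-a-time and each (group, dilation)
  pair sums a random power-of-two-sized channel subset fixed by the seed —
  the grouping lets one matrix product evaluate a whole kernel group.
  Bias quantiles use a subsample of 2^11 windows (~250k convolution values
  per kernel-dilation pair), which estimates the quantiles stably at a
  fraction of the cost of larger subsamples; the size is config-exposed.
- **Spectral baseline**: the log band-power ratio (3–8 Hz)/(0.5–3 Hz)
  summed over channels, monotonically mapped to [0, 1]. It is the
  physiological floor any learned model should clear, and the guarantee
  that the synthetic task is learnable at all.

## Evaluation (`evaluate`)

Everything splits by *subject*, never by window:

- **80/20 hold-out split** stratified by FOG occurrence: subjects are
  binned by their FOG-time percentage (zero-FOG subjects form their own
  bin, the rest cut at quartiles) and ~20 % is drawn per bin with
  largest-remainder rounding.
- **Five-fold grouped CV**: a seeded partition of training subjects into
  near-equal validation groups.
- **ROC/AUC**: thresholds at every distinct score, trapezoidal AUC (equal
  to the normalized Mann-Whitney U statistic; tested to 1e-12). The mean
  ROC is vertical averaging on a 101-point FPR grid; the reported mean AUC
  is the arithmetic mean of per-fold AUCs (not the AUC of the mean curve)
  with the population SD across folds.
- **Threshold**: the maximizer of the geometric mean
  sqrt(sensitivity x specificity) over all ROC thresholds, ties toward the
  larger threshold, prediction rule p >= tau. The threshold is chosen on
  pooled out-of-fold CV predictions of the selected configuration and then
  frozen for both test sets.
- **Metrics**: sensitivity, specificity, precision, F-score from the
  confusion table; precision and F are reported as NaN when nothing is
  predicted positive.
- **Sensor ablation**: the five configurations (seven sensors; six
  legs+feet; lower legs; lumbar; right foot -> 21/18/6/3/3 channels) are
  compared with one shared fold assignment (paired). Configuration
  selection takes the highest mean AUC with exact ties broken toward fewer
  sensors.

## Orchestration (`pipeline`, `analysis/`)

`run_experiment` chains simulate -> condition -> window -> family CV ->
family selection (highest mean CV AUC) -> ablation -> configuration
selection -> threshold -> frozen evaluation on hold-out and unseen cohorts,
and emits a JSON report that is byte-identical across runs with the same
config. One global seed is fanned out per stage by hashing the stage name,
so any stage can be rerun in isolation. The numbered scripts under
`analysis/` run the same chain step by step and write tables under
`results/`.

## Problem sizes

The shipped defaults are desk-scale: 20 subjects x 6 min (2 h, ~14,000
windows) for training/hold-out and 5 subjects x 5 min unseen. These sizes
were chosen so every analysis completes in minutes on one CPU while keeping
enough windows (>10^4) and subjects (>15) for the grouped-CV machinery to
be meaningful. Clinical-scale AUC/sensitivity/specificity values from real
cohorts are not reproducible from synthetic data and are not claimed; the
tests assert learnability bounds, oracle equivalences, leakage guards and
determinism instead.

## Known limitations

- The synthetic task is *easier* than clinical FOG detection: near-ceiling
  AUCs here reflect the generator's clean band separation, not expected
  field performance.
- Orientation processing ("translation to the local frame" of the
  recording hardware) is out of scope; inputs are treated as sensor-local.
  A quaternion column set is reserved in the file format but unparsed.
- Episode-level (event-based) detection metrics and detection latency are
  not computed; evaluation is window-level throughout.
- The CNN/InceptionTime parameter totals depend on unpinned widths
  (conv filter counts, bottleneck width); the defaults here are documented
  but not claimed to match any published total. The MiniRocket feature
  count (9,996) is exact by construction.
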