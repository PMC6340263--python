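# Methods

This note documents the models, conventions, and numerical choices behind
`perisacc`, and what the synthetic-data tests do and do not establish about
real recordings.

## Time base and windows

Everything is aligned to fixation onset *t* = 0, defined as the saccade's
end under the velocity criterion (below). Time is integer milliseconds: the
1 kHz LFP sampling makes this exact and avoids float-time drift. A window is
(τ, L) with even L; its sample set is {τ − L/2, …, τ + L/2 − 1}, so
(0, 100) covers −50…+49 ms (the peri-saccadic interval), (25, 100) covers
−25…+74 ms, and (±250, 100) are the fixation intervals ∓300…∓201 /
+200…+299 ms. Odd lengths are rejected rather than given an arbitrary
convention. For shorter windows (50/20/10 ms) the training grid contains
every center whose window lies inside the overall −100…+98/99 ms analysis
range used by the 100 ms grid; this reproduces both the canonical 100 ms
grid {−50…49} and the fact that the earliest 10 ms window (τ = −95) also
starts at −100 ms.

## Saccade detection

Eye speed is the norm of the central-difference velocity of the
two-component position trace (one-sided at the endpoints). The threshold is
mean + 3·SD of speed over a fixation baseline; saccade onset is the first
suprathreshold sample and saccade end the first sample falling back below.
Two practical choices:

* **No pre-threshold smoothing by default.** A moving average widens the
  speed pulse and biases the detected end late (measured on the generator:
  +1.5 ms mean, 4 ms worst case with a 5-point box). The unsmoothed speed
  is unbiased (≤ 2 ms worst case) because fixational position noise, being
  a nonnegative speed floor, already lifts the 3·SD threshold above noise
  excursions near the crossing. `smooth_speed` remains available and
  `detect_events(smooth_width=...)` re-enables smoothing.
* **Peak anchoring.** Applied literally over a long window, "first sample
  above threshold" fires on fixational noise (any noise process crosses a
  3·SD-of-itself threshold somewhere in hundreds of samples). The detector
  therefore supports `anchor="peak"`: anchor at the global speed maximum
  and walk outward to the nearest crossings — the same criterion evaluated
  around the actual saccade. The event-detection stage uses this mode; the
  literal mode remains the default for short, pre-localized traces.

## Normalization

Per channel, all trials are pooled to one mean and one SD (population
convention, divide by *n*); epochs are z-scored with these statistics.
Pooling includes every trial — train and test — which mildly leaks test
statistics into training; this matches the original recipe and is kept for
fidelity. Callers wanting strict separation can fit `NormStats` on a
training subset and pass them explicitly. Channels whose pooled SD is at
rounding-error level relative to their mean are rejected as dead.

## Classification and scoring

The classifier is a soft-margin linear SVM on 100 unweighted per-millisecond
features (scikit-learn `SVC(kernel="linear")`). The regularization weight
defaults to C = 1 on z-scored features and is exposed everywhere; the exact
hyperplane at a given C is not a scientific claim, the s-value protocol is.
S-values are signed perpendicular distances (**w**·**x** + b)/‖**w**‖,
positive on the saccade side, computed under leave-one-out: trial k is
scored against the hyperplane trained without trial k (both classes drop
the held-out trial).

ROC curves sweep thresholds at midpoints between consecutive distinct
scores plus sentinels beyond both extremes, so no score ever equals a
threshold and trapezoid integration equals exact pair counting with ties
worth ½ — the probabilistic definition AUC = P(s⁺ > s⁻). Percent correct is
reported both at the margin criterion (threshold 0) and at the
accuracy-maximizing threshold under equal error costs.

Channel pooling sums each trial's s-values across channels before the ROC
(one score per trial); a concatenated-histogram variant
(`pool_channels_concat`) exists for comparison but does not yield a
trial-level score. "Optimal combination" ranks channels by single-channel
AUC and takes the prefix with the highest pooled AUC; "channel average"
means the mean of single-channel AUCs.

## Timing sweep

For τ_train on the {−50…49} grid, test centers are
{τ_train − 100, …, τ_train + 99}: symmetric about τ_train and covering the
whole grid, so that under pure noise the expected vote is τ_train (no edge
bias; verified by simulation against the uniform-vote null, whose analytic
RMS over these offsets is 57.7 ms). Votes are the argmax of the s-curve;
ties break toward the center nearest τ_train, then earlier — a rule that
adds no directional bias in expectation. Trials whose span cannot cover the
full test range are skipped, not clipped; clipping would reintroduce the
edge bias the symmetric range removes.

## Direction analyses

One-vs-rest classifiers use the τ = 25 window (the epoch that generally
yields the highest saccade/fixation AUCs). The 12-way decoder trains all 66
pairwise SVMs per fold of a seeded 30-fold stratified cross-validation and
predicts by pairwise-contest wins; ties break by the larger sum of
winning-margin s-values. Direction votes are averaged with the circular
mean (summed unit vectors) — arithmetic averaging is ill-defined across the
0°/360° wrap — and errors are wrapped to (−180°, +180°]; the summary
statistics (average, RMS, SD, min, max) are taken over the absolute
per-direction errors.

The shape permutation test pools two directions' epochs and reassigns them
to labels preserving the original group sizes (keeping the null
exchangeable with the observed statistic even for unequal groups); the
statistic is the mean of the two within-group average pairwise Pearson
correlations, and the p-value is one-sided upper-tail with add-one
smoothing, p = (1 + #{null ≥ observed})/(n_perm + 1). Bonferroni correction
is applied per channel over its direction pairs (66 for 12 directions).
Note the discreteness constraint: the smallest achievable p is
1/(n_perm + 1), so clearing the Bonferroni threshold α/66 requires
n_perm > 66/α − 1 (≥ 1320 at α = 0.05; the default is 10 000).

Bootstrap confidence bands for mean LFPs are percentile bootstrap over
trials (default 2000 replicates), clipped to bracket the sample mean.

## Synthetic sessions

The generator emulates the study conditions: 12 saccade directions in 30°
steps, 7° outside-in saccades ending at *t* = 0, trials spanning −400…+399
ms, 1 kHz LFP and eye traces (a 2 kHz eye option is config-selectable).

* **Eye kinematics.** The speed profile is a raised cosine whose closed-form
  displacement makes the amplitude exact. Amplitude (7°) and duration
  (30 ms) are honoured exactly; the peak speed is then 2A/D ≈ 467 deg/s.
  (No unimodal pulse can have 7°, 30 ms *and* a 300–350 deg/s peak
  simultaneously; amplitude and duration are the quantities the analysis
  depends on.) Fixational noise is smoothed white position noise of SD
  0.01°.
* **Templates.** Three Gaussian lobes (dip/peak/dip at 5/35/65 ms, signed
  amplitudes −0.6/+1.0/−0.5) windowed to zero outside −30…+100 ms with
  10 ms cosine ramps. Direction tuning multiplies each lobe by a von Mises
  bump (κ = 2, floor 0.2) of the angle to the channel's preferred
  direction, with per-lobe direction offsets and a ±6 ms direction-dependent
  latency shift, so waveform *shape* — not only gain — varies smoothly with
  direction: neighboring directions correlate more than opposite ones.
  Channel preferred directions tile the circle with jitter. Templates are
  scaled so the direction-averaged RMS over the support is 1.
* **Noise and SNR.** Background is spectrally shaped Gaussian 1/f^α noise
  (α = 1 default), unit SD per channel, independent across trials and
  channels. `snr` multiplies the unit-RMS template (snr = 0 is the null
  mode: pure noise with intact metadata); per-channel lognormal gains
  (σ = 0.3) emulate electrode-to-electrode variability.
* **Latency jitter.** True fixation onset jitters trial-to-trial by a
  truncated Gaussian (SD 3 ms, clipped at ±10 ms) rounded to the 1 ms grid;
  the downstream analyses align to each trial's own event time, so jitter
  stresses detection, not the decoder.
* **Defaults as study conditions.** 42 trials per direction (the low end of
  the recorded per-direction counts) and 16 channels (the smallest array);
  default snr = 1, a regime where saccade/fixation AUCs land around 0.9.
  Recovery tests use snr = 5 and 12 × 40 × 8 sessions as the stated
  high-SNR condition.

**What the generator does not model:** biophysical LFP genesis, spiking,
microsaccades, blinks, corrective saccades (the analysis discards such
trials; the generator simply never produces them), cross-channel noise
correlations, or non-stationarities across a session. Tests passing on
these sessions establish that the *pipeline* is correct and calibrated —
recovering known signals and reporting chance on null data — not that real
V1 LFPs carry any particular information level.

## Problem sizes and seeds

Simulation-based tests and the acceptance script use sessions between
12 × 2 × 20 (null calibration, 100 replicate channels) and 12 × 40 × 8
(high-SNR recovery); these sizes give Monte-Carlo error comfortably inside
every asserted tolerance while keeping the whole suite fast. All randomness
flows through named integer seeds (`numpy.random.SeedSequence`); the
pipeline spawns per-stage sub-seeds from one master seed and records them
in its manifest.

## Known limitations

* Leave-one-out retrains an SVM per trial; at hundreds of trials per class
  this is the dominant cost. A k-fold option exists for the 12-way decoder
  (as in the original protocol) but not for the binary analyses.
* The 300 Hz low-pass with 1 kHz output keeps the original recipe; energy
  between 300 and 500 Hz is attenuated only by the filter roll-off, so mild
  aliasing of that band is possible.
* The pooled (train + test) normalization is a deliberate fidelity choice;
  see above for the strict alternative.
* Direction estimates use hard 12-way votes; a continuous direction
  regression is out of scope.
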