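# Methods

This note documents the models, statistical procedures and design choices
behind `fusi`, and what the synthetic benchmarks do and do not establish.

## Signal model

A functional-ultrasound acquisition produces, every second, one block of
300 complex compound frames at a 500 Hz slow-time rate. Per voxel the
slow-time signal is modelled as

```
s(t) = tissue(t) + blood(t) + n(t)
```

* **Tissue clutter** is strong and spatially coherent. The generator makes
  it exactly rank one — a single smooth spatial profile times one complex
  oscillation below 5 Hz (default 2 Hz) — so the behaviour of the SVD
  clutter filter on it is analytically known: removing one singular
  component annihilates it exactly in the noise-free case. Real clutter is
  only approximately low-rank (breathing, pulsatility, probe motion add
  further components); passing the rank-1 tests therefore validates the
  filter's algebra, not its rank selection on real data.
* **Blood** contributes `sqrt(blood_fraction) · exp(i(2π f_D t + φ))` with
  Doppler frequency `f_D = 2 v f₀ / c` for axial velocity `v`, transmit
  frequency `f₀ = 15 MHz` and speed of sound `c = 1540 m/s` (the standard
  soft-tissue value; the conversion constant is configurable). Power
  Doppler — the mean of `|s|²` over the block — is then proportional to
  the blood fraction, which is what makes it a blood-volume proxy.
* **Noise** is unit-variance complex white noise. No speckle, point-spread
  or physiological noise beyond these terms is simulated.

### Clutter filtering

The block is reshaped to its Casorati matrix (voxels × time) and the `k`
largest singular components are zeroed. `k` is a fixed configuration value
(default 1) rather than an adaptive energy threshold, which keeps tests
deterministic; an energy-fraction mode (remove leading components until a
cumulative energy quantile is reached) is available where adaptivity is
wanted.

### Velocity-band selection

The axial-velocity band is selected with a 5th-order low-pass Butterworth
at `f_c = 2 v_max f₀ / c`, applied forward and backward (zero phase) on the
complex slow-time signal so the band selection does not shift the power
estimate in time. Two consequences are worth noting. First, the filter is
symmetric in Doppler frequency: the sign of the axial velocity (flow toward
vs away from the probe) is not resolved. Second, the filter is a
bilinear-design digital Butterworth, whose stopband attenuation near
Nyquist is substantially deeper than the analog prototype formula
`|H(f)|² = 1/(1 + (f/f_c)^{2n})` because of frequency warping; the tests
check the measured attenuation against the warped closed form
`1/(1 + (tan(πf/f_s)/tan(πf_c/f_s))^{2n})`, which is the correct analytic
magnitude for the implemented filter.

### %CBV

`100·(PD(t) − B)/B` with `B` the mean power over a baseline window. The
default baseline is the pre-stimulus silence of each trial rather than a
session-global window, because baseline power drifts over tens of minutes.
Voxels with non-positive baseline are flagged invalid and set to NaN rather
than propagating meaningless ratios.

## Trial structure and responses

The tone protocol is 10 s of silence, 3 s of sound, 8 s of silence, with a
uniform inter-trial jitter of 1–3 s; five pure tones log-spaced from 602 Hz
to 19234 Hz, 10 trials each, in random order. Jittered gaps are rounded to
the 1 Hz grid, emulating acquisition synchronized to trial starts; this
keeps noise-free forward models exactly invertible on the sampling grid.

Window conventions are inclusive on the 1 Hz grid: "3 to 5 s" means the
samples at 3, 4 and 5 s after onset. Epoching subtracts each trial's own
pre-onset mean.

The hemodynamic impulse response is a gamma kernel `t^{a−1} e^{−t/b}` at
1 Hz with unit peak, peaking at 2 s (shape 3) and below 5 % of peak by 8 s.
The experimental literature for this preparation does not constrain the
shape tightly; the default was chosen once so that the 3–5 s response
window straddles the peak of the response to a 3 s stimulus. Response
amplitudes default to ~20 %CBV at the best frequency, the order of
magnitude reported for awake-mammal auditory cortex; the trial-to-trial
noise sd is a generator parameter with no published reference value and is
always stated explicitly in configurations (4 %CBV in the worked example).

Tuning statistics per voxel: one-way ANOVA across the five frequencies,
with pairwise Wilcoxon rank-sum post-hoc tests computed only where the
ANOVA reaches p < 1e-3. The tuning-curve s.e.m. is computed across trials
(not across time). The z-score used to pool "responsive" voxels for the
mean hemodynamic response is the across-trial mean over s.e.m. of the
windowed response, thresholded at 3.

The FIR GLM puts one indicator column per (frequency, lag) pair — lags 0–8 s
by default, the return-to-baseline duration — plus an intercept, and solves
least squares per voxel. Jittered inter-stimulus intervals make the design
well conditioned; a condition-number guard (default 1e8) raises on
rank-deficient designs instead of returning unstable estimates. No
autoregressive modelling of residuals is attempted.

Stimulation-evoked ROI responses use the 3–6 s window and a two-sided
Wilcoxon signed-rank test of per-trial ROI means against zero — chosen for
consistency with the nonparametric tests used elsewhere in the pipeline —
with significance tiers at 5e-2, 1e-2, 1e-3.

## Tonotopic map post-processing

Display masking keeps voxels with a ≥15 %CBV maximal response whose BF time
course correlates with the mean hemodynamic response (Pearson, over the
0–8 s peristimulus window) at p < 1e-3. BF smoothing treats the BF index as
ordinal on the log-frequency grid and renormalizes the 3×3×1 Gaussian
(σ = 0.5 voxel) over the mask so masked-out neighbours do not bleed in;
interpolated non-integer BF values are kept for display. Surface normals
are approximated by the depth axis, adequate for the flat synthetic
geometry; full normal estimation on curved cortex is out of scope. Slice
re-matching z-scores intensities and takes the argmax Pearson correlation
over the stack, returning the lowest index with an explicit flag on ties.

The layered-cortex generator assigns `floor(10 · relative depth)` between
two delineation polylines, with relative depth measured vertically; for
parallel delineations this equals the perpendicular fraction exactly.

## Decoding

The 5-class decoder is one-vs-one with a linear boundary per class pair
and majority voting (ties broken uniformly at random, seeded). The
boundary is the mean-difference (nearest-centroid) hyperplane through the
midpoint of the class means — the simplest rule consistent with a linear
pairwise classifier, with the Fisher decoder as its covariance-normalized
upgrade.

Cross-validation folds hold out one trial per class, so each pairwise
boundary trains on equal trial counts from its two classes (9 of 10 in the
standard protocol). This matters: if only a single trial is held out, the
held-out trial's class mean is estimated from one fewer trial than its
opponent's, and the resulting norm imbalance biases null-label accuracy
measurably below chance (≈0.156 instead of 0.200 at 10 trials per class
and 200 voxels). With balanced folds the null-label accuracy is exactly
1/K in expectation (verified to ±0.0003 by simulation).

The Fisher decoder regularizes the pooled within-class covariance as
`(1−λ)Σ̂ + λ·diag(Σ̂)` with default λ = 0.1: at 10 trials per class the
unregularized covariance is singular whenever voxels outnumber trials, so
shrinkage is mandatory and disclosed. λ = 1 reduces to a
diagonal-covariance decoder; λ = 0 requires an invertible covariance and
raises otherwise.

Permutation testing shuffles labels across trials, re-runs the decoder
(default 100 permutations), declares significance above the 95th
percentile of the null accuracies, and reports a p-value floored at
1/n_permutations. Pseudo-populations draw, per class and per shuffle, one
trial per slice without replacement and concatenate voxel vectors; slices
with unequal trial counts are truncated to the minimum with a warning.
Depth-resolved decoding equalizes voxel counts across depths by seeded
subsampling and compares depth profiles across subjects with a classical
one-way repeated-measures ANOVA (subject × depth decomposition, no
sphericity correction — profiles have few levels and the statistic is used
descriptively).

## Functional resolution

For each unordered voxel pair inside the analysis contour, a balanced
two-way fixed-effects ANOVA (2 voxels × 5 frequencies × n trials) is
computed from the windowed responses. The voxel main effect captures
overall-responsiveness differences; the voxel × frequency interaction
captures tuning-shape differences; a pair is "dissimilar" when the
corresponding p-value is below 0.05. Fractions of dissimilar pairs are
binned by the half-up-rounded Euclidean inter-voxel distance in voxel-pitch
units. The randomization null permutes all scalar response values jointly
over voxels, frequencies and trials (50 randomizations) and the observed
curve is compared per distance against the null's 95th percentile; the
resolution is the shortest exceeding distance times the 100 µm pitch.

Two small conventions: the distance formula is the evident Euclidean
intent (a literal variant that repeats the first coordinate difference is
available behind a flag for exact-reproduction studies), and rounding is
half-up. Contours are explicit input masks; no automatic transition
detection is attempted.

Because per-pair power grows quickly with effect size, the measured
resolution is a property of the generator's conditions as much as of the
statistic: with a 6 %CBV amplitude step between adjacent columns at 2 %CBV
trial noise, responsiveness resolves at one voxel pitch (100 µm); with a
1/3-frequency-step tuning drift per column at 4 %CBV noise, the
interaction test already has ~0.7 power for adjacent columns, so tuning
also resolves at one pitch under those conditions. Real cortical maps,
with smoother gradients and correlated noise, resolve more coarsely.

## Problem sizes and numerics

The test suite and the benchmark script run entirely on synthetic data at
deliberately modest sizes — frame blocks up to 20×20×300, trial series of a
few hundred samples, patches of ≤48 voxels, 25-seed resolution ensembles,
10⁴ decoder runs for the chance-level estimate — chosen so the full chain
re-runs in well under half an hour on one CPU while keeping Monte-Carlo
standard errors small relative to the tolerances tested. Numerical
tie-breaks are explicit everywhere randomness could hide: all generators
and decoders take integer seeds, majority-vote ties are broken by a seeded
uniform draw, and plane-matching ties return the lowest index with a flag.

## Known limitations

* No beamforming, plane-wave compounding, speckle or point-spread
  modelling; the generator starts at beamformed complex blocks.
* The rank-1 tissue model makes the clutter filter's task easier than on
  real data; respiratory and pulsatile artifacts are not simulated.
* Gaussian i.i.d. trial noise ignores the spatial and temporal noise
  correlations of real hemodynamics (the Fisher decoder's advantage is
  demonstrated on constructed correlated noise, not on the generator's
  default output).
* Surface projection assumes vertical normals; curved-cortex geometry is
  accepted only through explicit masks and delineations.
* The repeated-measures ANOVA omits sphericity correction.
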