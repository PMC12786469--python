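# Methods

This note records the models, parameter choices and numerical decisions
behind `eegsonify`, and what the synthetic-data experiments do and do not
demonstrate.

## Spectral features

Windows are 2 s with a 1-s step; a trailing partial window is dropped so
every window has identical statistics. Within a window the PSD is estimated
by Welch's method with 1-s Hann segments at 50% overlap (three averaged
segments per window). The 1-s segment gives 1-Hz resolution — the coarsest
grid that still resolves the 1-Hz lower edge of the delta band — while
averaging three segments reduces estimator variance. Band edges are
half-open `[lo, hi)` with the gamma band closed at 45 Hz, so the five bands
tile 1–45 Hz without double counting at the shared edges.

Normalized spectral entropy uses the natural logarithm over the K bins in
1–45 Hz, divided by ln K, giving H = 0 for a single spectral line and H = 1
for a flat spectrum. The relative band power itself (already in [0, 1]) is
the quantity fed to the synthesis mapping; no further per-recording
rescaling is applied.

Regional aggregation averages member-channel *PSDs* (midline channels at
weight 0.5 per hemisphere) and computes band powers and entropy from the
mean spectrum. Averaging channel-level entropies instead would estimate a
different quantity (the mean of entropies, not the entropy of the regional
spectrum); the mean-spectrum convention is the defensible regional analog
and keeps P and H mutually consistent. The default montage assigns
T5/T6 to the temporal regions by name; the 19-channel clinical montage has
no Oz, so the occipital regions hold O1/O2 only. Both choices are
configurable through the montage mapping.

## Synthesis chain

All mapping constants (oscillator ranges, tremolo ranges, the 0.85 gain
exponent, Q/fade/depth laws, filter cutoffs, 4-bit depth, 80-ms ramps,
−6/−24 dB focus gains) are the method’s reference values and live in
`MappingConstants`. Decisions the mapping leaves open were resolved as
follows:

* **Ramps.** Parameter transitions use a first-order exponential approach
  with time constant 80 ms / ln 100, so a track is within 1% of its target
  at 80 ms — a testable realization of exponential parameter automation.
  Each ramp starts from the current value; tracks are continuous.
* **Tremolo.** Sinusoidal LFO with gain in [1 − d, 1]; the modulation
  never boosts above unity.
* **Crossfade.** Equal-power (cos/sin) law, the standard constant-loudness
  choice.
* **Bit crusher.** Uniform mid-tread quantization to 2^bits levels,
  applied relative to the regional bus's own peak (a digital bit-depth
  reduction is defined against the representation's full scale). Fixing
  the quantizer to an absolute ±1 range instead makes the distortion power
  explode for quiet mixes and the rendered spectra are then dominated by
  quantization noise around the regional resonance — a regime incompatible
  with the reference acoustic profile of these sonifications.
* **Regional filter.** Realized as an RBJ peaking-EQ bell at 1 kHz whose
  boost equals Q (in dB) and whose width narrows as 1/Q: low entropy yields
  a prominent, selective resonance; high entropy leaves the spectrum nearly
  untouched. A 0-dB-peak band-pass realization was rejected on physical
  grounds: it attenuates the 45–95 Hz delta oscillator by ≈30 dB, which is
  irreconcilable with reference sonifications that carry roughly a third
  of their energy below 100 Hz. Coefficients are piecewise-constant,
  refreshed at window boundaries and at quarter-points of the ramp, with
  filter state carried across blocks.
* **Detune.** The alpha micro-detune is redrawn once per window, uniform
  in ±(6 + 14·H) cents, from a seeded stream, and ramped like every other
  parameter.
* **Mix levels.** Tonal sources enter at sine-RMS level; the two noise
  sources enter 6 dB higher. Equal-RMS noise is perceptually much quieter
  than a tone, and the reference energy balance (a large high-frequency
  noise share) implies a noise-forward calibration.
* **Numerics.** The amplitude path renders in float32 (24-bit mantissa,
  far beyond 16-bit WAV); oscillator phase accumulates in float64 and is
  wrapped to [0, 1) before waveform evaluation, keeping frequency accuracy
  over arbitrarily long renders. Renders are bit-deterministic given a
  seed; per-region substreams derive from the subject seed so regions are
  independently reproducible.

The master mix peak-normalizes to −1 dBFS only if it would clip, preserving
relative dynamics otherwise.

## Acoustic descriptors

STFT and RMS-envelope frames are 4096 samples with a 1024 hop at 48 kHz
(≈85 ms / 21 ms) — the standard 2048/512 music-analysis configuration at its
usual 22.05 kHz rate, carried to the rendering rate — which puts the
envelope near the integration time of perceived loudness. The centroid is
magnitude-weighted and frame-averaged; band energies and entropy come from
the averaged power spectrum; the harmonicity ratio floors its denominator
at 10⁻¹² of total energy. Every descriptor is invariant to positive
rescaling of the waveform (property-tested). The 45–95 Hz and <100 Hz
ranges overlap by construction and are both reported.

Group comparisons use Welch's unequal-variance t-test (robust to the
unequal group spreads typical here), Benjamini–Hochberg FDR across the
descriptor family, and pooled-SD Cohen's d. Zero-variance descriptors are
flagged NaN and excluded from the FDR family rather than silently dropped.

## Listener-panel statistics

The chance level is the probability-matching accuracy p² + (1 − p)²,
a stricter baseline than 50%. The exact binomial test is two-tailed by the
minimum-likelihood convention (all outcomes no more probable than the
observed one), which matches an exhaustive enumeration oracle for n ≤ 20 in
the tests. Holm's step-down correction controls the family-wise error over
evaluators. The permutation test permutes diagnostic labels with the rating
structure fixed and reports the conservative (1 + B)/(1 + N) estimator
(the naive B/N is returned alongside); N defaults to 10 000. Fleiss' κ is
computed on the complete-item submatrix (listwise exclusion of subjects
with any missing rating, mirroring the different Ns of accuracy and
agreement analyses); its 95% CI comes from a percentile bootstrap over
items (1000 draws). Missing ratings reduce an evaluator's own denominator
for accuracy metrics; n is always taken from the supplied matrix.

The power simulation draws evaluator accuracies from a normal distribution
truncated to [0, 1], samples Bernoulli-correct ratings per evaluator, and
applies the permutation test at level α; power is the rejection fraction.
This model is deliberately simple — the distributional form of "accuracy
under the alternative" is the least constrained part of the design — so its
output should be read as a coarse design check, not a calibrated power
figure.

## Synthetic EEG generator

Each channel is a sum of five band-limited noise components (4th-order
Butterworth band-pass on white noise, forward-backward filtered). Component
pass-bands are aligned to the 1-Hz analysis bins (half-bin shift of the
nominal band edges) and component variances solve a measured 5×5 leakage
system — the band allocation of each component under the exact Welch
analysis — so extracted mean relative powers match the profile weights to
within a few 10⁻³ (the contract is ±0.03 at 60 s). Naive variance scaling
is biased by spectral leakage (delta loses ≈15% of its nominal share to
neighboring bins), which the solve removes.

Realism features, all seeded and deterministic:

* **Topography.** A fixed anterior/posterior template (frontal
  delta/theta dominance, posterior alpha dominance, central beta) plus a
  mild left/right asymmetry modulates each channel's relative-power
  targets. The template is centered under the channels' region-exposure
  weights so the mean of the ten regional profiles equals the subject's
  global profile.
* **Rhythm concentration.** A profile can concentrate a band's power into
  a one-bin-wide rhythm at the band center. The default control profile
  concentrates 90% of alpha power at 10 Hz — the sharp posterior dominant
  rhythm of healthy eyes-closed EEG — while the AD-like profile spreads
  every band flat (spectral disorganization).
* **Waxing and waning.** Concentrated rhythms are amplitude-modulated by a
  slow (0.05–0.4 Hz) positive envelope shared across the whole scalp, as
  the posterior rhythm's global waxing is; modulation depth is fixed, only
  its temporal pattern varies with the seed.

Group profiles are directional stand-ins (AD δ/θ/α/β/γ =
.30/.30/.15/.15/.10; control .20/.15/.30/.22/.13), not estimates of any
real cohort. Hierarchical seeding (subject → channel → band substreams)
keeps every subject's data invariant under cohort growth.

**What the generator does not model.** Stationary Gaussian noise has no
burst dynamics, artifacts, 1/f background beyond the band weights, or
state transitions. One documented consequence: with band-flat AD spectra,
the bin-level spectral entropy of the AD-like group comes out slightly
*below* the control group (band-weight concentration into few slow bins
outweighs the controls' alpha peak after window smearing), so the
entropy-elevation biomarker of AD is not reproduced at the feature level.
A second consequence concerns the temporal coefficient of variation of
rendered mixes: the envelope variability of a ten-region mix is dominated
by slow amplitude beating between same-band oscillators of different
regions (regional feature differences map to frequency offsets of a few
Hz), and that beating necessarily grows with the slow-tonal share — i.e.,
with the AD-like profile. Under these synthetic conditions the AD group
therefore shows slightly *higher* envelope CV, whereas the reference
finding on real recordings is the opposite; reproducing it appears to
require nonstationary structure of real EEG beyond this generator's scope.
All other group-level acoustic contrasts (the five band-energy fractions,
the spectral centroid, the harmonicity ratio) reproduce in direction with
very large effect sizes on the default cohort.

Passing tests on synthetic cohorts demonstrate the internal consistency of
the pipeline — calibrated feature recovery, correct mapping and rendering,
valid statistics — not clinical performance on real EEG.

## Problem sizes used in validation

The end-to-end cohort check uses 36 AD-like and 29 control-like subjects at
60 s each (the study's group sizes at a recording length that keeps
feature-estimate noise well below the group contrast). Statistical
calibration checks use 200 permutation-test replicates at 300 permutations
and a 200-simulation power run; oracle checks enumerate exhaustively where
feasible (binomial n ≤ 20).
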