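# Methods

`respreset` implements an analysis of anticipatory phase resetting in
respiration-locked intracranial EEG: does expecting an odor re-align the
phase of low-frequency (delta, ~0.5–2 Hz) oscillations in olfactory cortex
before the inhale that would carry the odor, and does that re-alignment
matter for perception? Because the corresponding human recordings are not
redistributable, the package pairs the analysis code with a synthetic
generator that reproduces the statistical structure the analysis assumes,
so every stage is testable end to end.

## The measurement model

All phase quantities derive from a filter-bank Hilbert decomposition.
The voltage trace is z-scored, band-pass filtered at log-spaced center
frequencies (defaults 0.5–200 Hz, 50 bands, bandwidth growing
logarithmically from 1 to 2 Hz) with a two-pass zero-phase windowed-sinc
FIR, and Hilbert-transformed to instantaneous phase φ(t, f) and amplitude
A(t, f). Epochs are cut in a half-open window around each inhale onset
(default −1 s to +3 s for standalone use; the cohort pipeline uses −1 s to
+2 s), onset sample at t = 0.

Phase consistency across n trials at a time-frequency bin is the
inter-trial phase coherence (equivalently the phase-locking value),

    ITPC = | (1/n) Σ_j exp(i φ_j) | ∈ [0, 1],

tested per bin with the Rayleigh statistic z = n·R² and the standard
finite-n approximation of its p-value, with Benjamini–Hochberg FDR applied
jointly across all bins of a map (Benjamini–Yekutieli available). The
single-trial counterpart is the deviation from the mean phase (DMP): the
unsigned circular distance between a trial's onset phase and the circular
mean phase over trials, at the frequency of maximal onset ITPC within
0.5–2 Hz; DMP ∈ [0, π], small = well aligned.

Where a measured ITPC is compared against a population value (the
concentration-recovery analyses), the small-sample bias-corrected
estimator sqrt(max(0, (nR² − 1)/(n − 1))) is used, since the raw R has a
finite-n floor E[R] ≈ sqrt(π/4n) under uniformity.

Power analyses square the (10 ms moving-average smoothed) amplitude,
average over trials, and convert to decibels (10·log₁₀); pre-inhale
analyses use raw power (no baseline), post-inhale analyses subtract the
per-frequency baseline over the second before onset. PSDs use Welch's
method (Hann, 4 s segments or the full segment if shorter, 50% overlap,
zero-padded to a 0.05 Hz grid).

### Inference

* Combined (trial-pooled) ITPC maps use the Rayleigh test + FDR; the
  nonanticipatory pool is randomly subsampled to the anticipatory count.
* Per-subject windowed ITPC maxima (0.5–2 Hz; −1–0 s and its two halves)
  feed paired t tests and a 2×2 repeated-measures ANOVA
  (anticipatory-state × time-window), computed by within-subject contrasts
  (for two-level factors F = t², df = (1, n−1)).
* Pre-inhale power maps are compared with bin-wise paired t tests across
  subjects + FDR; post-inhale power differences use a condition-label
  shuffle null, and per-condition event-locked power uses a
  surrogate-event null (one independent uniform circular shift per event,
  minimum shift one epoch length), both z-scored against the permutation
  moments and FDR-corrected.
* The DMP↔accuracy link uses two bootstraps (1,000 repetitions): group by
  accuracy and difference mean DMP (incorrect − correct); and group by DMP
  extremes (smallest vs largest 20% after resampling) and difference
  percent-correct. Each reports a percentage-based p (the fraction of
  repetitions failing the hypothesized direction, exact zeros counting
  against it; a zero count is reported as "< 1/n_boot"), a
  normal-approximation p from the distribution's mean/SD, and an exact
  binomial sign test. Resample size equals the group size (configurable).
* Motor analyses use the normalized airflow trace: inhale onset = upward
  zero-crossing preceded by ≥0.2 s of sub-zero signal and followed by an
  excursion ≥0.2 normalized units; duration = time to first downward
  zero-crossing; peak = maximum over the inhale. Median-split comparisons
  of inhale peaks by DMP drop the median trial for odd counts and skip
  subjects with fewer than 4 trials.

## The synthetic generator

One "subject" is a continuous recording with four coupled components:

* **Respiration** — half-sine inhales with condition-dependent peak and
  duration (defaults: anticipatory 1.3 a.u. / 1.2 s, nonanticipatory
  1.0 a.u. / 1.0 s, ±8% jitter) followed by exponentially decaying exhales
  scaled so each breath integrates to zero (keeping zero-crossings fixed
  under z-scoring); breath period 3 s ± 15%. Each trial cycle is one
  anticipatory breath inside a trial window preceded by ≥8 intertrial
  breaths, so intertrial stretches exceed 6 respiratory periods. A
  first-order 0.08 Hz hardware high-pass can be applied to the airflow
  channel (off by default because it shifts zero-crossings slightly).
* **Delta oscillator** — a respiration-coupled oscillation (default 1 Hz,
  amplitude 2 in pre-normalization units) steered by continuous frequency
  modulation over the 2 s before *every* inhale so that its phase at onset
  equals a per-breath target. Anticipatory targets are von Mises draws
  (default κ = 4 about phase 0); nonanticipatory targets are uniform.
  Anticipation therefore changes only the *consistency* of the onset
  phase, not the signal's spectral content — both conditions share
  identical FM statistics, which is what makes the no-power-difference
  control hold by construction. Two designs were rejected: an
  instantaneous phase jump at onset (a symmetric filter then mixes ~50%
  pre-reset phase, capping measurable onset ITPC near 0.64 even at
  κ → ∞) and steering before anticipatory breaths only (which puts FM
  energy in one condition and creates a real pre-inhale power
  difference). The steering mechanism is an assumption: the source data
  cannot distinguish a true reset of the ongoing rhythm from an additive
  evoked component, and this generator implements a true reset.
* **Theta bursts** — every inhale is followed by a Gaussian-enveloped
  theta burst (6 Hz, peak 0.6 s after onset, σ = 0.12 s, random carrier
  phase), emulating inhale-driven piriform theta. On anticipatory trials
  the amplitude is base × (1 + gain · cos(onset phase − preferred phase)),
  base 1.5, gain 0.5 — the anticipation-enhanced odor response. Giving
  nonanticipatory breaths the base burst matters: with bursts on one
  condition only, backward smearing through the band filters produces a
  detectable pre-inhale power difference that the real system does not
  show.
* **Background** — 1/f^1.5 Gaussian noise, total SD 1.0. The resulting
  in-band (0.5–1.5 Hz) noise amplitude is ~8% of the delta amplitude, so
  the phase-noise attenuation of measured ITPC is ≤ ~2%, comfortably
  inside the ±0.07 recovery tolerance.

Behavioral accuracy is Bernoulli with P(correct) =
logistic(2.3 − slope · DMP_true), slope 2; the intercept puts overall
accuracy near 80% so both outcome groups stay populated. Inhale peaks are
independent of phase alignment by default (an optional coupling exists for
positive-control tests).

What the generator does *not* emulate: multi-electrode volume conduction,
epileptiform artifacts, non-stationary breathing rates, odorant-specific
response patterns, or between-subject heterogeneity in reset strength
(all subjects share κ). The last point means the across-subject
ITPC↔theta correlation — driven in real data by subjects differing in
reset strength — has no signal at the defaults; the pipeline reports it
but passing tests say nothing about it. More generally, passing tests
show the estimators and inference machinery behave correctly under this
generative model, not that the scientific claims hold in any recording.

## Numerical choices

* FIR design: `scipy.signal.firwin` (Hamming), order = 3 cycles of the
  band's low edge (fixed-bandwidth mode) or 2 cycles of the center
  (short-filter control); low band edges that would reach ≤0 Hz are
  clipped to a quarter of the center frequency with a warning. The
  two-pass application uses FFT convolution with odd-reflection padding
  (filtfilt's padding; identical result to round-off, much faster for
  multi-thousand-tap kernels).
* Phase convention: angle in (−π, π], 0 at a cosine peak. Epochs are
  half-open sample windows with the onset sample at t = 0. Windowed
  maxima break ties to the lowest frequency, then the earliest time.
* The DMP mean phase is refused (error) when the resultant length is
  numerically ~0, rather than guessed.
* The combined analysis pools trials across subjects after per-subject
  normalization, without stratifying the Rayleigh test by subject.
* Airflow normalization uses the sample (n−1) SD; neural preprocessing
  z-scores with the population SD (single-channel stand-in for
  common-average referencing plus normalization).
* All randomness flows through `numpy.random.Generator`s derived from
  explicit seeds (per-subject seeds via `SeedSequence` spawn keys), so
  reruns are bit-identical.

## Problem sizes

The default cohort configuration analyzes 13 subjects × 20 anticipatory
trials (nonanticipatory subsampled to match), a 20-band 0.5–40 Hz bank,
epochs −1 to +2 s, 200 label-shuffle permutations, and 1,000 bootstrap
repetitions; one cohort run takes ~30 s on a single core.
Concentration-recovery analyses use 100 anticipatory trials per dataset
over 10 seeds. `spectral.make_filter_bank()` keeps the full 50-band
0.5–200 Hz bank for standalone use.

## Known limitations

* The respiration model has no sensor noise; detection accuracy on real
  transducer data will be worse than the near-perfect recovery seen here.
* EDF import/export is not provided; interchange is HDF5 + CSV.
* The surrogate-event null is computed per subject and combined by a
  Stouffer-style mean-z; the label-shuffle null operates on the pooled
  trial set directly.
* Real mode expects events tables with precomputed condition and accuracy
  labels alongside the recordings; it re-detects onsets from the airflow
  channel and matches labels by onset time (50 ms tolerance).
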