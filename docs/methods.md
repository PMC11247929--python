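# Methods

This note documents the models, conventions, and numerical choices the
package implements, what the synthetic generator does and does not
emulate, and the known limitations.

## Preprocessing conventions

- **Neuropil correction** is linear: `F = F_somatic − r·F_neuropil`, with
  r chosen by indicator (0.7 for GCaMP6f/GCaMP7s, 0.8 for jGCaMP8m) and
  overridable in config.
- **Baseline F0** is the rolling 30th percentile of F over a 150 s window
  (4500 frames at 30 Hz).  The window is *centered* and truncated at the
  trace edges; a centered window avoids the phase lag a causal window
  would impose on F0.  An even-length window takes its extra sample on
  the left.  Percentiles interpolate linearly between order statistics.
- **dF/F0** errors out (rather than clipping) if F0 ≤ 0 anywhere; the
  synthetic generator therefore produces fluorescence with a positive
  offset, as real sensors do.
- **Standardization** subtracts the median and divides by the sample SD.
  One convention is used package-wide: sample SD with denominator n−1
  (`ddof=1`).
- **Inclusion**: an ROI is kept when its standardized dF/F0 reaches 3
  anywhere in the session (inclusive ≥).
- **5 Hz resampling** for correlation work: linear interpolation to a
  10 Hz grid, centered 5-point moving average with truncated edge
  windows, then every 2nd sample.  At 0.1 Hz the chain's gain is the
  5-point MA transfer sin(5πf/10)/(5·sin(πf/10)) ≈ 0.9959, which the
  tests verify.

## State dynamics

Running is speed > 1 cm/s, strictly; a frame at exactly 1 cm/s is
stationary.  The activity–speed statistic is the zero-lag Pearson
correlation at 5 Hz.  Significance comes from a shuffle test:
p = (1 + #{|r_shuffle| ≥ |r_zero|}) / (1 + n_shuffles) with 1000 shuffles
and α = 0.05 by default; the add-one rule keeps p strictly positive.
Cross-correlograms span ±10 s by default; the reported peak is the
largest |r| and its lag, populated only for significant neurons.  Lag
sign: positive lag means activity follows locomotion.

Two nulls are available:

- `permutation` (default): full random permutation of one series.  This
  destroys autocorrelation, so it is *exact* only for exchangeable
  samples.  On traces that have passed the 5 Hz smoothing chain it is
  measurably liberal: the chain leaves lag-1 autocorrelation ≈ 0.6 in any
  input (even white noise), and against a slow locomotion trace the true
  variance of r is ≈ 2.6/n while the permutation null assumes 1/n —
  about a 20% false-positive rate at α = 0.05.
- `circular`: random circular shifts of one series, preserving both
  autocorrelation structures.  Measured per-session false-positive rates
  on uncoupled synthetic neurons are 0–10% (mean ≈ 3%).

The default matches the conventional "shuffle" description; analyses on
smoothed traces (including the package's own recovery tests) should use,
and do use, the circular null.  Pairwise synchrony reports one row per
unordered pair (i < j), self-pairs excluded.

## Orientation tuning

Trial windows are half-open in frames, `floor(on·rate) … floor(off·rate)`;
the baseline is the 0.5 s immediately before grating onset.
Responsiveness needs ≥ 2 trials with response > 3× that trial's
baseline-window SD; a zero-SD baseline makes the threshold 0, so any
positive response counts.  gOSI uses the doubled angle 2θ (period 180°)
and takes the modulus of the complex sum — the only reading of the
vector-sum formula that yields a real number in [0, 1].  Both gOSI and
DSI are computed on min–max-normalized mean responses so negative
standardized-dF/F0 responses cannot corrupt them.  The preferred
orientation is the argmax of the mean curve with ties broken toward the
smallest angle; the "pseudo-90°" aligned curve circularly shifts the
12-point curve so the preferred bin sits at 90°.  Split-half signal
correlation uses one seeded random split by default (odd repetition
counts give the extra repetition to the first neuron); noise correlation
averages per-orientation Pearson correlations, skipping zero-variance
orientations with a warning.  Trials are pooled across locomotion states
by default, with a per-state option.

## Contrast tuning

Per-trial state labels come from the mean speed during the grating window
(boundary 1 cm/s → stationary).  cCOM floors negative weights at zero — a
center of mass needs nonnegative weights — and excludes blank (0%)
trials, whose ln c is undefined; blanks are reported separately.
Preference classes come from the argmax of the mean contrast curve (ties
toward the lower contrast): low = {5, 10}%, high = {60, 80}%, otherwise
"other".  A cCOM-band classifier is available behind config but argmax is
the default.

## Hierarchical bootstrap

Data are nested animal → neuron (→ trial).  Each bootstrap replicate
draws **n_animals − 1** animals with replacement, then neurons within
each drawn animal with replacement (then trials, for three-level input),
and computes the group statistic on the pooled resampled values; the
difference distribution over 10,000 replicates (default) gives quantile
CIs and a two-sided sign-crossing p-value with add-one smoothing.

Drawing n−1 rather than n animals is deliberate: the variance of an
n-out-of-n resampled mean underestimates the sampling variance of the
animal-level mean by (n−1)/n, which is severe at the ~5 animals typical
of imaging studies; n−1 draws make the replicate variance unbiased.
Under a null with between-animal SD equal to within-animal SD
(5 animals × 20 neurons), the measured type-I rate is ≈ 8% at α = 0.05
(2000 simulated datasets; the residual excess over nominal comes from
treating the 4-degree-of-freedom between-animal variance estimate as
known) versus ≈ 10–11% for n-out-of-n — while a pooled t-test on the same data
rejects ≈ 55% of the time, which is the failure mode the method exists to
avoid.  Monte-Carlo calibration experiments in the tests and acceptance
script use 200 simulated datasets at 1000 replicates each; the library
default stays at 10,000 replicates.  A single-animal group triggers a
warning (animal-level uncertainty is unidentifiable) and falls back to
neuron-level resampling.  BCa and studentized variants are out of scope.

## Rabies-tracing quantification

Starters are GFP⁺ mCherry⁺; inputs are mCherry⁺ GFP⁻.  Input fractions
use input cells only in the denominator (a flag restores
starter-inclusive counting); the reporting filter is strictly > 1%.
Local layer fractions restrict to ipsilateral cells in the injected
region (VISp by default).  Region labels follow Allen CCFv3 acronyms;
registration itself is upstream of this package.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, at
the level of extracted ROI traces:

- **Locomotion**: two-state semi-Markov bouts with exponential durations
  (means 20 s stationary / 10 s running — chosen so both states are well
  sampled in a 730 s session), lognormal run speed (median 5 cm/s,
  σ = 0.4), small within-bout jitter, and a 0.1 s Gaussian smoothing for
  wheel inertia.  Bout statistics of real mice are not reported in the
  protocols this emulates; these are conventions, not estimates.
- **Rates**: baseline 0.1 events/s, multiplied by `run_gain` in running
  frames, plus `speed_coupling`·speed, plus a visual term
  `visual_gain · vonMises(2(θ−pref), κ) · contrastResponse(c)` inside
  grating windows.  The contrast response is Naka–Rushton
  `c^n/(c^n + c50^n)` (defaults c50 = 20%, n = 2) or its reflection
  1 − NR for contrast-suppressed neurons; blanks drive nothing.
- **Fluorescence**: Poisson events per frame convolved with a single
  exponential kernel (τ = 1 s, GCaMP-like; amplitude 0.2 a.u.), a +1 a.u.
  offset, Gaussian noise (SD 0.1 a.u.), and a shared low-pass neuropil
  signal mixed in with weight 0.7 — equal to the correction factor, since
  that factor is the field's estimate of the true contamination weight.
- **Pupil**: slow Gaussian-filtered latent signal with square blink
  dropouts at Poisson times (default 2/min), returning ground-truth
  intervals for validating detection.
- **Traced cells**: multinomial sampling of regions, layers and
  hemispheres from a spec whose probabilities must sum to 1.

Every generator routes all randomness through a single seeded
`numpy.random.Generator`, so a fixed seed reproduces outputs
bit-identically.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: pixel-level imaging and
segmentation artifacts, motion/z-drift, indicator nonlinearity and
saturation, adaptation and trial-history effects, correlated network
variability beyond the shared neuropil term, and eye-movement-linked
pupil dynamics.

## Problem sizes in tests and acceptance

Recovery experiments use sizes a desk-scale study would: 40-neuron
spontaneous sessions (pooled over three sessions for the
coupling-recovery check, so the binomial noise of a 20-neuron group does
not dominate the outcome), a 100-neuron orientation session, 200–300
neuron contrast sessions at the full 6 × 8 × 15 trial design, 200–500
Monte-Carlo replicates for calibration experiments, and n = 5000 traced
cells.  The blank-trial zero-centering check is a ±2 SE assertion and so
retains an irreducible ~5% false-alarm probability by construction.

## Known limitations

- The permutation null's liberality on smoothed traces is inherent to
  permuting samples of an autocorrelated series; the circular null is the
  supported remedy, not a fix to the permutation itself.
- The hierarchical bootstrap is calibrated, not exact: with 5 animals its
  type-I rate sits slightly above nominal (≈ 8% at α = 0.05).
- Linear mixed-effects models and ANOVA are intentionally not
  re-implemented; result tables leave room for externally computed
  p-values.
- The Suite2p/Facemap ingestion path is a documented container schema,
  not a format parser.
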