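# Methods

## Staging model

Sleep staging is unsupervised, one recording at a time. The observation
sequence is the per-epoch vector of relative band powers in the four
stage-associated bands (Wake 35–50 Hz, REM 20–30 Hz, Light 10.15–15.75 Hz,
Deep 1–3 Hz); because the powers are normalized per epoch, features live on
the probability simplex and the 0.7/0.1 structure of the initial emission
means is directly commensurate with them. The hidden chain has four states
in fixed order Wake=0, REM=1, Light=2, Deep=3.

Assumptions: one scoring epoch is homogeneous (a single stage); emissions
are conditionally independent diagonal Gaussians given the stage (no
cross-band covariance — the initializer supplies only per-band standard
deviations, and the EM update keeps the diagonal restriction); stage
dynamics are first-order Markov at epoch resolution.

Initialization encodes physiology rather than data: π₀ = (1,0,0,0) because
a recording starts with lights-off wakefulness; Q₀ favors self-transitions
and forbids direct Wake→Deep and REM→Deep jumps; μ₀ puts 0.7 in the state's
own band; σ₀ is the identity. EM re-estimates all three parameter groups.
Two consequences are documented as behavior, not bugs:

* **Label anchoring.** Nothing but μ₀'s diagonal ties state 1 to "REM" etc.
  After EM the labels are only as trustworthy as that anchoring; on data
  whose band structure departs from the prior, stages can swap. The
  end-to-end tests quantify this on synthetic nights.
* **Structural zeros persist.** Zero entries of Q₀ are *not* clamped during
  EM, but a zero transition probability has zero expected counts and
  therefore remains exactly zero under the EM update — the unconstrained
  update and the clamped variant coincide. π is re-estimated by default;
  `update_startprob=False` holds it at (1,0,0,0).

Numerical choices: forward/backward, the transition-count accumulation and
Viterbi run in log space (numba kernels); the per-band emission standard
deviation is floored at 1e-4 to prevent cluster collapse on degenerate
features; EM stops when the absolute log-likelihood gain drops below 1e-6
or after 100 iterations; an internal error is raised if the log-likelihood
ever decreases beyond float tolerance (an EM invariant, asserted per
iteration); Viterbi ties break toward the lower stage index, so decoding is
deterministic; states with (numerically) zero occupancy keep their previous
parameters instead of dividing 0/0. A recording with a single complete
epoch is decoded under the prior parameters without EM, since EM needs at
least two epochs.

## Band-power features

Band filtering uses a complex Morlet CWT (`cmor2.0-1.0`) evaluated on a
0.5-Hz grid spanning each band, including fractional band edges. Three
calibration details matter:

* pywt's CWT differentiates an integrated wavelet, which imposes a
  first-difference sinc² rolloff toward Nyquist; the per-frequency power is
  divided by sinc²(f/fs) so the response to flat-spectrum input is level.
* per-frequency powers are *integrated* over the band (trapezoid), not
  averaged, so bands of very different widths (2 Hz vs 15 Hz) are
  comparable as total band power.
* epochs are reflect-padded past the longest wavelet support so the 1-Hz
  wavelet (whose support is a large fraction of a 30-s epoch) is not
  attenuated at epoch edges.

The wavelet bandwidth parameter (B = 2.0) and grid step (0.5 Hz) were
chosen together where three requirements meet: a pure tone at a band center
keeps >90% of its relative power in its own band; two equal-amplitude tones
in different bands come out within 0.1 of each other; and on broadband
noise the estimates agree with an independent periodogram band-integration
oracle within 15% (in practice ~2%). An order-4 zero-phase Butterworth
band-pass power estimator is provided as a second, independent cross-check.
No artifact rejection or notch filtering is applied; note that 50-Hz mains
interference would fall inside the Wake band on real recordings.

## Sleep indices

RNR is reported in percent with non-REM *sleep* (Light+Deep) in the
denominator; including Wake is switchable but off, because only the
sleep-only reading is consistent with cohort-scale values (REM ≈ 58 min
against ≈ 256 min of non-REM sleep gives ≈ 23%). SSI counts every
adjacent-epoch label change over the whole record, including changes into
and out of Wake, divided by TST in hours; a within-sleep-only variant is
available. Sleep onset is the first sleep-scored step with no
N-consecutive-epoch smoothing. SE/TST/SOL/WASO are computed from a binary
sleep/wake sequence at any step size, so hypnograms (0.5-min steps, sleep =
non-Wake) and actigraphy (1-min steps) share one code path. A record with
no sleep at all returns SE = 0 and TST = 0 with SOL/WASO as NaN — a single
return value cannot simultaneously raise and report, so "undefined" is
encoded as missing.

## Actigraphy scoring

The Sadeh regression PS = 7.601 − 0.065·AVG − 1.08·NAT − 0.056·SD −
0.703·LG is evaluated over an 11-minute window centered on each minute
(AVG: window mean; NAT: window minutes with counts in [50, 100); SD:
population standard deviation of the 5 preceding minutes; LG: ln(counts+1));
PS ≥ 0 scores sleep. The constants live in one auditable block. Record
edges use clamped windows over available minutes (SD over however many
preceding minutes exist, 0 at the first minute); the [50, 100) NAT band
follows the implementation tradition of the original regression. PS is
monotone decreasing in AVG and LG but *not* in the raw counts: a uniform
increase in activity can push minutes out of the [50, 100) band and raise
PS by up to 1.08 per exiting minute, so "more activity never flips wake to
sleep" holds only while band membership is unchanged — the property test is
scoped accordingly.

## Evaluation

Per-stage agreement is one-vs-rest (stage = positive, other three pooled),
the only framing in which a per-stage accuracy with a TN term is coherent.
Undefined ratios (zero denominators) are reported as NaN, never 0, so stage
averages are not silently deflated. Reference records may carry movement or
unscored epochs; these are removed pairwise before the remaining labels are
merged 6→4 (S1/S2→Light, S3/S4→Deep) or 5→4 (N1/N2→Light, N3→Deep).

## Study statistics

Condition comparisons use the paired two-sided Wilcoxon signed-rank test
with the exact null distribution up to 25 nonzero differences (the study
scale is n = 10, so no normal approximation is ever used there); zero
differences are dropped (Wilcoxon's convention; Pratt's is available).
"The better of S/SH" is resolved per index and direction-aware — higher is
better for depth, length, SE, TST, REM, Deep and RNR; lower for SOL, WASO
and SSI — because a single global "highest score" is not well defined
across indices with opposite polarities. No multiple-testing correction is
applied by default, matching the single-comparison-per-index design; a Holm
adjustment is available behind a flag. Subjects missing one night of a pair
are excluded with a warning. Spearman correlation uses average ranks for
ties. The poor/good split is PSQI > 5.

## Synthetic data

The generator reproduces the statistical structure the pipeline assumes,
with ground truth retained at every level:

* **Hypnograms** are samples of the four-state chain, defaulting to the
  stager's prior (π₀, Q₀) over 840 30-s epochs — a 7-h night.
* **EEG** is, per epoch, a sum of four *exactly* band-limited noise
  components (FFT brickwall), mixed with relative powers drawn around
  μ_true[stage], clipped to ≥0, renormalized, and scaled to unit epoch
  variance. Epochs are synthesized independently; continuity across epoch
  boundaries is not guaranteed. Default emission spread σ = 0.15 puts
  adjacent stage means 4 standard deviations apart on the discriminating
  band — the separability regime the end-to-end accuracy contract assumes.
* **Actigraphy** counts are per-minute Poisson, 200/min during Wake and
  5/min during sleep by default (quiescent sleep vs active wake at
  plausible count scales).
* **Cohorts** follow the three-condition crossover (A fully inflated
  mattress baseline, S shoulder-customized, SH shoulder+hip-customized,
  n = 10). Each subject has one base night shared across conditions (the
  within-subject correlation a paired design relies on) and each
  condition-night independently re-scores 10% of epochs from the subject's
  own stage distribution (night-to-night variability). Condition effects
  are injected by converting randomly chosen Light epochs to REM (or Deep)
  until an exact minute target is met — the default REM boost is 0 / 10 /
  20 min for A / S / SH, the direction and order of magnitude of the
  reported customization effect — so recovered effects can be compared to
  known truth. PSQI defaults to the fixed profile (2,3,4,5,5,6,7,8,9,10):
  mean 5.6, range 2–10, and exactly 5 poor sleepers at the PSQI > 5 cutoff.
  Subjective depth/length ratings are integer draws around per-condition
  means on the 1–7 scale.

What the generator does **not** emulate: physiological EEG morphology
(spindles, K-complexes, slow-wave shapes), artifacts, mains interference,
non-stationarity within an epoch, or realistic accelerometer burst
dynamics. Tests passing on this generator demonstrate the correctness of
the pipeline's *computations* under its own model assumptions, not staging
accuracy on real recordings.

## Problem sizes

Simulation-based checks use the study's native scales: 840-epoch nights,
2000-epoch sequences for parameter recovery (3 seeds), 500-epoch sequences
for EM-ascent checks (50 random initializations), 5 nights for end-to-end
accuracy, 200 cohorts for the null rejection rate and 20 for effect
detection.

## Known limitations

* Parameter recovery at *unit* emission spread is information-limited: with
  0.6 separation between means and σ = 1, 2000 epochs are insufficient for
  ±0.1 mean recovery even with known labels (Wake occupies ~8% of the
  night, giving a per-band standard error of ~0.08); the EM estimate is
  correspondingly farther. Recovery to ±0.1/±0.08 is demonstrated in the
  4-SD separable regime.
* The EDF writer is minimal (single channel, 16-bit, 1-s records) and
  intended for synthetic data; reading goes through MNE and handles
  EDF/EDF+ generally.
* No supervised or deep-learning stager, no 5-class decoding, no sleep-cycle
  detection, and no Cohen's kappa — outside the package's scope.
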