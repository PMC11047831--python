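# Methods

This note documents the models implemented in `aviasomn`, the defaults
and why they were chosen, the numerical decisions, what the synthetic
generator does and does not emulate, and the known limitations.

## Protocol model

A recording covers consecutive protocol days, each split 50/50 into a
light and a dark phase (12:12 at the default 24 h day). Recordings start
at lights-on (08:00 by convention), so the dark phase is the second half
of every day. The default study protocol is three days — `baseline`,
`cold`, `recovery` — with ambient temperature constant at 21 °C except
during the dark phase of the cold day: a linear descent over the first
sixth of the night (2 h of a 12 h night) to a 4.8 °C plateau, and a
mirrored re-warming ending at lights-on.

`day_hours` is configurable (default 24). Scaled-down days keep every
structural property (phase split, cold-night placement, epoch grid) and
are what the test suite and the cohort-determinism check run on, purely
to keep runtimes short; all scientific defaults are the full 72 h
protocol. Problem sizes used by the tests: 1–6 h days for signal-level
checks, full 24 h days for scoring recovery and architecture statistics,
the full 72 h protocol for temperature analyses.

## Sleep-architecture simulator

Vigilance states follow a semi-Markov chain on {WAKE, NREM, REM} with
bout durations in whole 4-s epochs, geometric by default (a negative
binomial with a dispersion parameter is available). Geometric bout
lengths make the epoch process first-order Markov and reproduce the
right-skewed bout histograms seen in short-sleeping birds with the
correct mean, using no parameters beyond that mean.

Structural constraints: REM is entered only from NREM; Wake can follow
either sleep state; Wake always returns to NREM. Per light phase, with
target sleep fraction `p`, REM share of sleep `r`, and mean bouts `mN`,
`mR`, `mW` (in epochs):

* `a = P(NREM→REM) = r·mN / ((1−r)·mR)`, clamped to 1;
* the expected wake time per sleep cycle is `(mN + a·mR)(1−p)/p`; when
  this exceeds the configured wake bout mean (the light phase of a
  strongly nocturnal sleeper), the wake bout mean is inflated to match,
  otherwise `b = P(REM→NREM)` absorbs the remainder;
* bouts are cut at light transitions and the state re-drawn from the new
  phase's stationary distribution (REM cannot open a phase and is folded
  into NREM), so each phase's expected sleep fraction equals its target
  exactly.

With the default night bout means (NREM 31.8 s, REM 11.1 s) an exact 26%
REM share is marginally infeasible under REM-only-from-NREM — each REM
bout needs an NREM predecessor, and the required `a` is ≈1.007. Clamping
to 1 yields a realized REM share of ≈25.9%, a 0.5% relative shortfall
that is invisible at the tolerances of every downstream analysis.

Defaults (baseline-night statistics of the study system): sleep in 90.5%
of the dark phase and 1.6% of the light phase; REM 26% of sleep; mean
bouts 31.8 s NREM, 11.1 s REM, 50.3 s Wake.

## Signal synthesis

Per-state EEG is Gaussian noise shaped by a second-order Butterworth
filter — low-pass at 5 Hz for NREM (slow, high-amplitude waves),
5–30 Hz band-pass for REM and Wake (fast, low-amplitude) — normalized to
unit RMS through the filter's analytic noise gain and scaled by the
state amplitude (NREM 2.0, REM/Wake 1.0, in arbitrary µV-like units), so
the NREM:REM epoch-RMS ratio is the configured 2 by construction. EMG is
white noise at a per-state tone (Wake 3.0, NREM 1.0, REM 0.4) plus
movement bursts in ~60% of Wake epochs. The accelerometer carries a
constant gravity offset, sensor noise (SD 0.005 g), and low-pass-shaped
movement (SD 0.3 g) during Wake only. These burst models and noise SDs
are free parameters of the generator; the values are chosen so the
state-separating contrasts (amplitude, EMG tone, movement) dominate the
within-state variability, as they do in clean recordings.

Artifacts are injected as gross movement events at a configurable rate
(epochs drawn uniformly; default rate 0): EEG and EMG of the epoch scale
by `artifact_gain` (default 3) and a large accelerometer burst is added,
so an artifact is elevated on all three channel groups relative to its
own state's background — the signature the artifact rule tests for.

## Brain-temperature model

Tbr(t) = base (41 °C) + circadian + state drift + cold depression +
white noise (SD 0.02 °C), on a 1 Hz grid by default.

* **Circadian**: a sinusoid with period one protocol day, peaking
  mid-light. The amplitude parameter is defined as the light-minus-dark
  *mean* difference (default 2.1 °C), so the sinusoid half-amplitude is
  `amp·π/4`.
* **State drift**: an Ornstein–Uhlenbeck-like integration
  `x ← x + dt·drift(state) − x·dt/τ` with τ = 180 s, so long bouts
  plateau instead of drifting without bound. Defaults: REM +0.004 °C/s
  (warming), Wake −0.003 °C/s (cooling), NREM −0.0005 °C/s (slight
  cooling).
* **Cold depression**: the ambient deficit, normalized to the cold
  plateau, passed through a first-order lag (τ = 30 min) and scaled by
  the depression parameter (default 1.1 °C at the settled plateau).

Two consequences worth knowing. First, the *realized* light–dark Tbr
difference under defaults is ≈1.5 °C, not 2.1 °C: sustained daytime
wakefulness sits near its OU equilibrium `drift·τ ≈ −0.54 °C` below the
circadian baseline, while the night mixes NREM/REM/Wake contributions
near zero. The 2.1 °C parameter is the circadian component itself
(recovered exactly when drifts are disabled). Second, with mean
reversion switched off the integrated drift is non-stationary: the
state-weighted mean drift differs between phases, producing a large
day-periodic sawtooth that a 23.15 h first-order filter only partially
removes. Drift-recovery checks therefore run on a single night, where
the detrending stage's short-series fallback (mean subtraction) applies
and episode-relative slopes recover the configured drifts within a few
percent.

## Scoring

Features per 4-s epoch (12 dimensions): log band power at 1.5–4, 4–8,
8–15, 15–25 Hz for both EEG channels (periodogram of the epoch), log
robust peak-to-peak amplitude (2.5–97.5 percentile span) for both EEG
channels, log EMG RMS, and accelerometer activity (mean jerk magnitude).
All-zero channels floor at 1e-12 inside the log rather than producing
non-finite features.

The classifier is a 300-tree random forest (scikit-learn), deterministic
under a fixed seed and robust at ~100 training epochs per class; the
`TrainedScorer` interface accepts any scikit-learn classifier. Training
epochs for automated runs are a stratified random draw standing in for
an experienced scorer's manual selection. Training requires all three
states with at least 20 epochs each.

Per-state "accuracy" is reported as the F-measure (harmonic mean of
per-state precision and recall), and the full confusion matrix is always
returned so recall, Cohen-style agreement, or any other statistic can be
recomputed. The permutation null control is reported as the mean
held-out accuracy over 20 independent label permutations: predictions
from a single permuted fit are cluster-correlated (whole feature regions
flip to one class), making one permutation a high-variance estimate of
the chance level.

## Artifact rule

An epoch is flagged when all three hold: EEG amplitude envelope >
2× reference, EMG RMS > 2× reference, accelerometer activity > 2×
reference, where each reference is the centred rolling median over the
75 nearest epochs *of the same scored state* (5 min of same-state
epochs). Conditioning on state keeps normal high-amplitude NREM epochs
from being flagged against a Wake-dominated neighbourhood; the median is
robust to the artifacts themselves at plausible rates. A disjunctive
("any") mode exists behind a flag. Raising any factor can only shrink
the flagged set. Flagged epochs keep their scored state for time
accounting and are excluded from spectral and temperature analyses only.

## Spectral analysis

Each 400-sample epoch is Hann-tapered, zero-padded to 512 points (the
smallest power of two that holds it — the only choice that yields 256
positive-frequency bins of ≈0.2 Hz at 100 Hz) and Fourier-transformed.
Power is mean-square per bin: one-sided, DC excluded, taper compensated
by its power, so with no taper and no padding the bins (plus DC) sum to
the epoch variance exactly. An untapered and a no-padding (400-point)
mode exist for verification.

Normalization divides each bin by the bird's own mean over
baseline-night clean NREM epochs, making the reference mean exactly 1 in
every bin and removing between-bird gain differences. The 1.5–25 Hz band
average is the unweighted mean over the 121 bins whose centres lie in
the closed interval. Both EEG derivations are averaged by default;
per-channel spectra are available. Hourly NREM power is the mean band
value over clean NREM epochs of the hour; cumulative NREM sleep energy
adds hourly power × hourly NREM minutes, with a zero increment (and
missing power) for hours without clean NREM — energy is a time-integral,
so an empty hour contributes nothing.

## Temperature processing

Minute deviations: non-overlapping 60-s means minus the bird's
baseline-day mean. Circadian detrending: first-order Butterworth
high-pass at 0.000012 Hz (cutoff period 23.15 h), applied
forward–backward (`sosfiltfilt`) because a single causal pass at this
cutoff lags the output by hours and would smear episode alignment; the
zero-phase gain is the squared magnitude response, attenuating a 24-h
sinusoid to ≈0.48 of its amplitude while a 60-s event keeps >99.9% of
its height over the local baseline. A literal low-pass mode exists for
comparison. Series are linearly interpolated to a 1-s grid first; NaN
gaps longer than 5 min split the series and each segment is filtered
independently; segments shorter than three cutoff periods fall back to
mean subtraction with a warning.

Episode alignment subtracts the 1-s value at episode onset (t = 0 is
exactly zero by construction), excludes episodes containing artifact
epochs, and averages across episodes per state × night × bout-length
stratum (short ≤ 75 s, long > 75 s; durations are multiples of 4 s, so
the boundary itself never occurs at the default epoch length). Short
curves truncate at 75 s; long curves extend to the longest contributing
episode with the per-point episode count reported, which is
non-increasing in time. SEM is across episodes pooled over the night;
a bird-first aggregation can be built from the per-bird outputs.
The bootstrap utility resamples episodes with replacement within each
night (1000 resamples, seeded) and reports the percentile CI of a
between-night difference at a chosen offset.

## Pipeline

`run_pipeline` executes simulate → score → artifact rejection →
spectra/energy → architecture report → temperature dynamics for a cohort
(default 8 birds, alternating sex labels carried as metadata only).
Stages communicate through files; existing outputs are reused, so
deleting one stage's files and re-running regenerates exactly that stage
and its dependents. Per-bird, per-stage seeds derive from the run seed
via `numpy.random.SeedSequence` with a stable digest of the stage name,
so identical config + seed gives byte-identical outputs. The manifest
records the package version, the config, and SHA-256 digests of every
output.

## What the generator does not emulate

Real recordings contain drifting electrode impedance, unihemispheric
and intermediate vigilance states, scorer disagreement near transitions,
non-stationary spectral content within a state, seasonal photoperiod
effects, and temperature sensor calibration drift — none of which are
modelled. The generator's state contrasts are strong and stationary, so
near-perfect scoring accuracy on synthetic data demonstrates that the
train-then-score machinery recovers a learnable mapping, not that real
recordings would score at that level; the study-scale figure of merit on
real data remains in the 0.89–0.98 range per state. Likewise the
artifact model (all-channel gross movement events) matches the rule that
detects it; subtler single-channel artifacts would require the
disjunctive mode or sample-level methods, which are out of scope.

## Known limitations

* The EDF writer supports the subset of EDF this pipeline produces
  (uniform rate, 16-bit, 1-s records); EDF+ annotations and BDF are not
  supported. Reading goes through `mne`, so anything mne reads can be
  adapted at the container level.
* Episodes truncated by a lights transition are excluded from
  night-restricted bout statistics; at bout means of tens of seconds the
  exclusion is negligible, but for species with hour-long bouts it would
  bias means low.
* The first-order circadian filter removes only ~52% of a 24-h
  sinusoid's amplitude (by design — it is first order); analyses that
  need stronger suppression should average episodes across circadian
  phases, as the episode-aligned curves do.
* The scorer is per-recording, as in the train-then-score protocol;
  cross-recording transfer is a non-goal.
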