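# Methods

This note documents the models, estimators and numerical choices behind
`sniffcode`, in the spirit of a statistical-software methods appendix.
Times are seconds everywhere, t = 0 is the first inhalation of odor (t0),
and every analysis window is half-open [a, b).

## Synthetic sessions

The generator emulates the structure of awake head-fixed recordings during
passive odor presentation: 11 odors × 4 relative concentrations
(0.25, 0.33, 0.50, 1.00) × 25 repetitions plus blank trials, ~300-ms
respiration cycles, and 1-s odor delivery triggered at the exhalation
phase so that the first inhalation of odor is well defined on every trial.

**Respiration.** Cycle periods are drawn i.i.d. N(0.30 s, 0.02 s) (clipped
positive); within a cycle the pressure is −sin(2π·phase), so inhalation is
the downward half-wave and cycle starts are descending zero-crossings.
Additive Gaussian noise (default 1% of the unit amplitude) models sensor
noise.  The true cycle starts are returned as ground-truth inhalation
onsets.

**Odor timing.** Odor valves open at the exhalation midpoint (phase 0.75)
of the first cycle after the nominal trial time; t0 is the next cycle
start.  Trials are spaced 4 s apart and presented in seeded random order.

**Rate model.** No published rate model exists for these data, so the
firing model is an explicit stand-in chosen for smooth, peaked SDFs: every
unit fires as an inhomogeneous Poisson process with rate

    λ(t) = b + A(c) · exp(−(t − t0 − L(c))² / 2w²)   (responsive pairs)
    λ(t) = b                                          (otherwise)

with baseline b = 3 spikes/s, bump width w = 20 ms, and gamma-distributed
amplitudes (mean 20, sd 8 spikes/s at the reference concentration).
A unit responds to a given odor with probability 0.15; with 11 odors this
makes ~51% of units responsive to two or more odors, matching the reported
~48% of cells with rate increases to at least two odors.

**Concentration laws** are log-linear per doubling, referenced to the
highest delivered concentration c_ref:

    L(c) = L₀ + s · log₂(c / c_ref),   A(c) = A · max(0, 1 + g · log₂(c / c_ref))

Class defaults: fan-like cells L₀ = 72 ms, s = 0 (latency invariant);
pyramidal-like cells L₀ = 78 ms, s = −10 ms/doubling (earlier at higher
concentration); both g = 0.2 (≈1.7-fold rate increase over the fourfold
range — a deliberately weak rate code).  The across-cell latency scatter
also shrinks with concentration, sd(c) = 12 ms − 5 ms · log₂(c/c_ref)⁻¹
style (sd 22 ms at the lowest, 12 ms at the highest concentration), which
produces the programmed increase of population synchrony.  Each unit-odor
pair draws one standard-normal deviate reused across concentrations, so a
pair's latency moves smoothly with concentration.

**Sampling.** Spike trains are exact inhomogeneous Poisson samples by
superposition: a homogeneous baseline process on the simulated trial
window plus, for responsive pairs, an independent bump process whose event
count is Poisson with mean A(c)·w·√(2π) and whose event times are normal
around t0 + L(c) (events outside the window are dropped — exactly the
window-truncated process).  This is distributionally equivalent to
thinning for this rate model, cheaper, and fully vectorized.  One global
integer seed drives independent sub-streams (respiration, ground truth,
schedule, spikes) via `numpy` SeedSequence spawning, so sessions are
byte-reproducible.

**Behavior.** 2AFC sessions draw stimulus class, LED state (default 25% of
trials), and correctness at the programmed accuracy per LED state
(defaults 0.80 off / 0.50 on).  First-lick times are
decision_latency + |N(0, jitter)| (defaults 200 ms + 25 ms), giving a
sharp earliest-lick onset that serves as ground truth for the d′ onset
estimator.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: trial-to-trial rate correlations and slow
drift, multi-peaked or suppressed responses, sniff-frequency modulation by
odor, cross-region conduction structure beyond class latency means, and
any biophysics.  Parameter-recovery results show the estimators are
correct, not that the rate model is.

## Event detection and alignment

Inhalation onsets are descending zero-crossings of the Gaussian-smoothed
(5-ms sd), mean-subtracted pressure, with hysteresis: a crossing counts
only after the signal re-armed above +h since the previous accepted onset,
h = 10% of the signal SD.  Crossing times are linearly interpolated
between samples.  On generator traces at 1% noise this recovers ≥99% of
true onsets within ±2 ms.  The experimental detector behind such data is
typically unpublished; this one is a documented choice.

t0 is the earliest onset at or after odor onset and before odor offset;
trials without one are flagged invalid, not dropped silently.  Rasters
store spike times relative to t0 in the default window [−0.10, 0.30) s —
one sniff cycle — and alignment is a pure translation (inter-spike
intervals are untouched; a test asserts this).

**Phototagging.** A unit is tagged if its rate in [0, 5) ms after light
pulses exceeds the [−10, 0) ms baseline (one-sided paired t-test across
pulses, default α = 0.01) *and* the SD of its first-spike latency across
pulses is ≤ 2 ms.  "Consistent latency" is not quantified in the
literature this mirrors; 2 ms is the package default and configurable.

## Single-unit statistics

SDFs convolve 1-ms binned counts with a unit-area Gaussian (σ = 10 ms);
kernel mass beyond the window edge is truncated, not renormalized, so
rates are biased low within ~2σ of the edges (documented, not corrected).
A unit-condition is **activated** when its early-window rate exceeds the
paired blank-trial rate (pairing by presentation order) with a one-sided
paired t-test at p < 0.05.  One-sided is a deliberate reading of
"significantly increased": it makes the null activated fraction equal α
(the type-I calibration test asserts the 5% level); a two-sided test with
a positive-mean gate would target 2.5%.  No multiple-comparison correction
is applied, mirroring common practice at p < 0.05.

The default early window is [50, 100) ms after t0 (where odor-evoked
firing peaks; the CA1 variant [81, 131) ms is provided as a constant), the
late window [200, 300) ms.  Lifetime sparseness uses the mean rate change
vs blank across odors with negatives clipped to zero; an all-zero vector
is undefined (NaN), never silently 0.  The cross-validated peak map sorts
cell–odor pairs by the peak time of their odd-trials SDF and displays
row-normalized even-trials SDFs, so ridge structure cannot arise from
sorting noise.

## Population geometry and decoding

Response tensors are units × condition × trial × bin rates; trial counts
are equalized by truncation in presentation order.  Pseudopopulations
concatenate units across recordings with seeded random trial pairing per
condition (identity pairing for a single recording).  PCA is fitted over
the unit dimension on condition-averaged time-bin vectors by default
(per-trial mode available), with per-unit mean centering and **no**
variance scaling — z-scoring would erase the rate-magnitude differences
the rate-code analyses quantify.  Discriminability is the unweighted mean
pairwise Euclidean distance between condition trajectories in the first
K = 3 components per 1-ms bin; it is invariant to joint rotations of the
scores (tested).

Decoding uses a linear SVM (C = 1, native one-vs-one), stratified 20%
holdout repeated with fresh seeded splits (default 50 repeats; tests use
fewer), classes equalized by seeded subsampling.  Binary features mark a
unit active on a trial when its rate exceeds the unit's *training-split*
mean — the threshold never sees test trials, so the binary mode cannot
leak.  Sliding windows advance in 5-ms steps with 50-ms width by default;
the number of positions is floor((T − w)/step) + 1.

## Temporal code statistics

Peak time is the earliest argmax of the trial-averaged SDF in
[0, 300) ms; ties break deterministically to the earliest bin.
Concentration trends are Spearman rank correlations pooled over cell–odor
pairs (rank-invariant to log vs raw concentration).  The synchrony
statistic averages |Δ peak time| over unordered pairs *within* odor, then
across odors — pooling across odors would mix odor tuning into what is
meant as a timing measure (a pooled mode exists for comparison).  The
programmed latency shift is recovered by least squares of peak time on
log₂ concentration; at 100 units/class, 6 odors and 25 trials the
recovery error is well under 1 ms against a ±3 ms requirement.

## Behavioral d′

A trial counts toward time t once its first lick occurred at or before t;
hit and false-alarm rates are cumulative response probabilities (the
unresponded remain in denominators).  The log-linear correction
(+0.5 counts, +1 totals) keeps d′ finite at rates 0 and 1; no correction
convention is standard for these tasks, so this common one is the package
default.  The significance onset compares per-session d′ curves against
their own stimulus-label-shuffled null (mean of 20 shuffles) with a
one-sided paired t-test per step, requiring k = 3 consecutive significant
steps to suppress isolated bins.  Antisymmetry holds under relabeling the
stimulus classes; scoring the other class as "signal" leaves d′ invariant
by construction.

## Pipeline and determinism

All inputs and outputs are tidy CSV (dense tensors are rebuilt from
events on demand rather than cached in a binary format); every output
carries the hash of the scientific config as a comment header, and
`manifest.json` records config, seed and library versions.  Configs are
schema-validated (unknown keys rejected, named in the error).  Running
`run-all` twice with one seed yields byte-identical result files; the run
log records wall-clock stage timings and is the one output excluded from
that contract.

Test problem sizes are chosen to keep the default suite fast while leaving
the statistical checks well-powered: calibration suites use 1000
independent unit-odor pairs, recovery suites 100 units per class with 6
odors and 25 trials per condition.  The generator's scientific defaults
(11 odors, 4 concentrations, 25 repetitions) are unchanged by any test.

## Known limitations

- The rate model is a stand-in; all generator distributions are package
  choices, not fitted to data.
- SDF edge bias (no kernel renormalization) slightly depresses peaks
  within ~20 ms of the window edges.
- The paired activation test assumes blank trials are exchangeable with
  odor trials in presentation order; slow drift would violate this.
- Spearman trends pool cell–odor pairs and ignore within-cell correlation,
  as is conventional for these statistics; p-values are anticonservative
  under strong within-cell dependence.
- The d′ onset criterion (shuffled-null paired test, 3 consecutive steps)
  is one reasonable choice among several; onsets shift by ±1 step under
  nearby choices.
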