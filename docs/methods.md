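# Methods

This note documents the models, estimators, and numerical choices behind
`skillcontext`, and what the synthetic generator does and does not
emulate.

## Behavioral model

**Correctness labeling.** A keypress is correct iff it belongs to at least
one run of five consecutive presses, within one practice trial, matching
any circular shift of the 5-item target sequence.  Ordinal positions
(1–5, relative to the canonical un-shifted sequence) are assigned from the
earliest-starting matching window containing the press; for sequences
whose circular shifts are all distinct (the default 4-1-3-2-4 included)
overlapping windows always agree on the ordinal, so the tie rule only
matters for degenerate periodic sequences.

**Skill.** The instantaneous correct-sequence speed is `1 / mean(4 KTTs)`
of a matching window, attached to the press that completes the window
(keypresses/s); per-trial skill is the median of these samples, NaN for
trials with no correct sequence.  Micro-online gain per trial is last
minus first instantaneous speed within the trial; micro-offline gain per
rest break is the first speed of the next trial minus the last speed of
the previous.  The first/last-sample estimator is a deliberate choice (the
field's verbal definition "end of one practice period to onset of the
next" does not pin down an estimator); with it, cumulative online +
offline sums telescope exactly to total early learning, which the tests
assert to 1e-10.  Missing trials propagate NaN gains and are excluded from
cumulative sums with a logged count.  The pre-planning control
(`skip_first_k`) removes speed samples from windows that start within the
first k presses of a trial.

**Learning curve.** `L(t) = C1 + C2 (1 − e^{−kt})` is fit to group-mean
trial speeds by trust-region-reflective least squares under `C2 ≥ 0`,
`k ∈ [1e−6, 10]`, with 5 starts (one deterministic at `(y₁, span, 0.2)`,
four seeded log-uniform in k) to guard against local minima.
Monotonically decreasing data drives k to its lower bound and emits a
warning rather than an error.  The early-learning cutoff is the closed
form `T = ⌈−ln(1 − f)/k⌉` (f = 0.95 by default): the smallest integer
trial at which the fitted fractional gain reaches f.  Note that for a
published parameter set of this paradigm (C1=0.5, C2=0.15, k=0.2) this
rule yields T=15 while the originating study reports T=11; the stated
rule and the printed value are inconsistent with each other, so the
package implements the rule and leaves T configurable wherever it is
consumed.

**Power calculation.** The minimum sample size for a two-sided one-sample
t-test is found by exact noncentral-t iteration: power(n) =
`1 − F_nct(t_crit; n−1, d√n) + F_nct(−t_crit; n−1, d√n)`, incrementing n
from the floor n=2.  At d=0.8115, α=0.05, power 0.95 this gives n=22.

## Feature extraction

Filtering uses a 4th-order Butterworth band-pass applied forward-backward
(`sosfiltfilt`), i.e. zero-phase, on the continuous series before
epoching, avoiding per-epoch edge artifacts.  Canonical band edges:
broadband 1–100, delta 1–3, theta 4–7, alpha 8–14, beta 15–24, gamma
25–50, high-gamma 51–100 Hz.

Sign-flip parcellation addresses the sign ambiguity of beamformed source
series: per parcel, voxel loadings on the first principal component define
the reference orientation (component sign fixed so the loading sum is
positive); negative-loading voxels are negated before averaging.  When
dipole orientations are available upstream they may be applied instead;
the PCA surrogate reproduces the orientation-mode rule's intent at this
pipeline's entry point (voxel time series, no geometry).  The global sign
of a parcel series remains arbitrary, as it must.

Epoch features average each channel over `[KeyDown + t, KeyDown + t + Δt)`
(closed-open in samples; KeyDown maps to the nearest sample at or after
the event).  The canonical window grid is onsets 0:10:100 ms × widths
25:25:350 ms = 154 windows.  (The originating study prints "140 windows"
for the same grids; the stated grids enumerate to 154, so the grids are
implemented as stated and both onset and width vectors are configurable.)
Only keypresses inside correctly typed sequence iterations are retained by
default.

The hybrid space concatenates whole-brain parcel features with regional
voxel features in descending order of regional CV accuracy; a region is
kept only if it improves CV accuracy by at least `saturation_tol`
(default 0.5 percentage points), and the first non-improving region stops
the search.

## Decoding protocol

Per iteration (8 by default): stratified 90/10 train/test split; inner
stratified 8-fold CV on the training part selects classifier settings
from a deterministic grid (replacing Bayesian search for reproducibility);
minority classes are oversampled (duplication with replacement up to the
majority count) inside training folds only — validation and test folds
are never oversampled.  The winner is refit on the full training part and
scored once on the untouched 10%.  Accuracy is averaged over iterations;
confusion matrices are summed.  Stratification is used even though a
plain "randomized split" would suffice at scale, because it guarantees
all classes appear in small test sets.

The supervised manifold is LDA to `n_classes − 1` dimensions, fit on
training folds only and applied unchanged to held-out data; a singular
within-class scatter falls back to shrinkage LDA with a warning.  PCA,
classical (Torgerson) MDS — implemented via the PCA equivalence so that
held-out data can be transformed exactly — and MRMR selection are the
alternative reducers; `none` disables reduction.  Classifier zoo beyond
LDA: Gaussian naive Bayes, KNN (K=4, Euclidean), decision tree (≤4
splits), RBF-kernel SVM, random forest (100 trees).

Metrics: accuracy; per-class F1; support-weighted F1; per-class
false-negative rate (misses / actual) and false-positive rate (false
alarms / predictions) — all derived from the confusion matrix and checked
against an independent reconstruction to 1e-12.  Chance-level checks use
two-sided 99% binomial intervals around 1/n_classes on pooled held-out
prediction counts.

MRMR ranking is greedy MID: relevance = mutual information between the
8-quantile-binned feature and the label; redundancy = mean MI with
already-selected features; deterministic with index-order tie-breaks.
Constant features bin to a single level and receive zero relevance.

## Contextualization

Representation vectors are hybrid-space feature rows of index-finger
presses at OP1/OP5 within completed sequences, optionally projected
through the fitted LDA manifold (both spaces are config switches and both
are exercised in tests; the literature is ambiguous about which space the
distances live in, so neither is privileged).  Distances are Euclidean.

Offline distance for trial t: last OP5 instance of t to first OP1
instance of t+1; the pre-planning control variant targets the OP1 of the
second completed sequence of t+1 and is missing when fewer than two
sequences were completed.  Online distance: mean within-sequence
OP1–OP5 distance (sequence-based) or first-OP1-to-last-OP5 (trial-based).
Cumulative sums run over trials 1..T (offline over the T−1 enclosed
boundaries); missing trials are skipped, not interpolated.

Cumulative offline vs online sums are compared across subjects with a
paired t-test and paired Cohen's d; zero variance of the differences is
reported as an infinite statistic with a warning, never silently clipped.
Correlation with skill gains reports Pearson r and R² alongside a
regression line fit by OLS or by Huber M-estimation (IRLS via
`statsmodels.RLM`).  The two fits coincide exactly when no residual
exceeds the Huber threshold (the outlier-free limit), which is how the
equivalence is tested; with Gaussian noise of any scale a small fraction
of residuals is always downweighted, so exact agreement on unbounded
noise should not be expected.  The robust fit's F statistic is computed
from its residual sum of squares against the constant model.

## Synthetic generator

**Behavior.** Planted per-trial start/end speeds follow the learning
curve, with each trial-to-trial increment split
`micro_offline_share : (1 − micro_offline_share)` between the rest
boundary and the trial interior (default share 1: total early learning
carried by micro-offline jumps, as observed in this paradigm at the group
level).  KTTs are log-normal around the instantaneous 1/speed with
coefficient of variation `ktt_jitter_cv` (positive support, heavy-ish
tail); substitution errors occur at `error_rate` (default 2.32%).
Defaults C1=2.0, C2=1.2, k=0.2 keypresses/s produce session keypress
counts (~1000 presses, index ≈ 2× other fingers) matching the reported
per-class sample sizes of the paradigm; the published curve parameters
(0.5, 0.15, 0.2) are used directly in fit-recovery tests, where the units
are irrelevant.  Target speeds implying KTT < 50 ms are rejected.

**Neural.** White Gaussian noise (σ=4 voxel units) plus, at each
keypress, the finger's spatial pattern added as a boxcar (default 250 ms
from KeyDown; overlapping responses superpose additively).  Patterns are
built from six orthonormal parcel-space directions: four class patterns
(parcel-constant component scaled by `parcel_signal`, plus zero-parcel-
mean voxel components inside designated region parcels scaled by
`regional_signal` — visible to regional voxel decoders but invisible to
parcel averaging) and two contextual directions orthogonal to all class
patterns and to each other.

**Planted contextual divergence** has two components sharing one
increment schedule (uniform increments over `delta_ramp_trials`, then
flat; each trial's increment split `offline_fraction : 1 −
offline_fraction` between the rest break *following* the trial and the
trial interior; `delta_ramp_trials=0` plants a constant, fully
established divergence):

* *separation*: OP1/OP5 index presses displaced ∓δ(t)/2 along one
  direction — the component decoders can exploit; because it is
  orthogonal to all class patterns it cannot inflate 4-class accuracy;
* *drift*: all OP1/OP5 index representations move along the second
  direction by `drift_gain` × the same increments — the component that
  makes the across-rest representation step dominate the within-trial
  step when `offline_fraction > 0.5`.

A single static separation cannot reproduce offline-dominant distance
sums: the online distance measures the *current* separation δ(t) while
the offline distance measures ≈ the boundary-straddling mean, so
cumulative online ≥ cumulative offline for any growing schedule
regardless of where increments are placed.  The drift component supplies
the across-rest representational step that the paradigm's offline
contextualization measure is designed to detect.

Defaults (delta_max=3, drift_gain=6, representation noise 0.35 — the
epoch-averaged equivalent of the voxel noise — between-subject scale SD
0.25, both the divergence magnitude and the planted skill gain multiplied
by the same subject factor) were chosen once so that the planted
offline-dominance effect has the magnitude this literature reports
(paired d ≈ 1.2–1.5, offline-gain correlation r ≈ 0.9).

**Fast path.** `simulate_representation_subject/_cohort` emit OP1/OP5
representation vectors directly (planted coordinates on two axes plus
isotropic Gaussian noise, the exact distribution of epoch-averaged white
sensor noise), at a small fraction of the cost of synthesizing continuous
time series.  Tests assert on full single subjects that pipeline-measured
distance series track the same ground-truth expectations; Monte-Carlo
replication checks (100 cohorts × 20 subjects) run on the fast path.

**What the generator does not emulate:** 1/f and oscillatory background
(available optionally but not default), sensor-array geometry and forward
models, artifacts (blinks, cardiac, movement), inter-regional
correlation structure, reactive-inhibition "scalloping" after the
performance plateau, and error-keypress dynamics beyond uniform random
substitution.  Passing tests therefore certify the *estimators* —
labeling, gain bookkeeping, fitting, CV protocol, distance and
correlation recovery under realistic noise levels — not decoding
accuracies transferable to real recordings.

## Problem sizes and determinism

Desk-scale defaults: 240 voxels in 12 parcels (2 region parcels × 20
voxels), 600 Hz, 36 trials; unit and validation suites use 60–120-voxel
subjects and 6–12-trial sessions, chosen to exercise every code path at
interactive runtimes.  Validation statistics use 20-subject cohorts with
100 replicates for the replication-rate estimate.  All randomness flows
through integer seeds (`numpy.random.default_rng` /
`SeedSequence.spawn` for cohorts); identical seed + config + data
reproduce results bit-for-bit, which the tests assert.

## Known limitations

* The ordinal tie rule is untestable on the default sequence (shifts all
  distinct); periodic sequences would exercise it.
* `optimize_window` refits features per window; for large grids on long
  recordings, precomputing cumulative sums would be faster.
* The robust-regression F statistic is a pseudo-F (RSS-based), not a
  sandwich-variance Wald test.
* Day-2 retest/control sessions are representable (any labeled event
  stream with its own sequence), but no dedicated session-transfer
  machinery is provided.
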