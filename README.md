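# skillcontext

Analysis pipeline for early motor-skill learning in sequential keypress
tasks: behavioral skill metrics, multi-scale ("hybrid-space") neural
decoding of keypresses from source-localized MEG-style activity, and
quantification of how the neural representation of the *same* action
differentiates with its sequence context ("contextualization").

## The scientific problem

In a classic skill-learning paradigm, participants repeatedly type a
5-item sequence (e.g. **4**-1-3-2-**4**, fingers of the non-dominant hand)
over 36 trials of 10 s practice alternating with 10 s rest.  Three
questions structure the analysis:

1. **Behavior.** Skill is the *correct sequence typing speed*: keypresses
   are marked correct when they belong to a 5-press window matching any
   circular shift of the target sequence, and the instantaneous speed is
   the inverse mean of the 4 keypress transition times (KTTs) of a correct
   iteration, in keypresses/s.  Early learning follows
   `L(t) = C1 + C2 (1 − e^{−kt})`; the early-learning cutoff `T` is the
   first trial reaching 95% of the fitted gain, `T = ⌈−ln(0.05)/k⌉`.
   Skill changes decompose into **micro-online** gains (within a practice
   trial) and **micro-offline** gains (across a rest break).
2. **Decoding.** Source-space voxel activity is band-filtered (zero-phase
   4th-order Butterworth), collapsed to parcels with sign-flip averaging,
   and averaged in KeyDown-locked windows `[t, t+Δt)`.  A *hybrid* feature
   space concatenates whole-brain parcel features with voxel features from
   top-ranked regions, grown greedily until cross-validated accuracy
   saturates.  Decoders (supervised LDA manifold to `n_classes − 1`
   dimensions + linear discriminant, with pluggable alternatives) are
   evaluated by stratified 90/10 splits over 8 iterations with inner
   8-fold CV for model selection; minority classes are oversampled inside
   training folds only.
3. **Contextualization.** The index finger occurs at ordinal positions 1
   and 5 of the sequence (Index_OP1, Index_OP5).  The Euclidean distance
   between their neural representations is tracked per trial: *online*
   (within a practice trial) and *offline* (last OP5 of a trial to first
   OP1 of the next, across the rest break).  Cumulative offline vs online
   distances are compared by paired t-test, and offline distances are
   related to micro-offline skill gains by Pearson correlation and robust
   (Huber IRLS) regression.

A fully ground-truthed synthetic generator (`skillcontext.synthetic`)
emulates these study conditions — exponential speed-up with micro-offline
jumps, ~2.3% keypress errors, evoked class-specific spatial patterns, and
a planted, offline-weighted contextual divergence schedule — so that every
stage of the pipeline is testable without any external data.

## Worked example

```python
import numpy as np
from skillcontext import behavior as bh
from skillcontext import synthetic as syn

# one synthetic participant: 36 trials, 10 s practice / 10 s rest
params = syn.BehaviorParams(seed=1)
events, truth = syn.generate_behavior(params)
labeled = bh.label_correct(events)
series = bh.instantaneous_speed(labeled)
speeds = bh.trial_speed(series, params.n_trials)
fit = bh.fit_learning_curve(speeds)
print(f"C1={fit.C1:.3f}  C2={fit.C2:.3f}  k={fit.k:.3f}")
print("early-learning cutoff T =", bh.early_cutoff(fit, 0.95))
gains = bh.micro_gains(series, params.schedule, T=11)
print(f"cumulative micro-offline gain = {gains.cumulative_offline:.2f} kp/s")
print("minimum sample size (d=0.8115) =", bh.min_sample_size(0.8115))
```

Output:

```
C1=2.014  C2=1.166  k=0.228
early-learning cutoff T = 14
cumulative micro-offline gain = 1.23 kp/s
minimum sample size (d=0.8115) = 22
```

The fitted curve recovers the planted parameters (C1=2.0, C2=1.2, k=0.2)
up to single-subject measurement noise; the cumulative micro-offline gain
approximates the planted rest-boundary jumps; and the power calculation
reproduces the exact minimum n for a two-sided one-sample t-test at
α=0.05, power 0.95, d=0.8115.

A command-line interface drives the full pipeline:

```bash
skillcontext simulate --out data/ --subjects 1 --seed 3
skillcontext run --events data/sub-01/events.tsv --neural data/sub-01/neural.h5 \
    --out results/sub-01
```

writing `behavior.csv`, `decode.json`, `context.csv` and `report.json`.

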