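"""Ground-truthed synthetic cohorts: behavior and source-space neural data.

The generator emulates the study conditions of a sequential keypress
skill-learning session: repetitive typing of a 5-item sequence (default
4-1-3-2-4) over 36 trials of 10 s practice alternating with 10 s rest,
exponential speed-up ``L(t) = C1 + C2 (1 - e^{-kt})`` with the skill gain
placed predominantly across rest boundaries (micro-offline jumps), a small
keypress substitution error rate, and source-space voxel time series with
evoked class-specific spatial patterns at each keypress.

Contextual divergence of the index finger at ordinal positions 1 vs 5 is
planted with two components sharing one increment schedule, both along
directions orthogonal to the four class patterns:

* a symmetric *separation*: OP1 and OP5 instances are displaced by
  -/+ delta(t)/2 along one contextual direction, which is what the 2-class
  and 5-class decoders can exploit;
* a common *drift*: all index-keypress representations move along a second
  orthogonal direction by ``drift_gain`` times the same increments, so the
  representation step measured across a rest break reflects where in time
  the increments were placed.

Each trial's increment is split by ``offline_fraction`` between the trial
itself and the rest break that follows it, so the generator controls
whether representational change accrues online (during practice) or
offline (consolidating over rest).  Every generated dataset
is accompanied by a ground-truth ledger sufficient to compute the expected
value of each downstream statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import SEQUENCE, TrialSchedule, label_correct, sequence_iterations
from .contextualization import RepresentationSet
from .features import FeatureMatrix, SourceTimeSeries

__all__ = [
    "BehaviorParams",
    "NeuralParams",
    "generate_behavior",
    "generate_neural",
    "generate_subject",
    "generate_cohort",
    "simulate_representation_subject",
    "simulate_representation_cohort",
    "expected_context_series",
    "noise_feature_matrix",
    "gaussian_class_matrix",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioral generating parameters.

    Speeds are in keypresses/s.  The learning-curve defaults are chosen so
    that a session produces keypress counts comparable to the study's
    reported per-class totals (~1000 keypresses, ~2x index presses); the
    share of the planted gain placed across rest boundaries defaults to 1
    (total early learning accounted for by micro-offline gains).
    """

    sequence: tuple = SEQUENCE
    n_trials: int = 36
    practice_dur: float = 10.0
    rest_dur: float = 10.0
    C1: float = 2.0
    C2: float = 1.2
    k: float = 0.2
    micro_offline_share: float = 1.0
    error_rate: float = 0.0232
    ktt_jitter_cv: float = 0.1
    seed: int = 0

    @property
    def schedule(self) -> TrialSchedule:
        return TrialSchedule(self.n_trials, self.practice_dur, self.rest_dur)


@dataclass(frozen=True)
class NeuralParams:
    """Neural generating parameters (desk-scale defaults).

    240 voxels in 12 equal parcels at 600 Hz keep a full subject cheap while
    preserving the parcel/voxel/hybrid structure.  Class patterns have a
    parcel-constant component (visible after parcel averaging, scaled by
    ``parcel_signal``) and, within the designated region parcels, a
    zero-parcel-mean voxel component (``regional_signal``) that only the
    regional voxel space can see.
    """

    n_voxels: int = 240
    n_parcels: int = 12
    region_parcels: tuple = (0, 1)
    srate: float = 600.0
    evoked_amplitude: float = 1.0
    evoked_latency: float = 0.0
    evoked_duration: float = 0.25
    parcel_signal: float = 1.0
    regional_signal: float = 1.0
    noise_sigma: float = 4.0
    delta_max: float = 3.0
    delta_ramp_trials: int = 11
    offline_fraction: float = 0.9
    drift_gain: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.offline_fraction <= 1.0:
            raise ValueError("offline_fraction must be in [0, 1]")
        if self.n_voxels % self.n_parcels:
            raise ValueError("n_voxels must divide evenly into parcels")


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def _learning_curve(p: BehaviorParams, t: np.ndarray) -> np.ndarray:
    return p.C1 + p.C2 * (1.0 - np.exp(-p.k * np.asarray(t, dtype=float)))


def planted_speeds(p: BehaviorParams) -> tuple[np.ndarray, np.ndarray]:
    """Planted (start, end) speed per trial under the offline/online split."""
    L = _learning_curve(p, np.arange(1, p.n_trials + 2))
    inc = np.diff(L)  # gain accrued around trial t
    f = p.micro_offline_share
    v_start = np.empty(p.n_trials)
    v_end = np.empty(p.n_trials)
    v_start[0] = L[0]
    for t in range(p.n_trials):
        if t > 0:
            v_start[t] = v_end[t - 1] + f * inc[t - 1]
        v_end[t] = v_start[t] + (1.0 - f) * inc[t]
    return v_start, v_end


def generate_behavior(p: BehaviorParams) -> tuple[pd.DataFrame, dict]:
    """Generate a keypress event stream plus its ground-truth ledger.

    Within each practice trial the target speed ramps linearly from the
    planted start to end value; keypress transition times are drawn from a
    log-normal around the instantaneous 1/speed with coefficient of
    variation ``ktt_jitter_cv``; each press is replaced by a random wrong
    key with probability ``error_rate``.
    """
    v_start, v_end = planted_speeds(p)
    if (1.0 / max(v_start.max(), v_end.max())) < 0.05:
        raise ValueError("planted speed implies KTT < 50 ms; unrealistic parameters")
    rng = np.random.default_rng(p.seed)
    keys_canon = list(p.sequence)
    wrong = {k: [x for x in (1, 2, 3, 4) if x != k] for k in (1, 2, 3, 4)}
    onsets, keys, trials = [], [], []
    n_errors = 0
    cv = p.ktt_jitter_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    for t in range(p.n_trials):
        t0 = p.schedule.practice_onsets[t]
        tau = 0.0
        pos = 0
        while True:
            frac = min(tau / p.practice_dur, 1.0)
            v = v_start[t] + (v_end[t] - v_start[t]) * frac
            mean_ktt = 1.0 / v
            if sigma > 0:
                ktt = float(rng.lognormal(math.log(mean_ktt) - 0.5 * sigma * sigma, sigma))
            else:
                ktt = mean_ktt
            tau += ktt
            if tau >= p.practice_dur:
                break
            key = keys_canon[pos % len(keys_canon)]
            if p.error_rate > 0 and rng.random() < p.error_rate:
                key = int(rng.choice(wrong[key]))
                n_errors += 1
            onsets.append(t0 + tau)
            keys.append(int(key))
            trials.append(t + 1)
            pos += 1
    events = pd.DataFrame({"onset": onsets, "key": keys, "trial": trials})
    inc_online = v_end - v_start
    inc_offline = v_start[1:] - v_end[:-1]
    gt = {
        "params": p,
        "v_start": v_start,
        "v_end": v_end,
        "planted_online": inc_online,
        "planted_offline": inc_offline,
        "planted_cumulative_online": float(inc_online.sum()),
        "planted_cumulative_offline": float(inc_offline.sum()),
        "n_errors": n_errors,
        "n_events": len(events),
    }
    return events, gt


# ---------------------------------------------------------------------------
# contextual divergence schedule
# ---------------------------------------------------------------------------


def _delta_bounds(n_trials: int, delta_max: float, ramp_trials: int, f: float):
    """Per-trial (start, end) values of the separation coordinate delta.

    Increments are uniform over the ramp trials and zero afterwards; the
    increment earned in trial t is split (1 - f) : f between the trial
    itself (online) and the rest break that follows it (offline
    consolidation), so the full delta_max is always realized by the end of
    the ramp.
    """
    if ramp_trials == 0:  # divergence fully established before trial 1
        const = np.full(n_trials, delta_max)
        return const, const.copy()
    inc = np.zeros(n_trials)
    inc[: min(ramp_trials, n_trials)] = delta_max / ramp_trials
    start = np.empty(n_trials)
    end = np.empty(n_trials)
    start[0] = 0.0
    for t in range(n_trials):
        end[t] = start[t] + (1.0 - f) * inc[t]
        if t + 1 < n_trials:
            start[t + 1] = end[t] + f * inc[t]
    return start, end


def _context_coeffs(meta: pd.DataFrame, n_trials: int, practice_dur: float,
                    practice_onsets: np.ndarray, np_: NeuralParams) -> pd.DataFrame:
    """Per-event separation and drift coefficients from the planted schedule."""
    d_start, d_end = _delta_bounds(n_trials, np_.delta_max, np_.delta_ramp_trials,
                                   np_.offline_fraction)
    g_start = d_start * np_.drift_gain
    g_end = d_end * np_.drift_gain
    trial = meta["trial"].to_numpy().astype(int)
    onset = meta["onset"].to_numpy(dtype=float)
    frac = np.clip((onset - practice_onsets[trial - 1]) / practice_dur, 0.0, 1.0)
    delta = d_start[trial - 1] + (d_end[trial - 1] - d_start[trial - 1]) * frac
    drift = g_start[trial - 1] + (g_end[trial - 1] - g_start[trial - 1]) * frac
    op = meta["ordinal_position"].to_numpy(dtype=float)
    sign = np.where(op == 5.0, 0.5, np.where(op == 1.0, -0.5, 0.0))
    is_index = meta["key"].to_numpy() == 4
    out = meta[["trial", "onset"]].copy()
    out["delta_coeff"] = np.where(is_index, sign * delta, 0.0)
    out["drift_coeff"] = np.where(is_index & (sign != 0.0), drift, 0.0)
    return out


def expected_context_series(coeffs: pd.DataFrame, meta: pd.DataFrame, n_trials: int,
                            amplitude: float = 1.0) -> pd.DataFrame:
    """Noise-free expected online/offline distance series from the ledger.

    Uses the same instance-selection rules as the analysis (last OP5 to next
    first OP1 for offline; within-sequence pairs for online) applied to the
    planted coefficients, so every measured distance has a stated
    expectation.
    """
    from .contextualization import contextualization_series

    sel = (
        (meta["key"].to_numpy() == 4)
        & np.isin(meta["ordinal_position"].to_numpy(dtype=float), [1.0, 5.0])
        & np.isfinite(meta["sequence_index"].to_numpy(dtype=float))
    )
    coords = amplitude * np.column_stack(
        [coeffs["delta_coeff"].to_numpy()[sel], coeffs["drift_coeff"].to_numpy()[sel]]
    )
    reps = RepresentationSet(coords=coords, meta=meta[sel].reset_index(drop=True))
    series = contextualization_series(reps, n_trials)
    return series.rename(columns={"online_seq": "online"})[["trial", "online", "offline"]]


# ---------------------------------------------------------------------------
# neural time series
# ---------------------------------------------------------------------------


def _build_patterns(np_: NeuralParams, rng: np.random.Generator) -> dict:
    """Class patterns and contextual directions in voxel space.

    Six orthonormal parcel-space directions (QR of a random matrix) provide
    the parcel-constant components: four class patterns plus the separation
    and drift directions.  Regional voxel components are zero-mean within
    their parcel so parcel averaging cannot see them.
    """
    P, V = np_.n_parcels, np_.n_voxels
    vpp = V // P
    parcel_map = np.repeat(np.arange(P), vpp)
    if P < 6:
        raise ValueError("need at least 6 parcels for orthogonal pattern construction")
    q, _ = np.linalg.qr(rng.standard_normal((P, 6)))
    vox = q.T[:, parcel_map] / math.sqrt(vpp)  # rows unit-norm in voxel space
    class_patterns = {}
    for i, key in enumerate((1, 2, 3, 4)):
        pat = np_.parcel_signal * vox[i].copy()
        for rp in np_.region_parcels:
            sel = parcel_map == rp
            comp = rng.standard_normal(vpp)
            comp -= comp.mean()
            comp /= np.linalg.norm(comp)
            pat[sel] += np_.regional_signal * comp
        class_patterns[key] = pat
    return {
        "parcel_map": parcel_map,
        "class_patterns": class_patterns,
        "c_sep": vox[4],
        "c_drift": vox[5],
    }


def generate_neural(labeled: pd.DataFrame, np_: NeuralParams,
                    schedule: TrialSchedule) -> tuple[SourceTimeSeries, dict]:
    """Voxels x samples series with planted evoked patterns and divergence.

    White Gaussian noise everywhere; at each keypress the finger's spatial
    pattern (plus, for index presses at OP1/OP5, the contextual perturbation)
    is added as a boxcar over the evoked window.  Overlapping evoked windows
    superpose additively.
    """
    needed = {"onset", "key", "trial", "ordinal_position", "sequence_index"}
    if not needed <= set(labeled.columns):
        raise ValueError("events must be labeled and sequence-tagged")
    rng = np.random.default_rng(np_.seed)
    pats = _build_patterns(np_, rng)
    total_dur = schedule.n_trials * (schedule.practice_dur + schedule.rest_dur)
    n_samples = int(round(total_dur * np_.srate))
    data = np_.noise_sigma * rng.standard_normal(
        (np_.n_voxels, n_samples), dtype=np.float32
    )
    coeffs = _context_coeffs(labeled, schedule.n_trials, schedule.practice_dur,
                             schedule.practice_onsets, np_)
    lat = int(round(np_.evoked_latency * np_.srate))
    dur = int(round(np_.evoked_duration * np_.srate))
    onset_samp = np.ceil(labeled["onset"].to_numpy() * np_.srate - 1e-9).astype(int)
    keys = labeled["key"].to_numpy().astype(int)
    dc = coeffs["delta_coeff"].to_numpy()
    gc = coeffs["drift_coeff"].to_numpy()
    a = np_.evoked_amplitude
    for i in range(len(labeled)):
        s0 = onset_samp[i] + lat
        s1 = min(s0 + dur, n_samples)
        if s0 >= n_samples:
            continue
        wave = pats["class_patterns"][keys[i]].copy()
        if dc[i] != 0.0 or gc[i] != 0.0:
            wave = wave + dc[i] * pats["c_sep"] + gc[i] * pats["c_drift"]
        data[:, s0:s1] += (a * wave[:, None]).astype(np.float32)
    ts = SourceTimeSeries(
        data,
        srate=np_.srate,
        parcel_map=pats["parcel_map"],
        region_labels=[f"parcel{i}" for i in range(np_.n_parcels)],
    )
    gt = {
        "params": np_,
        "class_patterns": pats["class_patterns"],
        "c_sep": pats["c_sep"],
        "c_drift": pats["c_drift"],
        "coeffs": coeffs,
        "expected_series": expected_context_series(
            coeffs, labeled, schedule.n_trials, amplitude=a
        ),
    }
    return ts, gt


def generate_subject(bparams: BehaviorParams, nparams: NeuralParams) -> dict:
    """Full synthetic subject: labeled events, neural series, ground truth."""
    events, bgt = generate_behavior(bparams)
    labeled = sequence_iterations(label_correct(events, bparams.sequence))
    ts, ngt = generate_neural(labeled, nparams, bparams.schedule)
    return {"events": labeled, "ts": ts, "behavior_truth": bgt, "neural_truth": ngt}


def generate_cohort(
    n_subjects: int,
    bparams: BehaviorParams = BehaviorParams(),
    nparams: NeuralParams = NeuralParams(),
    master_seed: int = 0,
    subject_scale_sd: float = 0.25,
    couple_gains: bool = True,
) -> list[dict]:
    """Cohort with deterministic per-subject seeds and coupled effect sizes.

    Each subject draws a positive scale factor; when ``couple_gains`` is set
    it multiplies both the learning-curve gain C2 (hence the planted
    micro-offline gains) and the contextual divergence magnitude, planting a
    between-subject association between skill gains and contextualization.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_subjects)]
    rng = np.random.default_rng(seeds[-1])
    out = []
    for i in range(n_subjects):
        scale = float(np.clip(1.0 + subject_scale_sd * rng.standard_normal(), 0.3, None)) \
            if subject_scale_sd > 0 else 1.0
        bp = replace(bparams, seed=seeds[2 * i], C2=bparams.C2 * (scale if couple_gains else 1.0))
        np2 = replace(nparams, seed=seeds[2 * i + 1],
                      delta_max=nparams.delta_max * (scale if couple_gains else 1.0))
        subj = generate_subject(bp, np2)
        subj["scale"] = scale
        out.append(subj)
    return out


# ---------------------------------------------------------------------------
# representation-level fast path
# ---------------------------------------------------------------------------


def simulate_representation_subject(
    nparams: NeuralParams = NeuralParams(),
    n_trials: int = 36,
    seqs_per_trial: int = 6,
    dim: int = 8,
    rep_noise: float = 0.35,
    seed: int = 0,
    scale: float = 1.0,
    practice_dur: float = 10.0,
    rest_dur: float = 10.0,
) -> tuple[RepresentationSet, dict]:
    """Event-level shortcut of the same generative model.

    Emits Index_OP1/Index_OP5 representation vectors directly in a D-dim
    feature space: the planted separation and drift coordinates live on the
    first two axes and isotropic Gaussian noise models the epoch-averaged
    sensor noise.  Statistically equivalent to running the full
    events -> time series -> epoch pipeline, at a fraction of the cost; the
    equivalence is asserted by tests on full single subjects.
    """
    rng = np.random.default_rng(seed)
    np2 = replace(nparams, delta_max=nparams.delta_max * scale)
    period = practice_dur + rest_dur
    seq_dur = practice_dur / (seqs_per_trial + 0.5)
    rows = []
    for tr in range(1, n_trials + 1):
        t0 = (tr - 1) * period
        for si in range(1, seqs_per_trial + 1):
            s_on = t0 + (si - 1) * seq_dur
            rows.append(dict(onset=s_on, key=4, trial=tr, is_correct=True,
                             ordinal_position=1.0, sequence_index=float(si)))
            rows.append(dict(onset=s_on + 0.8 * seq_dur, key=4, trial=tr,
                             is_correct=True, ordinal_position=5.0,
                             sequence_index=float(si)))
    meta = pd.DataFrame(rows)
    sched_onsets = np.arange(n_trials) * period
    coeffs = _context_coeffs(meta, n_trials, practice_dur, sched_onsets, np2)
    coords = rep_noise * rng.standard_normal((len(meta), dim))
    coords[:, 0] += nparams.evoked_amplitude * coeffs["delta_coeff"].to_numpy()
    coords[:, 1] += nparams.evoked_amplitude * coeffs["drift_coeff"].to_numpy()
    gt = {
        "params": np2,
        "coeffs": coeffs,
        "expected_series": expected_context_series(
            coeffs, meta, n_trials, amplitude=nparams.evoked_amplitude
        ),
        "scale": scale,
    }
    return RepresentationSet(coords=coords, meta=meta), gt


def simulate_representation_cohort(
    n_subjects: int = 20,
    nparams: NeuralParams = NeuralParams(),
    bparams: BehaviorParams = BehaviorParams(),
    n_trials: int = 36,
    master_seed: int = 0,
    subject_scale_sd: float = 0.25,
    rep_noise: float = 0.35,
    **kwargs,
) -> list[dict]:
    """Cohort of representation-level subjects with coupled planted gains.

    Each subject's scale factor multiplies both the contextual divergence
    and the planted cumulative micro-offline skill gain recorded in its
    ground truth, so between-subject recovery of the gain-contextualization
    association can be tested.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects + 1)]
    rng = np.random.default_rng(seeds[-1])
    base_gain = bparams.micro_offline_share * bparams.C2 * (
        1.0 - math.exp(-bparams.k * nparams.delta_ramp_trials)
    )
    out = []
    for i in range(n_subjects):
        scale = float(np.clip(1.0 + subject_scale_sd * rng.standard_normal(), 0.3, None)) \
            if subject_scale_sd > 0 else 1.0
        reps, gt = simulate_representation_subject(
            nparams, n_trials=n_trials, rep_noise=rep_noise,
            seed=seeds[i], scale=scale, **kwargs,
        )
        gt["planted_micro_offline_gain"] = base_gain * scale
        out.append({"reps": reps, "truth": gt, "scale": scale})
    return out


# ---------------------------------------------------------------------------
# plain feature-matrix fixtures
# ---------------------------------------------------------------------------


def noise_feature_matrix(n_samples: int, n_features: int, n_classes: int,
                         seed: int = 0) -> FeatureMatrix:
    """Pure-noise features with balanced class labels (chance-level fixture)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_features))
    y = np.arange(n_samples) % n_classes + 1
    rng.shuffle(y)
    meta = pd.DataFrame({"trial": np.ones(n_samples, dtype=int),
                         "onset": np.arange(n_samples, dtype=float)})
    return FeatureMatrix(X=X, y=y, feature_names=[f"f{i}" for i in range(n_features)],
                         meta=meta, space="synthetic")


def gaussian_class_matrix(n_per_class: int, n_features: int, n_classes: int,
                          separation: float, seed: int = 0) -> FeatureMatrix:
    """Gaussian class clusters with mean separation ``separation``."""
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((n_classes, n_features))
    means *= separation / np.linalg.norm(means, axis=1, keepdims=True)
    X = np.vstack([means[c] + rng.standard_normal((n_per_class, n_features))
                   for c in range(n_classes)])
    y = np.repeat(np.arange(n_classes) + 1, n_per_class)
    perm = rng.permutation(len(y))
    X, y = X[perm], y[perm]
    meta = pd.DataFrame({"trial": np.ones(len(y), dtype=int),
                         "onset": np.arange(len(y), dtype=float)})
    return FeatureMatrix(X=X, y=y, feature_names=[f"f{i}" for i in range(n_features)],
                         meta=meta, space="synthetic")
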