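"""Behavioral analysis of keypress event streams.

The skill measure throughout is the *correct sequence typing speed* in
keypresses per second: the inverse of the mean keypress transition time (KTT)
across one correctly typed 5-item sequence iteration.  From a labeled event
stream this module derives instantaneous and per-trial speeds, micro-online /
micro-offline gains across practice and rest intervals, an exponential
learning-curve fit, the early-learning cutoff trial, and the study-design
power calculation.

Events are held in a pandas DataFrame with columns ``onset`` (seconds),
``key`` (1-4), ``trial`` (1-based), plus ``is_correct`` and
``ordinal_position`` once labeled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TrialSchedule",
    "MicroGains",
    "LearningCurveFit",
    "label_correct",
    "instantaneous_speed",
    "trial_speed",
    "micro_gains",
    "fit_learning_curve",
    "early_cutoff",
    "min_sample_size",
    "ktt_profile",
    "sequence_iterations",
]

EVENT_COLUMNS = ("onset", "key", "trial")

SEQUENCE = (4, 1, 3, 2, 4)  # trained sequence; index finger at OP1 and OP5


@dataclass(frozen=True)
class TrialSchedule:
    """Alternating practice/rest layout of a training session."""

    n_trials: int = 36
    practice_dur: float = 10.0
    rest_dur: float = 10.0

    @property
    def practice_onsets(self) -> np.ndarray:
        period = self.practice_dur + self.rest_dur
        return np.arange(self.n_trials) * period

    def trial_of(self, t: np.ndarray) -> np.ndarray:
        """1-based practice trial containing each time, -1 if in a rest gap."""
        t = np.asarray(t, dtype=float)
        period = self.practice_dur + self.rest_dur
        idx = np.floor(t / period).astype(int)
        within = t - idx * period
        ok = (idx >= 0) & (idx < self.n_trials) & (within <= self.practice_dur)
        return np.where(ok, idx + 1, -1)


@dataclass
class MicroGains:
    """Per-boundary skill changes and their cumulative sums (keypresses/s)."""

    online: np.ndarray
    offline: np.ndarray
    cumulative_online: float
    cumulative_offline: float
    total_early_learning: float
    skip_first_k: int = 0
    n_missing: int = 0


@dataclass
class LearningCurveFit:
    """Exponential fit L(t) = C1 + C2 (1 - exp(-k t)) to group trial speeds."""

    C1: float
    C2: float
    k: float
    rmse: float
    r_squared: float
    n_trials: int = 0
    T: int | None = None

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.C1 + self.C2 * (1.0 - np.exp(-self.k * t))


def _circular_shifts(sequence: tuple[int, ...]) -> list[tuple[int, ...]]:
    n = len(sequence)
    return [tuple(sequence[(s + i) % n] for i in range(n)) for s in range(n)]


def label_correct(events: pd.DataFrame, sequence=SEQUENCE) -> pd.DataFrame:
    """Mark keypresses correct and assign ordinal positions.

    A keypress is correct iff it lies in at least one run of 5 consecutive
    keypresses (within one trial) matching any circular shift of ``sequence``.
    Ordinal positions (1..5, position within the canonical un-shifted
    sequence) are assigned from the earliest-starting matching window that
    contains the keypress.
    """
    sequence = tuple(int(k) for k in sequence)
    if len(sequence) != 5:
        raise ValueError(f"sequence must have 5 items, got {len(sequence)}")
    if not set(sequence) <= {1, 2, 3, 4}:
        raise ValueError("sequence items must be in {1, 2, 3, 4}")

    out = events.copy()
    out["is_correct"] = False
    out["ordinal_position"] = np.nan
    if len(out) == 0:
        return out

    shifts = _circular_shifts(sequence)
    n = len(sequence)
    keys = out["key"].to_numpy()
    trials = out["trial"].to_numpy()
    correct = np.zeros(len(out), dtype=bool)
    ordinal = np.full(len(out), np.nan)

    # windows never span trial boundaries; scan each trial independently
    for tr in np.unique(trials):
        idx = np.flatnonzero(trials == tr)
        k = keys[idx]
        for start in range(len(k) - n + 1):
            window = tuple(int(x) for x in k[start : start + n])
            for s, shifted in enumerate(shifts):
                if window == shifted:
                    sel = idx[start : start + n]
                    correct[sel] = True
                    for i, j in enumerate(sel):
                        if np.isnan(ordinal[j]):  # earliest window wins
                            ordinal[j] = (s + i) % n + 1
                    break  # shifts are checked in shift order; first match
    out["is_correct"] = correct
    out["ordinal_position"] = ordinal
    return out


def instantaneous_speed(events: pd.DataFrame, sequence=SEQUENCE) -> pd.DataFrame:
    """Instantaneous correct-sequence speed, one sample per completed window.

    Each 5-press window matching a circular shift of the sequence yields one
    speed sample 1/mean(4 KTTs), attached to the time and trial of the
    keypress completing the window, together with the within-trial index of
    the window start (used by the pre-planning control).

    Returns a DataFrame with columns ``time``, ``trial``, ``speed``,
    ``window_start`` (0-based index of the window's first press within its
    trial).
    """
    sequence = tuple(int(k) for k in sequence)
    shifts = set(_circular_shifts(sequence))
    n = len(sequence)
    rows = []
    for tr, g in events.groupby("trial", sort=True):
        k = tuple(int(x) for x in g["key"].to_numpy())
        t = g["onset"].to_numpy()
        for start in range(len(k) - n + 1):
            if k[start : start + n] in shifts:
                ktts = np.diff(t[start : start + n])
                rows.append(
                    dict(
                        time=t[start + n - 1],
                        trial=int(tr),
                        speed=1.0 / float(np.mean(ktts)),
                        window_start=start,
                    )
                )
    return pd.DataFrame(rows, columns=["time", "trial", "speed", "window_start"])


def trial_speed(series: pd.DataFrame, n_trials: int | None = None) -> pd.Series:
    """Per-trial median of instantaneous speeds; NaN where a trial has none."""
    if n_trials is None:
        n_trials = int(series["trial"].max()) if len(series) else 0
    med = series.groupby("trial")["speed"].median()
    return med.reindex(range(1, n_trials + 1))


def micro_gains(
    series: pd.DataFrame,
    schedule: TrialSchedule,
    T: int | None = None,
    skip_first_k: int = 0,
) -> MicroGains:
    """Micro-online and micro-offline gains from the instantaneous series.

    online[n] = last speed of trial n minus first speed of trial n;
    offline[n] = first speed of trial n+1 minus last speed of trial n.
    Cumulative sums run over trials 1..T (offline over boundaries 1..T-1),
    so that cumulative_online + cumulative_offline telescopes to the first-
    to-last speed difference when no trial is missing.

    With ``skip_first_k`` > 0 speed samples from windows containing any of
    the first k keypresses of a trial are excluded (pre-planning control).
    """
    if T is None:
        T = schedule.n_trials
    s = series
    if skip_first_k > 0:
        s = s[s["window_start"] >= skip_first_k]
    first = np.full(T, np.nan)
    last = np.full(T, np.nan)
    for tr, g in s.groupby("trial"):
        if 1 <= tr <= T:
            g = g.sort_values("time")
            first[tr - 1] = g["speed"].iloc[0]
            last[tr - 1] = g["speed"].iloc[-1]
    online = last - first
    offline = first[1:] - last[:-1]
    n_missing = int(np.isnan(online).sum() + np.isnan(offline).sum())
    if n_missing:
        warnings.warn(f"{n_missing} micro-gain entries missing (no correct sequence)")
    cum_on = float(np.nansum(online)) if np.isfinite(online).any() else np.nan
    cum_off = float(np.nansum(offline)) if np.isfinite(offline).any() else np.nan
    return MicroGains(
        online=online,
        offline=offline,
        cumulative_online=cum_on,
        cumulative_offline=cum_off,
        total_early_learning=cum_on + cum_off,
        skip_first_k=skip_first_k,
        n_missing=n_missing,
    )


def _exp_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    c1, c2, k = params
    return c1 + c2 * (1.0 - np.exp(-k * t))


def fit_learning_curve(
    trial_speeds: np.ndarray | pd.Series,
    n_starts: int = 5,
    seed: int = 0,
) -> LearningCurveFit:
    """Fit L(t) = C1 + C2 (1 - e^{-kt}) to group-average trial speeds.

    Constrained trust-region least squares (C2 >= 0, k > 0) with multi-start
    to guard against local minima.  Trials are numbered 1..n.
    """
    y = np.asarray(trial_speeds, dtype=float)
    mask = np.isfinite(y)
    t = np.arange(1, len(y) + 1, dtype=float)[mask]
    y = y[mask]
    if len(y) < 5:
        raise ValueError("need at least 5 finite trial speeds to fit")

    k_lo = 1e-6
    lo = np.array([-np.inf, 0.0, k_lo])
    hi = np.array([np.inf, np.inf, 10.0])
    span = max(y.max() - y.min(), 1e-12)
    rng = np.random.default_rng(seed)
    starts = [np.array([y[0], span, 0.2])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    y[0] * rng.uniform(0.5, 1.5),
                    span * rng.uniform(0.2, 2.0),
                    10 ** rng.uniform(-2, 0.5),
                ]
            )
        )
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(
                lambda p: _exp_model(p, t) - y, x0, bounds=(lo, hi), method="trf"
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError(f"learning-curve fit failed: {best.message if best else 'no start converged'}")
    c1, c2, k = best.x
    if k <= 2 * k_lo:
        warnings.warn("learning rate k at lower bound; data may be non-increasing")
    resid = _exp_model(best.x, t) - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return LearningCurveFit(
        C1=float(c1), C2=float(c2), k=float(k), rmse=rmse, r_squared=r2, n_trials=len(t)
    )


def early_cutoff(fit: LearningCurveFit, fraction: float = 0.95) -> int:
    """First trial at which the given fraction of total learning is reached.

    (L(t) - C1) / C2 >= fraction  <=>  t >= -ln(1 - fraction) / k, so the
    cutoff is the ceiling of the closed-form crossing point.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if fit.C2 <= 0:
        raise ValueError("cutoff undefined for C2 <= 0 (no learning)")
    if fit.k <= 0:
        raise ValueError("cutoff undefined for k <= 0")
    t_star = -math.log(1.0 - fraction) / fit.k
    return max(1, math.ceil(t_star))


def _t_test_power(n: int, d: float, alpha: float) -> float:
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * math.sqrt(n)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def min_sample_size(d: float, alpha: float = 0.05, power: float = 0.95) -> int:
    """Smallest n for a two-sided one-sample t-test to reach the target power.

    Exact noncentral-t computation: the test statistic under the alternative
    is noncentral t with noncentrality d*sqrt(n) and df n-1; n is incremented
    from the floor n=2 until the attained power crosses the target.
    """
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    n = 2
    while _t_test_power(n, d, alpha) < power:
        n += 1
        if n > 10_000_000:  # pragma: no cover
            raise RuntimeError("sample-size search did not terminate")
    return n


def ktt_profile(labeled: pd.DataFrame, sequence=SEQUENCE) -> pd.DataFrame:
    """Normalized KTT distribution per sequence transition.

    Each KTT between consecutive correct keypresses at adjacent ordinal
    positions (including the wrap 5 -> 1 across sequence iterations) is
    divided by the participant's median correct-sequence duration.  Returns a
    long DataFrame with columns ``transition`` (e.g. "4-1"), ``trial``,
    ``normalized_ktt``.
    """
    sequence = tuple(int(k) for k in sequence)
    series = instantaneous_speed(labeled, sequence)
    if len(series) == 0:
        return pd.DataFrame(columns=["transition", "trial", "normalized_ktt"])
    median_seq_time = float(np.median(4.0 / series["speed"].to_numpy()))

    rows = []
    for tr, g in labeled.groupby("trial", sort=True):
        t = g["onset"].to_numpy()
        op = g["ordinal_position"].to_numpy()
        ok = g["is_correct"].to_numpy()
        key = g["key"].to_numpy()
        for i in range(len(g) - 1):
            if not (ok[i] and ok[i + 1]):
                continue
            p, q = op[i], op[i + 1]
            if np.isnan(p) or np.isnan(q):
                continue
            if int(q) != int(p) % 5 + 1:
                continue
            rows.append(
                dict(
                    transition=f"{int(key[i])}-{int(key[i + 1])}",
                    trial=int(tr),
                    normalized_ktt=(t[i + 1] - t[i]) / median_seq_time,
                )
            )
    return pd.DataFrame(rows, columns=["transition", "trial", "normalized_ktt"])


def sequence_iterations(labeled: pd.DataFrame) -> pd.DataFrame:
    """Tag completed canonical sequence iterations (ordinals 1..5 in a row).

    Returns a copy with a ``sequence_index`` column: consecutive correct
    keypresses whose ordinal positions run 1,2,3,4,5 within one trial form
    iteration 1, 2, ... of that trial; all other rows get NaN.  This is the
    bookkeeping behind OP1/OP5 instance selection for the representation
    analysis.
    """
    out = labeled.copy()
    out["sequence_index"] = np.nan
    seq_idx = np.full(len(out), np.nan)
    pos = {c: i for i, c in enumerate(out.columns)}
    arr_op = out["ordinal_position"].to_numpy()
    arr_ok = out["is_correct"].to_numpy()
    arr_tr = out["trial"].to_numpy()
    i = 0
    idx = np.arange(len(out))
    while i < len(out) - 4:
        if (
            arr_ok[i]
            and arr_op[i] == 1
            and all(
                arr_ok[i + j] and arr_op[i + j] == j + 1 and arr_tr[i + j] == arr_tr[i]
                for j in range(5)
            )
        ):
            seq_idx[i : i + 5] = 0  # placeholder, renumbered per trial below
            i += 5
        else:
            i += 1
    # renumber iterations within each trial
    out["sequence_index"] = seq_idx
    for tr, g in out.groupby("trial"):
        starts = g.index[(g["sequence_index"] == 0) & (g["ordinal_position"] == 1)]
        for n, st in enumerate(starts, start=1):
            loc = out.index.get_loc(st)
            out.iloc[loc : loc + 5, out.columns.get_loc("sequence_index")] = n
    return out
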