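"""Representational contextualization of a repeated action.

The trained sequence contains the same index-finger keypress at ordinal
positions 1 and 5 (Index_OP1 / Index_OP5).  This module quantifies how far
apart the neural representations of those two contexts sit, trial by trial:

* offline distance - last Index_OP5 of a trial to the first Index_OP1 of the
  next trial (across the interleaved rest break), mirroring the micro-offline
  skill measure; a pre-planning control variant targets the OP1 of the second
  completed sequence of the next trial instead;
* online distance - within a practice trial, either the mean Index_OP1 to
  Index_OP5 distance over completed sequences (sequence-based) or the first
  Index_OP1 to last Index_OP5 distance (trial-based).

Cumulative online/offline sums over early learning are compared across
subjects with a paired t-test, and the offline series is related to
micro-offline skill gains with Pearson correlation and robust (Huber IRLS)
regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .decoding import ManifoldModel
from .features import FeatureMatrix

__all__ = [
    "RepresentationSet",
    "CorrelationResult",
    "keypress_representation",
    "offline_distance",
    "online_distance",
    "contextualization_series",
    "cumulative_sums",
    "cumulative_compare",
    "correlate_with_gains",
    "specificity_contrast",
]


@dataclass
class RepresentationSet:
    """Per-keypress representation vectors with their instance tags."""

    coords: np.ndarray  # n_instances x D
    meta: pd.DataFrame  # trial, onset, ordinal_position, sequence_index

    def __post_init__(self):
        if len(self.coords) != len(self.meta):
            raise ValueError("coords and meta must be row-aligned")


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    slope: float
    intercept: float
    rmse: float
    f_statistic: float
    p_value: float
    method: str = "ols"
    n: int = 0


def keypress_representation(
    fm: FeatureMatrix,
    manifold: ManifoldModel | None = None,
    index_key: int = 4,
) -> RepresentationSet:
    """Index-finger keypress representations for the distance analysis.

    Rows of the (hybrid) feature matrix belonging to index-finger keypresses
    of completed sequences are projected through the fitted manifold (or used
    raw when ``manifold`` is None); each retains its trial, onset, ordinal
    position, and within-trial sequence index.
    """
    meta = fm.meta
    required = {"trial", "onset", "ordinal_position", "sequence_index"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"feature-matrix meta lacks columns {sorted(missing)}")
    keys = meta["key"].to_numpy() if "key" in meta.columns else fm.y
    sel = (
        (keys == index_key)
        & np.isfinite(meta["sequence_index"].to_numpy(dtype=float))
        & np.isin(meta["ordinal_position"].to_numpy(), [1.0, 5.0])
    )
    n_skipped = int(((keys == index_key) & ~sel).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} index keypresses outside completed sequences skipped")
    X = fm.X[sel]
    coords = manifold.transform(X) if manifold is not None else X
    return RepresentationSet(
        coords=np.asarray(coords, dtype=float),
        meta=meta[sel].reset_index(drop=True),
    )


def _instances(reps: RepresentationSet, trial: int, ordinal: int) -> tuple[np.ndarray, pd.DataFrame]:
    m = reps.meta
    sel = (m["trial"].to_numpy() == trial) & (m["ordinal_position"].to_numpy() == ordinal)
    order = np.argsort(m["onset"].to_numpy()[sel], kind="stable")
    return reps.coords[np.flatnonzero(sel)[order]], m[sel].iloc[order]


def offline_distance(
    reps: RepresentationSet, trial: int, variant: str = "lastOP5_to_firstOP1"
) -> float:
    """Euclidean distance across the rest break following ``trial``.

    Variants: ``lastOP5_to_firstOP1`` (default) and
    ``lastOP5_to_secondSeqOP1`` (pre-planning control: the OP1 of the second
    completed sequence of the next trial; missing when that trial completes
    fewer than two sequences).
    """
    op5, _ = _instances(reps, trial, 5)
    if len(op5) == 0:
        return np.nan
    op1, meta1 = _instances(reps, trial + 1, 1)
    if variant == "lastOP5_to_firstOP1":
        if len(op1) == 0:
            return np.nan
        target = op1[0]
    elif variant == "lastOP5_to_secondSeqOP1":
        second = meta1["sequence_index"].to_numpy() == 2
        if not second.any():
            return np.nan
        target = op1[np.flatnonzero(second)[0]]
    else:
        raise ValueError(f"unknown offline variant {variant!r}")
    return float(np.linalg.norm(op5[-1] - target))


def online_distance(reps: RepresentationSet, trial: int, mode: str = "sequence") -> float:
    """Within-trial Index_OP1 to Index_OP5 Euclidean distance.

    ``sequence`` mode averages the distance within each completed sequence;
    ``trial`` mode takes the first OP1 to the last OP5.
    """
    op1, m1 = _instances(reps, trial, 1)
    op5, m5 = _instances(reps, trial, 5)
    if len(op1) == 0 or len(op5) == 0:
        return np.nan
    if mode == "trial":
        return float(np.linalg.norm(op5[-1] - op1[0]))
    if mode == "sequence":
        s1 = dict(zip(m1["sequence_index"].astype(int), op1))
        s5 = dict(zip(m5["sequence_index"].astype(int), op5))
        common = sorted(set(s1) & set(s5))
        if not common:
            return np.nan
        return float(np.mean([np.linalg.norm(s5[i] - s1[i]) for i in common]))
    raise ValueError(f"unknown online mode {mode!r}")


def contextualization_series(
    reps: RepresentationSet,
    n_trials: int,
    offline_variant: str = "lastOP5_to_firstOP1",
) -> pd.DataFrame:
    """Per-trial distance series.

    Columns: ``trial``, ``online_seq``, ``online_trial``, and ``offline``
    (the distance across the rest break *following* the trial; NaN for the
    last trial).
    """
    m = reps.meta
    trial = m["trial"].to_numpy().astype(int)
    onset = m["onset"].to_numpy(dtype=float)
    op = m["ordinal_position"].to_numpy(dtype=float)
    seq = m["sequence_index"].to_numpy(dtype=float)
    order = np.lexsort((onset, trial))
    trial_s, onset_s, op_s, seq_s = trial[order], onset[order], op[order], seq[order]
    coords_s = reps.coords[order]
    bounds = np.searchsorted(trial_s, np.arange(1, n_trials + 2))
    first_op1 = {}
    second_seq_op1 = {}
    last_op5 = {}
    per_trial = {}
    for tr in range(1, n_trials + 1):
        lo, hi = bounds[tr - 1], bounds[tr]
        i1 = lo + np.flatnonzero(op_s[lo:hi] == 1.0)
        i5 = lo + np.flatnonzero(op_s[lo:hi] == 5.0)
        if len(i1):
            first_op1[tr] = coords_s[i1[0]]
            sec = i1[seq_s[i1] == 2.0]
            if len(sec):
                second_seq_op1[tr] = coords_s[sec[0]]
        if len(i5):
            last_op5[tr] = coords_s[i5[-1]]
        per_trial[tr] = (i1, i5)
    rows = []
    for tr in range(1, n_trials + 1):
        i1, i5 = per_trial[tr]
        online_seq = online_trial = np.nan
        if len(i1) and len(i5):
            online_trial = float(np.linalg.norm(coords_s[i5[-1]] - coords_s[i1[0]]))
            s1 = {int(s): j for j, s in zip(i1, seq_s[i1])}
            s5 = {int(s): j for j, s in zip(i5, seq_s[i5])}
            common = sorted(set(s1) & set(s5))
            if common:
                online_seq = float(
                    np.mean(
                        [np.linalg.norm(coords_s[s5[c]] - coords_s[s1[c]]) for c in common]
                    )
                )
        offline = np.nan
        if tr < n_trials and tr in last_op5:
            if offline_variant == "lastOP5_to_firstOP1":
                target = first_op1.get(tr + 1)
            elif offline_variant == "lastOP5_to_secondSeqOP1":
                target = second_seq_op1.get(tr + 1)
            else:
                raise ValueError(f"unknown offline variant {offline_variant!r}")
            if target is not None:
                offline = float(np.linalg.norm(last_op5[tr] - target))
        rows.append(
            dict(trial=tr, online_seq=online_seq, online_trial=online_trial, offline=offline)
        )
    return pd.DataFrame(rows)


def cumulative_sums(series: pd.DataFrame, T: int, online_mode: str = "sequence") -> tuple[float, float]:
    """Cumulative (online, offline) distance over trials 1..T.

    Online sums trials 1..T; offline sums the T-1 rest breaks inside the
    span.  Missing trials are skipped (and counted by the caller via NaNs).
    """
    s = series[series["trial"] <= T]
    online_col = "online_seq" if online_mode == "sequence" else "online_trial"
    online = float(np.nansum(s[online_col].to_numpy()))
    off = s[s["trial"] <= T - 1]["offline"].to_numpy()
    return online, float(np.nansum(off))


def cumulative_compare(
    subject_series: list[pd.DataFrame], T: int, online_mode: str = "sequence"
) -> dict:
    """Paired comparison of cumulative offline vs online distance across subjects.

    Returns t, p, df, Cohen's d (paired), and the per-subject sums.  A zero
    variance of the paired differences produces an infinite statistic with
    p = 0 and a warning rather than a silent clip.
    """
    if len(subject_series) < 3:
        raise ValueError("need at least 3 subjects for the paired comparison")
    online = np.empty(len(subject_series))
    offline = np.empty(len(subject_series))
    for i, s in enumerate(subject_series):
        online[i], offline[i] = cumulative_sums(s, T, online_mode)
    diff = offline - online
    sd = diff.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance of paired differences; degenerate t statistic")
        t = np.inf if diff.mean() > 0 else (-np.inf if diff.mean() < 0 else 0.0)
        p = 0.0 if diff.mean() != 0 else 1.0
        d = t
    else:
        t, p = stats.ttest_rel(offline, online)
        d = diff.mean() / sd
    return {
        "t": float(t),
        "p": float(p),
        "df": len(diff) - 1,
        "cohens_d": float(d),
        "offline_sums": offline,
        "online_sums": online,
    }


def correlate_with_gains(
    context: np.ndarray, gains: np.ndarray, method: str = "irls_robust"
) -> CorrelationResult:
    """Relate a contextualization series to skill gains.

    Pearson r and R^2 are always reported; the regression line is fit either
    by OLS or by Huber M-estimation via iteratively reweighted least squares
    (``irls_robust``), which coincides with OLS in the outlier-free limit.
    The F statistic and its p-value test the slope against a constant-only
    model.
    """
    x = np.asarray(context, dtype=float)
    y = np.asarray(gains, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 aligned points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    X = sm.add_constant(x)
    if method == "ols":
        fit = sm.OLS(y, X).fit()
        slope = float(fit.params[1])
        intercept = float(fit.params[0])
        resid = fit.resid
        f_stat, f_p = float(fit.fvalue), float(fit.f_pvalue)
    elif method == "irls_robust":
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        slope = float(fit.params[1])
        intercept = float(fit.params[0])
        resid = y - fit.fittedvalues
        # F test of the robust fit against the constant-only model
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        df_res = len(y) - 2
        f_stat = max(ss_tot - ss_res, 0.0) / (ss_res / df_res) if ss_res > 0 else np.inf
        f_p = float(stats.f.sf(f_stat, 1, df_res))
    else:
        raise ValueError(f"unknown method {method!r}")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CorrelationResult(
        r=float(r),
        r_squared=float(r**2),
        slope=slope,
        intercept=intercept,
        rmse=rmse,
        f_statistic=f_stat,
        p_value=f_p,
        method=method,
        n=len(x),
    )


def specificity_contrast(trained_distances: np.ndarray, control_distances: dict) -> pd.DataFrame:
    """Percent contextualization reduction of control families vs trained.

    For each control family, 100 * (trained - control) / trained using the
    mean distances; positive values mean the trained sequence shows more
    contextualization.
    """
    trained = np.asarray(trained_distances, dtype=float)
    trained_mean = float(np.nanmean(trained))
    if trained_mean == 0:
        raise ValueError("trained mean distance is zero; contrast undefined")
    rows = []
    for family, dists in control_distances.items():
        c = float(np.nanmean(np.asarray(dists, dtype=float)))
        rows.append(
            dict(
                family=family,
                trained_mean=trained_mean,
                control_mean=c,
                percent_lower=100.0 * (trained_mean - c) / trained_mean,
            )
        )
    return pd.DataFrame(rows)
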