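"""From source-space voxel time series to decoder-ready feature matrices.

A :class:`SourceTimeSeries` holds a voxels x samples array with a voxel ->
parcel map.  The pipeline filters the continuous series into a frequency
band, optionally collapses it to parcel space with sign-flip averaging,
averages activity in sliding windows locked to KeyDown events, and builds
the multi-scale "hybrid" space by concatenating whole-brain parcel features
with voxel features from top-ranked regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SourceTimeSeries",
    "BandSpec",
    "BANDS",
    "EpochWindow",
    "FeatureMatrix",
    "bandpass",
    "sign_flip_parcellate",
    "window_grid",
    "extract_epoch_features",
    "rank_regions",
    "build_hybrid",
]


@dataclass
class SourceTimeSeries:
    """Continuous multi-channel series: voxels (or parcels) x samples."""

    data: np.ndarray
    srate: float = 600.0
    parcel_map: np.ndarray | None = None  # per-voxel parcel index
    region_labels: list[str] | None = None  # per-parcel anatomical name

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.parcel_map is not None:
            self.parcel_map = np.asarray(self.parcel_map, dtype=int)
            if len(self.parcel_map) != self.data.shape[0]:
                raise ValueError("parcel_map length must equal number of voxels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float


#: Canonical oscillatory bands (Hz).
BANDS = {
    "broadband": BandSpec("broadband", 1.0, 100.0),
    "delta": BandSpec("delta", 1.0, 3.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 14.0),
    "beta": BandSpec("beta", 15.0, 24.0),
    "gamma": BandSpec("gamma", 25.0, 50.0),
    "high-gamma": BandSpec("high-gamma", 51.0, 100.0),
}


@dataclass(frozen=True)
class EpochWindow:
    """KeyDown-locked averaging window: onset t and width dt, both in ms."""

    t: float = 0.0
    dt: float = 200.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("window width must be > 0 ms")


@dataclass
class FeatureMatrix:
    """Epoch-averaged features: one row per keypress event."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    meta: pd.DataFrame  # per-row tags: trial, onset, ordinal_position, ...
    space: str = "parcel"
    band: str = "broadband"
    window: EpochWindow | None = None

    def __post_init__(self):
        if len(self.X) != len(self.y) or len(self.X) != len(self.meta):
            raise ValueError("X, y and meta must be row-aligned")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def bandpass(ts: SourceTimeSeries, band: BandSpec | str) -> SourceTimeSeries:
    """Zero-phase 4th-order Butterworth band-pass, applied per channel.

    Forward-backward filtering (sosfiltfilt) gives zero phase shift, so
    event-locked windows are not delayed by the filter.
    """
    if isinstance(band, str):
        band = BANDS[band]
    nyq = ts.srate / 2.0
    if not (0 < band.lo < band.hi < nyq):
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] Hz outside (0, {nyq}) Hz")
    sos = signal.butter(4, [band.lo, band.hi], btype="bandpass", fs=ts.srate, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return replace(ts, data=filtered)


def sign_flip_parcellate(ts: SourceTimeSeries) -> SourceTimeSeries:
    """Average voxels within parcels after sign alignment.

    Beamformed source series are sign-ambiguous, so a plain mean can cancel.
    Per parcel, the reference is the first principal component of the voxel
    series; voxels with negative loading are negated before averaging.  The
    component sign is fixed so that the majority loading mass is positive,
    which makes the operation an identity-mean on already-aligned parcels.
    """
    if ts.parcel_map is None:
        raise ValueError("parcel_map is required for parcellation")
    parcels = np.unique(ts.parcel_map)
    rows = []
    kept = []
    for p in parcels:
        vox = ts.data[ts.parcel_map == p]
        if vox.shape[0] == 0:  # pragma: no cover - unique() precludes this
            warnings.warn(f"parcel {p} is empty; excluded")
            continue
        if vox.shape[0] == 1:
            rows.append(vox[0])
            kept.append(p)
            continue
        centered = vox - vox.mean(axis=1, keepdims=True)
        # leading left singular vector = PC loadings over voxels
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        loadings = u[:, 0]
        if loadings.sum() < 0:
            loadings = -loadings
        flips = np.where(loadings < 0, -1.0, 1.0)
        rows.append((vox * flips[:, None]).mean(axis=0))
        kept.append(p)
    labels = None
    if ts.region_labels is not None:
        labels = [ts.region_labels[p] for p in kept]
    return SourceTimeSeries(np.asarray(rows), srate=ts.srate, region_labels=labels)


def window_grid(
    onsets_ms: np.ndarray | None = None, widths_ms: np.ndarray | None = None
) -> list[EpochWindow]:
    """Cartesian grid of KeyDown-locked windows.

    Defaults: onsets 0..100 ms in 10 ms steps, widths 25..350 ms in 25 ms
    steps (11 x 14 = 154 windows).
    """
    if onsets_ms is None:
        onsets_ms = np.arange(0, 101, 10)
    if widths_ms is None:
        widths_ms = np.arange(25, 351, 25)
    return [EpochWindow(float(t), float(dt)) for t in onsets_ms for dt in widths_ms]


def extract_epoch_features(
    ts: SourceTimeSeries,
    events: pd.DataFrame,
    window: EpochWindow,
    space: str = "parcel",
    band: str = "broadband",
    correct_only: bool = True,
    feature_names: list[str] | None = None,
) -> FeatureMatrix:
    """Average each channel over the event-locked window, one row per event.

    KeyDown maps to the nearest sample at or after the event onset; the
    window covers samples [start + t, start + t + dt) (closed-open).  Events
    whose window exceeds the recording are dropped with a logged count.  By
    default only keypresses belonging to correctly typed sequence iterations
    are retained.
    """
    ev = events
    if correct_only:
        if "is_correct" not in ev.columns:
            raise ValueError("events must be labeled (run label_correct) for correct_only")
        ev = ev[ev["is_correct"]]
    onset_samp = np.ceil(ev["onset"].to_numpy() * ts.srate - 1e-9).astype(int)
    start = onset_samp + int(round(window.t * ts.srate / 1000.0))
    n_win = int(round(window.dt * ts.srate / 1000.0))
    keep = (start >= 0) & (start + n_win <= ts.n_samples)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} events dropped: window outside recording")
    ev = ev[keep]
    start = start[keep]
    X = np.empty((len(ev), ts.n_channels))
    for i, s0 in enumerate(start):
        X[i] = ts.data[:, s0 : s0 + n_win].mean(axis=1)
    if feature_names is None:
        if ts.region_labels is not None and len(ts.region_labels) == ts.n_channels:
            feature_names = [str(l) for l in ts.region_labels]
        else:
            feature_names = [f"{space}:{i}" for i in range(ts.n_channels)]
    return FeatureMatrix(
        X=X,
        y=ev["key"].to_numpy().astype(int),
        feature_names=feature_names,
        meta=ev.reset_index(drop=True),
        space=space,
        band=band,
        window=window,
    )


def rank_regions(per_region_accuracy: dict) -> list:
    """Regions ordered by decoding accuracy, descending; ties keep input order."""
    items = list(per_region_accuracy.items())
    order = sorted(range(len(items)), key=lambda i: (-items[i][1], i))
    return [items[i][0] for i in order]


def build_hybrid(
    parcel_fm: FeatureMatrix,
    regional_fms: dict,
    ranking: list,
    eval_fn,
    saturation_tol: float = 0.005,
) -> tuple[FeatureMatrix, list]:
    """Greedy multi-scale feature concatenation.

    Starting from whole-brain parcel features, regional voxel features are
    appended in ranking order; a region is kept only if cross-validated
    accuracy (``eval_fn(X, y)``) improves by at least ``saturation_tol``,
    and the first non-improving region stops the search.
    """
    X = parcel_fm.X
    names = list(parcel_fm.feature_names)
    y = parcel_fm.y
    selected = []
    best = eval_fn(X, y)
    for region in ranking:
        fm = regional_fms[region]
        if len(fm.X) != len(X) or not np.array_equal(fm.y, y):
            raise ValueError(f"regional matrix {region!r} not row-aligned with parcel matrix")
        X_try = np.hstack([X, fm.X])
        acc = eval_fn(X_try, y)
        if acc - best < saturation_tol:
            break
        X = X_try
        names += [f"{region}:{n}" for n in fm.feature_names]
        best = acc
        selected.append(region)
    hybrid = FeatureMatrix(
        X=X,
        y=y,
        feature_names=names,
        meta=parcel_fm.meta,
        space="hybrid",
        band=parcel_fm.band,
        window=parcel_fm.window,
    )
    return hybrid, selected
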