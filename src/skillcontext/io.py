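"""File formats: BIDS-style events TSV and HDF5 array containers.

Events travel as tab-separated text with columns ``onset`` (seconds),
``key`` (1-4), ``trial`` (1-based) plus the labeling columns once present.
Continuous series live in an HDF5 container with datasets ``data``
(channels x samples), ``srate``, optional ``parcel_map`` and
``region_labels``; schemas are versioned through a root attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import SourceTimeSeries

__all__ = [
    "SchemaError",
    "read_events",
    "write_events",
    "read_series",
    "write_series",
]

SCHEMA_VERSION = "1"

EVENT_REQUIRED = ("onset", "key", "trial")
EVENT_OPTIONAL = ("is_correct", "ordinal_position", "sequence_index")


class SchemaError(ValueError):
    """Malformed or incomplete input file."""


def write_events(events: pd.DataFrame, path) -> None:
    cols = [c for c in EVENT_REQUIRED + EVENT_OPTIONAL if c in events.columns]
    missing = set(EVENT_REQUIRED) - set(cols)
    if missing:
        raise SchemaError(f"events missing required columns {sorted(missing)}")
    events[cols].to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    except Exception as e:
        raise SchemaError(f"cannot parse events file {path}: {e}") from e
    missing = set(EVENT_REQUIRED) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    for col, kind in (("onset", float), ("key", int), ("trial", int)):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(f"{path}: non-numeric {col!r} at line {line}")
        if kind is int and not np.allclose(converted.dropna() % 1, 0):
            frac = (converted % 1 != 0) & converted.notna()
            line = int(frac.idxmax()) + 2
            raise SchemaError(f"{path}: non-integer {col!r} at line {line}")
        df[col] = converted.astype(kind) if kind is int else converted
    if not df["key"].isin([1, 2, 3, 4]).all():
        bad = ~df["key"].isin([1, 2, 3, 4])
        raise SchemaError(f"{path}: key outside 1-4 at line {int(bad.idxmax()) + 2}")
    if "is_correct" in df.columns:
        df["is_correct"] = df["is_correct"].astype(bool)
    return df


def write_series(ts: SourceTimeSeries, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("data", data=ts.data)
        f.create_dataset("srate", data=float(ts.srate))
        if ts.parcel_map is not None:
            f.create_dataset("parcel_map", data=ts.parcel_map)
        if ts.region_labels is not None:
            f.create_dataset(
                "region_labels",
                data=np.array([str(l) for l in ts.region_labels], dtype="S"),
            )


def read_series(path, require_parcel_map: bool = True) -> SourceTimeSeries:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("data", "srate"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset {name!r}")
        if require_parcel_map and "parcel_map" not in f:
            raise SchemaError(f"{path}: missing dataset 'parcel_map'")
        data = f["data"][()]
        srate = float(f["srate"][()])
        parcel_map = f["parcel_map"][()] if "parcel_map" in f else None
        labels = None
        if "region_labels" in f:
            labels = [s.decode() for s in f["region_labels"][()]]
    return SourceTimeSeries(data, srate=srate, parcel_map=parcel_map, region_labels=labels)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=default)
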