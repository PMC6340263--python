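"""Persistent trial container (HDF5) and structured configuration.

The container layout is array-first: groups ``/lfp``, ``/eye``, ``/events``
(one dataset per events column), and ``/meta`` (YAML-serialized attributes,
including the generator config and seed for synthetic sessions).  Time is
stored as integer milliseconds relative to fixation onset, which the 1 kHz
sampling makes exact.  Events are additionally exportable as a plain CSV for
inspection.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EVENT_COLUMNS, TrialSet
from .errors import FormatError

__all__ = [
    "write_container",
    "read_container",
    "write_events_csv",
    "load_config",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1


def write_container(path: str | Path, trialset: TrialSet) -> None:
    """Write a TrialSet to an HDF5 container (lossless round trip)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "perisacc-trialset"
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["sample_rate"] = trialset.sample_rate
        f.attrs["eye_sample_rate"] = trialset.eye_sample_rate
        f.attrs["t0_index"] = trialset.t0_index
        f.attrs["meta_yaml"] = yaml.safe_dump(_plain(trialset.meta))
        f.create_dataset("lfp", data=trialset.lfp)
        f.create_dataset("eye", data=trialset.eye)
        f.create_dataset("time_ms", data=trialset.time_ms)
        g = f.create_group("events")
        for col in EVENT_COLUMNS:
            g.create_dataset(col, data=np.asarray(trialset.events[col], dtype=float))


def read_container(path: str | Path) -> TrialSet:
    """Read a TrialSet container written by :func:`write_container`."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open container {path}: {exc}") from exc
    with f:
        if f.attrs.get("format") != "perisacc-trialset":
            raise FormatError(f"{path} is not a perisacc trial container")
        version = int(f.attrs.get("version", -1))
        if version != FORMAT_VERSION:
            raise FormatError(
                f"container version {version} unsupported (expected {FORMAT_VERSION})"
            )
        for group in ("lfp", "eye", "time_ms", "events"):
            if group not in f:
                raise FormatError(f"container missing required group '{group}'")
        events_grp = f["events"]
        missing = [c for c in EVENT_COLUMNS if c not in events_grp]
        if missing:
            raise FormatError(f"events table missing columns: {missing}")
        events = pd.DataFrame({c: events_grp[c][()] for c in EVENT_COLUMNS})
        events["trial_id"] = events["trial_id"].astype(int)
        meta = yaml.safe_load(f.attrs.get("meta_yaml", "{}")) or {}
        return TrialSet(
            lfp=f["lfp"][()],
            eye=f["eye"][()],
            time_ms=f["time_ms"][()],
            events=events,
            sample_rate=float(f.attrs["sample_rate"]),
            eye_sample_rate=float(f.attrs["eye_sample_rate"]),
            meta=meta,
        )


def write_events_csv(path: str | Path, trialset: TrialSet) -> None:
    """Dump the events table (trial_id, onset_ms, end_ms, direction_deg)."""
    trialset.events.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a nested key/value config from a YAML (or JSON) text file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must contain a mapping at top level")
    return cfg


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and tuples to YAML-safe types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
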