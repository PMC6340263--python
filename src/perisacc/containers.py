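"""In-memory containers for trial-structured LFP recordings.

The pipeline's universal input is a :class:`TrialSet`: a stack of trials,
each holding multi-channel LFP sampled at 1 kHz on a common time grid,
two-component eye position in degrees, and per-trial event metadata (saccade
onset, saccade end, saccade direction).  Time is kept in integer milliseconds
relative to the nominal fixation onset t = 0 (the detected end of the
saccade), which the 1 kHz sampling makes exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidInputError

EVENT_COLUMNS = ("trial_id", "onset_ms", "end_ms", "direction_deg")


@dataclass
class TrialSet:
    """Trial-structured LFP + eye traces + event metadata.

    Parameters
    ----------
    lfp : ndarray, shape (n_trials, n_channels, n_time)
        LFP voltage (raw or normalized units) at ``sample_rate``.
    eye : ndarray, shape (n_trials, 2, n_eye_time)
        Horizontal / vertical eye position in degrees.
    time_ms : ndarray, shape (n_time,)
        Integer-millisecond time axis of the LFP grid; ``time_ms == 0`` is the
        nominal fixation-onset alignment point (t = 0).
    events : DataFrame
        Columns ``trial_id, onset_ms, end_ms, direction_deg``; ``end_ms`` is
        each trial's true/detected saccade end on the ``time_ms`` axis and
        defines that trial's t = 0.
    """

    lfp: np.ndarray
    eye: np.ndarray
    time_ms: np.ndarray
    events: pd.DataFrame
    sample_rate: float = 1000.0
    eye_sample_rate: float = 1000.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.eye = np.asarray(self.eye, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=int)
        if self.lfp.ndim != 3:
            raise InvalidInputError("lfp must be (n_trials, n_channels, n_time)")
        if self.eye.ndim != 3 or self.eye.shape[1] != 2:
            raise InvalidInputError("eye must be (n_trials, 2, n_time)")
        if self.lfp.shape[2] != self.time_ms.size:
            raise InvalidInputError("time axis length does not match LFP")
        if self.lfp.shape[0] != self.eye.shape[0]:
            raise InvalidInputError("lfp and eye trial counts differ")
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise InvalidInputError(f"events table missing columns: {sorted(missing)}")
        if len(self.events) != self.n_trials:
            raise InvalidInputError("one events row per trial required")
        if not np.all(np.diff(self.time_ms) == 1):
            raise InvalidInputError("time axis must be contiguous 1 ms steps")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_time(self) -> int:
        return self.lfp.shape[2]

    @property
    def t0_index(self) -> int:
        """Index on the time axis where ``time_ms == 0``."""
        idx = np.flatnonzero(self.time_ms == 0)
        if idx.size != 1:
            raise InvalidInputError("time axis must contain t = 0 exactly once")
        return int(idx[0])

    def directions(self) -> np.ndarray:
        """Sorted unique saccade directions (deg) present in the events table."""
        return np.unique(np.asarray(self.events["direction_deg"], dtype=float))

    def trials_for_direction(self, direction: float) -> np.ndarray:
        """Row indices of trials whose saccade direction equals ``direction``."""
        d = np.asarray(self.events["direction_deg"], dtype=float)
        return np.flatnonzero(np.isclose(d, float(direction)))

    def copy(self) -> "TrialSet":
        return TrialSet(
            lfp=self.lfp.copy(),
            eye=self.eye.copy(),
            time_ms=self.time_ms.copy(),
            events=self.events.copy(),
            sample_rate=self.sample_rate,
            eye_sample_rate=self.eye_sample_rate,
            meta=dict(self.meta),
        )


@dataclass
class EpochMatrix:
    """Trials-by-samples feature matrix for one channel and analysis window.

    Each row is one trial's LFP over the window's 1 ms sample set; ``label``
    tags the class the rows represent (``"saccade"``, ``"fixation"``, or a
    direction in degrees).
    """

    data: np.ndarray
    label: Any
    channel: int
    window: Any  # WindowSpec; kept loose to avoid a circular import
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.trial_ids = np.asarray(self.trial_ids)
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("epoch matrix contains non-finite entries")
        if self.data.shape[0] != self.trial_ids.size:
            raise InvalidInputError("one trial id per epoch row required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]
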