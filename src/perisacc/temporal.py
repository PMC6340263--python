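"""Fixation-onset timing analysis: the temporal-window sweep.

A family of classifiers is trained with the saccade class taken from 100 ms
windows centered at tau_train on the training grid {−50 … 49} ms (fixation
class fixed at the post-saccadic window, tau = 250, unless configured
otherwise).  Each held-out trial is then scored with test windows slid over
a *bias-corrected* range of centers obeying two rules: (1) the test range is
symmetric about tau_train, and (2) it covers the full training grid
{−50 … 49}.  Together these give tau_test in {tau_train − 100, …,
tau_train + 99} — 200 centers — so that under pure noise no edge of the
range is favoured and the expected vote equals tau_train.

Each trial votes for the tau_test with the largest s-value; the RMS of
(vote − tau_train) across trials measures how precisely the LFP times
fixation onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import LinearClassifier, s_value, train_linear_svm
from .containers import TrialSet
from .errors import EpochOutOfBoundsError, InvalidConfigError
from .preprocess import (
    NormStats,
    TrialEvents,
    WindowSpec,
    build_epoch_matrix,
    extract_epoch,
    fit_norm_stats,
    apply_norm,
)

__all__ = [
    "SweepResult",
    "TRAIN_GRID",
    "tau_test_range",
    "tau_train_grid",
    "slide_classify",
    "vote",
    "rms_error",
    "sweep",
    "uniform_null_rms",
]

#: canonical 100 ms training grid of saccade-class window centers (ms)
TRAIN_GRID = np.arange(-50, 50)


@dataclass
class SweepResult:
    """Per-tau_train outcome: votes, s-curves, and the RMS timing error."""

    tau_train: int
    channel: int
    votes: np.ndarray  # best tau_test per trial (ms)
    s_curves: np.ndarray  # (n_trials, n_test_centers)
    test_centers: np.ndarray
    trial_ids: np.ndarray
    rms: float
    skipped_trials: int = 0

    @property
    def vote_mean(self) -> float:
        return float(np.mean(self.votes))

    @property
    def vote_sd(self) -> float:
        return float(np.std(self.votes))


def tau_test_range(tau_train: int) -> np.ndarray:
    """Bias-corrected test-window centers for a given training center.

    {tau_train − 100, …, tau_train + 99}: 200 centers at 1 ms steps,
    symmetric about tau_train and covering the whole training grid.
    """
    if tau_train not in TRAIN_GRID:
        raise InvalidConfigError(
            f"tau_train must lie on the training grid {{-50..49}}, got {tau_train}"
        )
    return np.arange(tau_train - 100, tau_train + 100)


def tau_train_grid(length: int = 100) -> np.ndarray:
    """Training-window centers for a given window length.

    All centers whose windows lie inside the overall analysis range used by
    the 100 ms grid (whose last window is the one centered at +49 ms); for
    length 100 this is {−50 … 49}; for length 10, {−95 … 94} — the earliest
    10 ms window also starts at −100 ms.
    """
    if length <= 0 or length % 2:
        raise InvalidConfigError("window length must be positive and even")
    return np.arange(-100 + length // 2, 99 - length // 2 + 1)


def slide_classify(
    clf: LinearClassifier,
    trial_lfp: np.ndarray,
    time_ms: np.ndarray,
    events: TrialEvents,
    tau_train: int,
    length: int = 100,
    stats: NormStats | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """s-value of one trial's LFP at every test-window center.

    Returns (test_centers, s_curve); raises EpochOutOfBoundsError if the
    trial span does not cover every test window (callers should skip, not
    clip, such trials — clipping would reintroduce the edge bias the
    symmetric range removes).
    """
    centers = tau_test_range(tau_train)
    trace = trial_lfp if stats is None else apply_norm(trial_lfp, stats)
    curve = np.empty(centers.size)
    for i, tau in enumerate(centers):
        vec = extract_epoch(trace, time_ms, events, WindowSpec(int(tau), length))
        curve[i] = s_value(clf, vec)
    return centers, curve


def vote(s_curve: np.ndarray, test_centers: np.ndarray, tau_train: int) -> int:
    """The tau_test with the largest s-value.

    Ties are broken toward the center closest to tau_train, then toward the
    earlier center, so that no direction is favoured in expectation.
    """
    s_curve = np.asarray(s_curve, dtype=float)
    best = np.flatnonzero(s_curve == s_curve.max())
    cands = np.asarray(test_centers)[best]
    dist = np.abs(cands - tau_train)
    nearest = cands[dist == dist.min()]
    return int(nearest.min())


def rms_error(votes: np.ndarray, tau_train: int) -> float:
    """Root-mean-square deviation of the votes from the training center (ms)."""
    votes = np.asarray(votes, dtype=float)
    return float(np.sqrt(np.mean((votes - tau_train) ** 2)))


def uniform_null_rms(tau_train: int) -> float:
    """Analytic RMS error if votes were uniform over the test range.

    With centers {tau_train − 100 … tau_train + 99}, offsets d run over
    {−100 … 99} and E[d²] = mean of d², whose square root this returns.
    """
    offsets = tau_test_range(tau_train) - tau_train
    return float(np.sqrt(np.mean(offsets.astype(float) ** 2)))


def sweep(
    trialset: TrialSet,
    channel: int,
    direction: float | None,
    tau_trains: np.ndarray | list[int] | None = None,
    length: int = 100,
    fixation_tau: int = 250,
    c: float = 1.0,
    normalize: bool = True,
) -> dict[int, SweepResult]:
    """Leave-one-out temporal sweep for one channel.

    For each tau_train, a classifier is trained per held-out trial (saccade
    class: the tau_train window of the remaining trials; fixation class: the
    tau = ``fixation_tau`` window of the remaining trials) and the held-out
    trial's s-curve is computed over the bias-corrected test range; its
    argmax is the trial's vote.

    Parameters
    ----------
    direction : float or None
        Restrict to saccades of one direction (None pools all directions).

    Returns
    -------
    dict mapping tau_train -> SweepResult
    """
    if tau_trains is None:
        tau_trains = TRAIN_GRID
    trials = (
        trialset.trials_for_direction(direction)
        if direction is not None
        else np.arange(trialset.n_trials)
    )
    stats = fit_norm_stats(trialset, channel) if normalize else None
    neg = build_epoch_matrix(
        trialset, channel, WindowSpec(fixation_tau, length), trials=trials,
        label="fixation", stats=stats,
    )
    results: dict[int, SweepResult] = {}
    for tau_train in np.asarray(tau_trains, dtype=int):
        pos = build_epoch_matrix(
            trialset, channel, WindowSpec(int(tau_train), length), trials=trials,
            label="saccade", stats=stats,
        )
        if pos.n_trials != trials.size or neg.n_trials != trials.size:
            # leave-one-out indexing below assumes full window coverage
            raise EpochOutOfBoundsError(
                "some trials do not cover the training or fixation window"
            )
        votes, curves, kept, skipped = [], [], [], 0
        centers = tau_test_range(int(tau_train))
        for k, trial in enumerate(trials):
            clf = train_linear_svm(
                np.delete(pos.data, k, axis=0), np.delete(neg.data, k, axis=0), c=c
            )
            ev = trialset.events.iloc[trial]
            events = TrialEvents(
                saccade_onset=float(ev["onset_ms"]),
                saccade_end=float(ev["end_ms"]),
                direction=float(ev["direction_deg"]),
            )
            try:
                _, curve = slide_classify(
                    clf,
                    trialset.lfp[trial, channel],
                    trialset.time_ms,
                    events,
                    int(tau_train),
                    length,
                    stats=stats,
                )
            except EpochOutOfBoundsError:
                skipped += 1
                continue
            votes.append(vote(curve, centers, int(tau_train)))
            curves.append(curve)
            kept.append(ev["trial_id"])
        votes_arr = np.asarray(votes)
        results[int(tau_train)] = SweepResult(
            tau_train=int(tau_train),
            channel=channel,
            votes=votes_arr,
            s_curves=np.vstack(curves) if curves else np.empty((0, centers.size)),
            test_centers=centers,
            trial_ids=np.asarray(kept),
            rms=rms_error(votes_arr, int(tau_train)) if votes else float("nan"),
            skipped_trials=skipped,
        )
    return results


def sweep_summary(results_by_channel: dict[int, dict[int, SweepResult]]) -> pd.DataFrame:
    """Tidy per-(channel, tau_train) summary plus the channel-averaged RMS.

    Returns a DataFrame with columns channel, tau_train, vote_mean, vote_sd,
    rms, n_trials; the channel average is the mean RMS across channels at
    each tau_train (rows with channel = -1).
    """
    rows = []
    for ch, res in results_by_channel.items():
        for tau, r in res.items():
            rows.append(
                {
                    "channel": ch,
                    "tau_train": tau,
                    "vote_mean": r.vote_mean,
                    "vote_sd": r.vote_sd,
                    "rms": r.rms,
                    "n_trials": r.votes.size,
                }
            )
    df = pd.DataFrame(rows)
    avg = (
        df.groupby("tau_train", as_index=False)[["rms"]]
        .mean()
        .assign(channel=-1, vote_mean=np.nan, vote_sd=np.nan, n_trials=np.nan)
    )
    return pd.concat([df, avg], ignore_index=True)
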