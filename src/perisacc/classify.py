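"""Linear max-margin classification of LFP epochs and criterion-free scoring.

The decoding statistic throughout is the *s-value*: the signed perpendicular
distance of a trial's feature vector (100 one-millisecond LFP samples by
default) from the maximum-margin hyperplane separating the positive (saccade)
class from the negative (fixation) class,

    s(x) = (w · x + b) / ||w||,

with positive s on the saccade side.  Held-out s-values come from a
leave-one-out protocol: each trial is scored against a hyperplane trained
with that trial removed.  Performance is summarized criterion-free by the
ROC obtained from a threshold sweep over the s-values; its area (AUC) equals
the probability that a random positive trial out-scores a random negative
one, with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import EpochMatrix
from .errors import (
    InsufficientClassError,
    InsufficientDataError,
    InvalidInputError,
    MisalignedChannelsError,
)

__all__ = [
    "LinearClassifier",
    "SValueTable",
    "ROCCurve",
    "train_linear_svm",
    "s_value",
    "loo_svalues",
    "roc_auc",
    "percent_correct",
    "amplitude_auc",
    "shape_only",
    "pool_channels",
    "pool_channels_concat",
    "sequential_optimal",
]

DEFAULT_C = 1.0


@dataclass
class LinearClassifier:
    """A trained max-margin separator: weights, bias, and provenance."""

    weights: np.ndarray
    bias: float
    meta: dict[str, Any]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.linalg.norm(self.weights) > 0:
            raise InvalidInputError("classifier weights must be non-zero")

    @property
    def weight_norm(self) -> float:
        return float(np.linalg.norm(self.weights))


@dataclass
class SValueTable:
    """Per-trial signed distances to the (held-out) separating hyperplane."""

    trial_ids: np.ndarray
    true_class: np.ndarray  # +1 positive (saccade), -1 negative (fixation)
    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.true_class = np.asarray(self.true_class, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids)
        if not np.all(np.isfinite(self.s)):
            raise InvalidInputError("s-values must be finite")

    @property
    def s_pos(self) -> np.ndarray:
        return self.s[self.true_class > 0]

    @property
    def s_neg(self) -> np.ndarray:
        return self.s[self.true_class < 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial_id": self.trial_ids, "true_class": self.true_class, "s": self.s}
        )


@dataclass
class ROCCurve:
    """Threshold sweep: ordered (threshold, TPR, FPR) triples plus the AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _as_array(epochs: EpochMatrix | np.ndarray) -> np.ndarray:
    if isinstance(epochs, EpochMatrix):
        return epochs.data
    return np.atleast_2d(np.asarray(epochs, dtype=float))


def train_linear_svm(
    pos: EpochMatrix | np.ndarray,
    neg: EpochMatrix | np.ndarray,
    c: float = DEFAULT_C,
    meta: dict[str, Any] | None = None,
) -> LinearClassifier:
    """Train a soft-margin linear SVM on unweighted per-millisecond features.

    Parameters
    ----------
    pos, neg : EpochMatrix or array (n, d)
        Positive-class (saccade) and negative-class (fixation) feature rows.
    c : float
        Soft-margin regularization weight; large values approach the
        hard-margin optimum.

    Returns
    -------
    LinearClassifier
        Deterministic given the inputs (the dual QP has a unique optimum for
        a linear kernel on distinct data).
    """
    xp, xn = _as_array(pos), _as_array(neg)
    if xp.shape[0] < 1 or xn.shape[0] < 1:
        raise InsufficientClassError("each class needs at least one example")
    if xp.shape[1] != xn.shape[1]:
        raise InvalidInputError("feature dimensions differ between classes")
    x = np.vstack([xp, xn])
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite features")
    y = np.concatenate([np.ones(xp.shape[0]), -np.ones(xn.shape[0])])
    svm = SVC(kernel="linear", C=c)
    svm.fit(x, y)
    m = {"n_pos": xp.shape[0], "n_neg": xn.shape[0], "c": c}
    if meta:
        m.update(meta)
    return LinearClassifier(
        weights=svm.coef_[0], bias=float(svm.intercept_[0]), meta=m
    )


def s_value(clf: LinearClassifier, x: np.ndarray) -> float | np.ndarray:
    """Signed distance of feature vector(s) to the hyperplane, in feature units."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != clf.weights.size:
        raise InvalidInputError(
            f"feature dimension {x.shape[-1]} != classifier dimension {clf.weights.size}"
        )
    s = (x @ clf.weights + clf.bias) / clf.weight_norm
    return float(s) if s.ndim == 0 else s


def loo_svalues(
    pos: EpochMatrix | np.ndarray,
    neg: EpochMatrix | np.ndarray,
    c: float = DEFAULT_C,
    pos_ids: Sequence | None = None,
    neg_ids: Sequence | None = None,
) -> SValueTable:
    """Leave-one-out s-values for every trial of both classes.

    Trial k's s-value is its signed distance to the hyperplane trained on all
    trials except k.  The class being held out must keep >= 1 example after
    removal (so >= 2 per class overall).
    """
    xp, xn = _as_array(pos), _as_array(neg)
    if isinstance(pos, EpochMatrix) and pos_ids is None:
        pos_ids = pos.trial_ids
    if isinstance(neg, EpochMatrix) and neg_ids is None:
        neg_ids = neg.trial_ids
    if pos_ids is None:
        pos_ids = np.arange(xp.shape[0])
    if neg_ids is None:
        neg_ids = np.arange(xp.shape[0], xp.shape[0] + xn.shape[0])
    if xp.shape[0] < 2 or xn.shape[0] < 2:
        raise InsufficientClassError("leave-one-out needs >= 2 examples per class")

    ids, classes, svals = [], [], []
    for k in range(xp.shape[0]):
        clf = train_linear_svm(np.delete(xp, k, axis=0), xn, c=c)
        svals.append(s_value(clf, xp[k]))
        ids.append(pos_ids[k])
        classes.append(1)
    for k in range(xn.shape[0]):
        clf = train_linear_svm(xp, np.delete(xn, k, axis=0), c=c)
        svals.append(s_value(clf, xn[k]))
        ids.append(neg_ids[k])
        classes.append(-1)
    return SValueTable(
        trial_ids=np.asarray(ids), true_class=np.asarray(classes), s=np.asarray(svals)
    )


def roc_auc(s_pos: np.ndarray, s_neg: np.ndarray) -> ROCCurve:
    """ROC from a threshold sweep over s-values; AUC by pair counting.

    Thresholds are placed at midpoints between consecutive distinct scores,
    plus sentinels above and below all scores, so the curve runs from (0, 0)
    to (1, 1).  The AUC equals the fraction of (positive, negative) pairs
    with s_pos > s_neg, ties counted 1/2 — the probabilistic reading of the
    area under the sweep.
    """
    s_pos = np.asarray(s_pos, dtype=float).ravel()
    s_neg = np.asarray(s_neg, dtype=float).ravel()
    if s_pos.size == 0 or s_neg.size == 0:
        raise InsufficientDataError("both score sets must be non-empty")
    distinct = np.unique(np.concatenate([s_pos, s_neg]))
    mid = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[-1] + 1.0], mid[::-1], [distinct[0] - 1.0]])
    # classify positive when s > threshold; sweep from high to low threshold
    tpr = np.array([(s_pos > th).mean() for th in thresholds])
    fpr = np.array([(s_neg > th).mean() for th in thresholds])
    # ties at the threshold contribute half via the trapezoid between the
    # bracketing midpoint thresholds; with midpoints no score equals any
    # threshold, so trapezoid integration is exactly pair counting
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def percent_correct(
    s_pos: np.ndarray, s_neg: np.ndarray, mode: str = "svm"
) -> float:
    """Fraction of correct classifications under a fixed or optimized criterion.

    mode "svm" uses the SVM hyperplane itself (threshold 0: s > 0 is called a
    saccade).  mode "optimal" scans all thresholds and reports the best
    achievable accuracy under equal false-positive/false-negative costs.
    """
    s_pos = np.asarray(s_pos, dtype=float).ravel()
    s_neg = np.asarray(s_neg, dtype=float).ravel()
    if s_pos.size == 0 or s_neg.size == 0:
        raise InsufficientDataError("both score sets must be non-empty")
    n = s_pos.size + s_neg.size
    if mode == "svm":
        return float(((s_pos > 0).sum() + (s_neg <= 0).sum()) / n)
    if mode == "optimal":
        distinct = np.unique(np.concatenate([s_pos, s_neg]))
        mid = (distinct[:-1] + distinct[1:]) / 2.0
        candidates = np.concatenate([[distinct[0] - 1.0], mid, [distinct[-1] + 1.0]])
        acc = [((s_pos > th).sum() + (s_neg <= th).sum()) / n for th in candidates]
        return float(max(acc))
    raise InvalidInputError(f"unknown mode {mode!r}")


def amplitude_auc(
    pos: EpochMatrix | np.ndarray, neg: EpochMatrix | np.ndarray
) -> ROCCurve:
    """Baseline classifier: score each trial by its mean epoch amplitude.

    Moves a threshold across the two mean-amplitude distributions; serves as
    the 1-dimensional control against the 100-dimensional margin classifier.
    """
    return roc_auc(_as_array(pos).mean(axis=1), _as_array(neg).mean(axis=1))


def shape_only(epochs: EpochMatrix | np.ndarray) -> EpochMatrix | np.ndarray:
    """Remove each trial's mean amplitude, leaving only waveform shape."""
    if isinstance(epochs, EpochMatrix):
        data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
        return EpochMatrix(
            data=data,
            label=epochs.label,
            channel=epochs.channel,
            window=epochs.window,
            trial_ids=epochs.trial_ids,
        )
    arr = np.atleast_2d(np.asarray(epochs, dtype=float))
    return arr - arr.mean(axis=1, keepdims=True)


def _aligned_stack(tables: Sequence[SValueTable]) -> tuple[np.ndarray, np.ndarray]:
    ref = tables[0]
    order0 = np.argsort(ref.trial_ids, kind="stable")
    stacked = []
    for tab in tables:
        if tab.s.size != ref.s.size:
            raise MisalignedChannelsError("channel tables differ in trial count")
        order = np.argsort(tab.trial_ids, kind="stable")
        if not np.array_equal(tab.trial_ids[order], ref.trial_ids[order0]):
            raise MisalignedChannelsError("channel tables cover different trials")
        if not np.array_equal(tab.true_class[order], ref.true_class[order0]):
            raise MisalignedChannelsError("class labels disagree across channels")
        stacked.append(tab.s[order])
    return np.vstack(stacked), ref.true_class[order0]


def pool_channels(tables: Sequence[SValueTable]) -> ROCCurve:
    """Population read-out: sum each trial's s-values across channels, then ROC."""
    if len(tables) == 0:
        raise InsufficientDataError("need at least one channel table")
    s_stack, classes = _aligned_stack(list(tables))
    pooled = s_stack.sum(axis=0)
    return roc_auc(pooled[classes > 0], pooled[classes < 0])


def pool_channels_concat(tables: Sequence[SValueTable]) -> ROCCurve:
    """Variant pooling: concatenate per-channel s-value histograms.

    Treats each (trial, channel) s-value as its own observation instead of
    summing within trials; kept behind this separate entry point because it
    does not yield one score per trial.
    """
    if len(tables) == 0:
        raise InsufficientDataError("need at least one channel table")
    s = np.concatenate([t.s for t in tables])
    cls = np.concatenate([t.true_class for t in tables])
    return roc_auc(s[cls > 0], s[cls < 0])


def sequential_optimal(
    tables: Sequence[SValueTable],
) -> tuple[list[int], float]:
    """Optimal channel combination by sequential addition.

    Channels are ranked by single-channel AUC (descending); the trial-summed
    pooled AUC is evaluated for every prefix of the ranking, and the prefix
    with the highest pooled AUC is returned as (channel indices, auc).
    """
    if len(tables) == 0:
        raise InsufficientDataError("need at least one channel table")
    singles = [roc_auc(t.s_pos, t.s_neg).auc for t in tables]
    order = sorted(range(len(tables)), key=lambda i: singles[i], reverse=True)
    best_subset, best_auc = [order[0]], -np.inf
    for k in range(1, len(order) + 1):
        subset = order[:k]
        auc = pool_channels([tables[i] for i in subset]).auc
        if auc > best_auc:
            best_subset, best_auc = list(subset), auc
    return best_subset, float(best_auc)
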