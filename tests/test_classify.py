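"""Max-margin classification, s-values, ROC/AUC, controls, channel pooling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from perisacc import (
    LinearClassifier,
    SValueTable,
    amplitude_auc,
    loo_svalues,
    percent_correct,
    pool_channels,
    roc_auc,
    s_value,
    sequential_optimal,
    shape_only,
    train_linear_svm,
)
from perisacc.errors import (
    InsufficientClassError,
    InsufficientDataError,
    InvalidInputError,
    MisalignedChannelsError,
)

HARD = 1e6  # large soft-margin weight: effectively hard margin


def pair_count_auc(s_pos, s_neg):
    """Exhaustive pair-counting oracle: P(s_pos > s_neg), ties 1/2."""
    wins = sum(
        1.0 if a > b else (0.5 if a == b else 0.0)
        for a in s_pos
        for b in s_neg
    )
    return wins / (len(s_pos) * len(s_neg))


class TestTrainLinearSvm:
    def test_symmetric_1d_hard_margin(self):
        clf = train_linear_svm([[1.0]], [[-1.0]], c=HARD)
        # boundary at 0: w = 1, b = 0
        assert clf.weights[0] == pytest.approx(1.0, abs=1e-6)
        assert clf.bias == pytest.approx(0.0, abs=1e-6)
        assert s_value(clf, [0.0]) == pytest.approx(0.0, abs=1e-6)

    def test_2d_perpendicular_bisector(self):
        clf = train_linear_svm([[2.0, 0.0]], [[0.0, 0.0]], c=HARD)
        # boundary x1 = 1; s-value of (2, 0) is +1
        assert s_value(clf, [2.0, 0.0]) == pytest.approx(1.0, abs=1e-6)
        assert s_value(clf, [1.0, 5.0]) == pytest.approx(0.0, abs=1e-6)

    def test_identical_classes_give_chance_auc(self, rng):
        x = rng.normal(size=(6, 4))
        clf = train_linear_svm(x, x, c=1.0)
        s = s_value(clf, x)
        assert roc_auc(s, s).auc == pytest.approx(0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(InsufficientClassError):
            train_linear_svm(np.empty((0, 3)), np.zeros((2, 3)))

    def test_nonfinite_features_rejected(self):
        with pytest.raises(InvalidInputError):
            train_linear_svm([[np.nan]], [[0.0]])


class TestSValue:
    def test_plane_geometry(self):
        clf = LinearClassifier(weights=[3.0, 4.0], bias=0.0, meta={})
        assert s_value(clf, [3.0, 4.0]) == pytest.approx(5.0)

    def test_point_on_hyperplane(self):
        clf = LinearClassifier(weights=[3.0, 4.0], bias=0.0, meta={})
        assert s_value(clf, [4.0, -3.0]) == pytest.approx(0.0)

    def test_antisymmetry_with_zero_bias(self, rng):
        clf = LinearClassifier(weights=rng.normal(size=5), bias=0.0, meta={})
        x = rng.normal(size=5)
        assert s_value(clf, -x) == pytest.approx(-s_value(clf, x))

    def test_dimension_mismatch(self):
        clf = LinearClassifier(weights=[1.0, 2.0], bias=0.0, meta={})
        with pytest.raises(InvalidInputError):
            s_value(clf, [1.0, 2.0, 3.0])


class TestLooSValues:
    def test_row_count(self, rng):
        pos = rng.normal(1, 1, size=(4, 3))
        neg = rng.normal(-1, 1, size=(5, 3))
        table = loo_svalues(pos, neg)
        assert table.s.size == 9
        assert (table.true_class == 1).sum() == 4

    def test_1d_margin_geometry(self):
        # hold out +1: boundary midway between +2 and -1 at +0.5
        table = loo_svalues([[1.0], [2.0]], [[-1.0], [-2.0]], c=HARD)
        held_out_plus1 = table.s[0]
        assert held_out_plus1 == pytest.approx(0.5, abs=1e-5)

    def test_matches_explicit_retraining_oracle(self, rng):
        # independent route: sklearn SVC per held-out trial, decision_function
        pos = rng.normal(0.5, 1, size=(5, 4))
        neg = rng.normal(-0.5, 1, size=(6, 4))
        table = loo_svalues(pos, neg, c=1.0)
        oracle = []
        for k in range(5):
            svm = SVC(kernel="linear", C=1.0)
            x = np.vstack([np.delete(pos, k, axis=0), neg])
            y = np.r_[np.ones(4), -np.ones(6)]
            svm.fit(x, y)
            oracle.append(
                svm.decision_function([pos[k]])[0] / np.linalg.norm(svm.coef_)
            )
        for k in range(6):
            svm = SVC(kernel="linear", C=1.0)
            x = np.vstack([pos, np.delete(neg, k, axis=0)])
            y = np.r_[np.ones(5), -np.ones(5)]
            svm.fit(x, y)
            oracle.append(
                svm.decision_function([neg[k]])[0] / np.linalg.norm(svm.coef_)
            )
        assert np.allclose(table.s, oracle, atol=1e-9)

    def test_needs_two_per_class(self):
        with pytest.raises(InsufficientClassError):
            loo_svalues([[1.0]], [[-1.0], [-2.0]])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4], [1, 2]).auc == pytest.approx(1.0)

    def test_identical_multisets_chance(self):
        assert roc_auc([1, 2, 3], [1, 2, 3]).auc == pytest.approx(0.5)

    def test_hand_counted_pairs(self):
        # 3 of 4 (pos, neg) pairs win
        assert roc_auc([0.9, 0.2], [0.5, 0.1]).auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        roc = roc_auc(rng.normal(1, 1, 20), rng.normal(0, 1, 25))
        assert roc.tpr[0] == 0 and roc.fpr[0] == 0
        assert roc.tpr[-1] == 1 and roc.fpr[-1] == 1
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=200)
    def test_equals_pair_counting_oracle_with_ties(self, pos, neg):
        # integer scores force many exact ties
        assert roc_auc(pos, neg).auc == pytest.approx(
            pair_count_auc(pos, neg), abs=1e-12
        )

    @given(
        pos=st.lists(st.integers(-50, 50), min_size=1, max_size=15),
        neg=st.lists(st.integers(-50, 50), min_size=1, max_size=15),
        scale=st.floats(0.1, 4.0),
        shift=st.floats(-3, 3),
    )
    @settings(deadline=None, max_examples=100)
    def test_invariant_under_increasing_transform(self, pos, neg, scale, shift):
        # affine map with positive slope preserves the score ordering; scores
        # on a 0.1 grid keep the transform exactly order-preserving in floats
        f = lambda x: scale * (np.asarray(x) / 10.0) + shift
        assert roc_auc(f(pos), f(neg)).auc == pytest.approx(
            roc_auc(pos, neg).auc, abs=1e-9
        )

    def test_agrees_with_sklearn(self, rng):
        pos = rng.normal(0.5, 1, 30)
        neg = rng.normal(0, 1, 40)
        y = np.r_[np.ones(30), np.zeros(40)]
        assert roc_auc(pos, neg).auc == pytest.approx(
            roc_auc_score(y, np.r_[pos, neg]), abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_auc([], [1.0])


class TestPercentCorrect:
    def test_perfect_separation_both_modes(self):
        assert percent_correct([1, 2], [-1, -2], "svm") == 1.0
        assert percent_correct([1, 2], [-1, -2], "optimal") == 1.0

    def test_optimal_threshold_scan(self):
        assert percent_correct([0.9, 0.2], [0.5, 0.1], "optimal") == pytest.approx(0.75)

    @given(
        pos=st.lists(st.floats(-3, 3), min_size=1, max_size=10),
        neg=st.lists(st.floats(-3, 3), min_size=1, max_size=10),
    )
    @settings(deadline=None, max_examples=100)
    def test_optimal_dominates_fixed_criterion(self, pos, neg):
        assert percent_correct(pos, neg, "optimal") >= percent_correct(
            pos, neg, "svm"
        )


class TestAmplitudeBaselineAndShapeOnly:
    def test_separated_epoch_means(self):
        pos = np.array([[1.0, 1.0], [0.8, 0.8]])
        neg = np.array([[0.2, 0.2], [0.4, 0.4]])
        assert amplitude_auc(pos, neg).auc == 1.0

    def test_identical_epochs_chance(self, rng):
        x = rng.normal(size=(5, 10))
        assert amplitude_auc(x, x).auc == pytest.approx(0.5)

    def test_amplitude_auc_blind_to_shape(self, rng):
        # mean-subtracted epochs carry no amplitude information: exact chance
        # (integer epochs with sums divisible by the width keep the
        # subtraction exact, so every score is exactly 0)
        x = rng.integers(-8, 8, size=(6, 4)).astype(float)
        y = rng.integers(-8, 8, size=(7, 4)).astype(float)
        x[:, -1] -= x.sum(axis=1) % 4
        y[:, -1] -= y.sum(axis=1) % 4
        assert amplitude_auc(shape_only(x), shape_only(y)).auc == 0.5

    def test_shape_only_rows(self):
        assert np.allclose(shape_only(np.array([[1.0, 2.0, 3.0]])), [[-1, 0, 1]])
        assert np.allclose(shape_only(np.array([[2.0, 2.0]])), [[0, 0]])
        z = np.array([[-1.0, 0.0, 1.0]])
        assert np.allclose(shape_only(z), z)


def _table(s_pos, s_neg, ids=None):
    s = np.r_[s_pos, s_neg]
    cls = np.r_[np.ones(len(s_pos)), -np.ones(len(s_neg))]
    ids = np.arange(s.size) if ids is None else np.asarray(ids)
    return SValueTable(trial_ids=ids, true_class=cls, s=s)


class TestPooling:
    def test_single_channel_identity(self):
        t = _table([1.0, 2.0], [-1.0, 0.5])
        assert pool_channels([t]).auc == roc_auc(t.s_pos, t.s_neg).auc

    def test_two_channel_sum(self):
        t1 = _table([2.0], [0.0])
        t2 = _table([1.0], [-1.0])
        # pooled pos {3}, neg {-1}
        assert pool_channels([t1, t2]).auc == pytest.approx(1.0)

    def test_zero_channel_leaves_auc_unchanged(self, rng):
        t1 = _table(rng.normal(1, 1, 5), rng.normal(0, 1, 5))
        t0 = _table(np.zeros(5), np.zeros(5), ids=t1.trial_ids)
        assert pool_channels([t1, t0]).auc == pytest.approx(
            pool_channels([t1]).auc
        )

    def test_trial_mismatch_rejected(self):
        t1 = _table([1.0], [0.0], ids=[0, 1])
        t2 = _table([1.0], [0.0], ids=[0, 2])
        with pytest.raises(MisalignedChannelsError):
            pool_channels([t1, t2])


class TestSequentialOptimal:
    def test_single_channel(self):
        t = _table([1.0, 2.0], [-1.0, 0.0])
        subset, auc = sequential_optimal([t])
        assert subset == [0]
        assert auc == roc_auc(t.s_pos, t.s_neg).auc

    def test_harmful_channel_excluded(self):
        # ch0 perfect; ch1 anticorrelated and larger: pooling hurts
        t0 = _table([10.0, 11.0], [0.0, 1.0])
        t1 = _table([-10.0, -12.0], [0.0, 2.0])
        pooled_auc = pool_channels([t0, t1]).auc
        subset, auc = sequential_optimal([t0, t1])
        assert pooled_auc < 1.0
        assert subset == [0]
        assert auc == pytest.approx(1.0)

    def test_optimal_at_least_full_pool(self, rng):
        tables = [
            _table(rng.normal(0.5, 1, 8), rng.normal(0, 1, 8)) for _ in range(4)
        ]
        for t in tables[1:]:
            t.trial_ids = tables[0].trial_ids
        _, auc = sequential_optimal(tables)
        assert auc >= pool_channels(tables).auc - 1e-12
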