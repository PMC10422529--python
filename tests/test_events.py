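"""Derivative scoring, event labelling and the Mann-Whitney AUC."""

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st
from sklearn.metrics import roc_auc_score

from ipmap import (
    DEFAULT_EVENT_HALF_WINDOW_S,
    ParameterSeries,
    ValidationError,
    auc_grid,
    derivative,
    enumerate_configurations,
    label_samples,
    roc_auc,
    scores_and_labels,
)


def series(values, frequency=1.0):
    return ParameterSeries("peak_pressure", np.asarray(values, float), frequency)


class TestDerivative:
    def test_constant_series_gives_zero_magnitudes(self):
        d = derivative(series([5.0] * 6))
        assert np.all(d.magnitudes == 0)
        assert len(d) == 5

    def test_hand_computed_step(self):
        d = derivative(series([0.0, 0.0, 10.0, 10.0]))
        np.testing.assert_array_equal(d.magnitudes, [0.0, 10.0, 0.0])
        np.testing.assert_array_equal(d.times, [0.5, 1.5, 2.5])

    @given(st.integers(1, 8), st.floats(1.0, 50.0))
    def test_step_response_max_equals_step_height(self, at, height):
        values = np.zeros(10)
        values[at:] = height
        d = derivative(series(values))
        assert d.magnitudes.max() == pytest.approx(height)

    def test_missing_values_propagate(self):
        d = derivative(series([1.0, np.nan, 1.0, 1.0]))
        assert np.isnan(d.magnitudes[0]) and np.isnan(d.magnitudes[1])
        assert d.magnitudes[2] == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            derivative(series([1.0]))


class TestLabelSamples:
    def test_window_arithmetic_at_explicit_tolerance(self):
        # one event at 62.5 s in a 1 Hz recording, +-5 s window
        d = derivative(series(np.zeros(126)))
        labels = label_samples(d, [62.5], tolerance=5.0)
        assert labels.sum() == 11  # midpoints 57.5 .. 67.5
        assert labels[57] == 1 and labels[67] == 1 and labels[56] == 0

    def test_default_tolerance_covers_the_transition(self):
        d = derivative(series(np.zeros(126)))
        labels = label_samples(d, [62.5])
        assert labels.sum() == 5  # half-transition window: midpoints 60.5..64.5
        d10 = derivative(series(np.zeros(13), frequency=0.1))
        # at 0.1 Hz the window widens to one 10 s sample interval
        assert label_samples(d10, [62.5]).sum() == 2

    def test_zero_tolerance_labels_at_most_one_sample_per_event(self):
        d = derivative(series(np.zeros(20)))
        assert label_samples(d, [7.5], tolerance=0.0).sum() == 1
        assert label_samples(d, [7.3], tolerance=0.0).sum() == 0

    def test_event_outside_span_rejected(self):
        d = derivative(series(np.zeros(10)))
        with pytest.raises(ValidationError, match="outside"):
            label_samples(d, [60.0])

    def test_no_events_rejected(self):
        d = derivative(series(np.zeros(10)))
        with pytest.raises(ValidationError, match="degenerate"):
            label_samples(d, [])


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc(np.array([1.0, 2.0, 10.0, 11.0]), np.array([0, 0, 1, 1]))
        assert r.auc == 1.0

    def test_all_ties_is_chance(self):
        r = roc_auc(np.full(10, 3.0), np.array([1] * 5 + [0] * 5))
        assert r.auc == 0.5

    def test_hand_enumerated_pairs(self):
        # positives {3, 1}, negatives {2, 0}: 3 of 4 pairs won
        r = roc_auc(np.array([3.0, 1.0, 2.0, 0.0]), np.array([1, 1, 0, 0]))
        assert r.auc == 0.75

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=50),
        st.data(),
    )
    def test_matches_pair_counting_oracle_with_ties(self, score_ints, data):
        n = len(score_ints)
        labels = np.array(
            data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        )
        if labels.sum() in (0, n):
            return
        scores = np.array(score_ints, dtype=float)
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.lists(st.floats(0.0, 100.0), min_size=4, max_size=30, unique=True))
    def test_invariant_under_increasing_transform(self, values):
        scores = np.array(values)
        transformed = np.exp(scores / 50.0)
        # the transform must stay injective in floating point
        assume(len(np.unique(transformed)) == len(np.unique(scores)))
        labels = (np.arange(len(scores)) % 2).astype(int)
        a = roc_auc(scores, labels).auc
        b = roc_auc(transformed, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_curve_runs_from_origin_to_unity_monotonically(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.3).astype(int)
        curve = roc_auc(scores, labels).curve
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_nan_scores_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.array([np.nan, 2.0]), np.array([1, 0]))


class TestAucGrid:
    def test_grid_cardinality_and_range(self, small_cohort):
        rows, cols = small_cohort[0].shape
        configs = enumerate_configurations(
            rows, cols, blocks=(1, 5), decimations=(1, 10)
        )
        grid = auc_grid(small_cohort, configs)
        assert len(grid) == 4 * 7
        assert grid["auc"].between(0, 1).all()
        assert set(grid["n_sensors"]) == {5664, 207}

    def test_native_config_separates_cop_long(self, small_cohort):
        grid = auc_grid(
            small_cohort,
            enumerate_configurations(118, 48, blocks=(1,), decimations=(1,)),
        )
        cop_long = grid[grid["parameter"] == "cop_long"]["auc"].iloc[0]
        assert cop_long > 0.9

    def test_shuffled_labels_give_chance_auc(self, small_cohort, balanced_cohort):
        """Permuting labels against scores destroys discrimination."""
        rng = np.random.default_rng(42)
        scores, labels = [], []
        for seq in small_cohort + balanced_cohort:
            s, l = scores_and_labels(seq, block=1, decimation=1)["cop_long"]
            scores.append(s)
            labels.append(l)
        scores = np.concatenate(scores)
        labels = np.concatenate(labels)
        assert len(scores) >= 500  # permutation null is tight at this size
        r = roc_auc(scores, rng.permutation(labels))
        assert abs(r.auc - 0.5) < 0.05
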