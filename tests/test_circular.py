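"""Strategy angles, circular descriptives, Rao's spacing test, histogram."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from srtkit.circular import (
    angular_histogram,
    circular_mean,
    circular_median,
    circular_summary,
    classify_strategy,
    normalize_angle,
    rao_spacing_statistic,
    rao_spacing_test,
    session_angles,
    strategy_angle,
)
from srtkit.discrimination import trial_scores
from srtkit.trial_data import DesignError

from conftest import make_trial

d2s = st.floats(min_value=-1.0, max_value=1.0, allow_nan=False)


def brute_force_rao(angles):
    """Direct-definition oracle: explicit sorted gaps including the wrap."""
    a = sorted(x % 360.0 for x in angles)
    n = len(a)
    gaps = [a[i + 1] - a[i] for i in range(n - 1)] + [360.0 - a[-1] + a[0]]
    lam = 360.0 / n
    return 0.5 * sum(abs(g - lam) for g in gaps)


class TestStrategyAngle:
    def test_equal_positive_preference_is_exactly_45(self):
        assert strategy_angle(0.5, 0.5) == pytest.approx(45.0, abs=1e-12)

    def test_zero_zero_is_undefined(self):
        assert strategy_angle(0.0, 0.0) is None

    @settings(max_examples=200, derandomize=True)
    @given(d2s, d2s)
    def test_negating_both_inputs_rotates_by_180(self, a, b):
        fwd = strategy_angle(a, b)
        rev = strategy_angle(-a, -b)
        if fwd is None:
            assert rev is None
        else:
            assert abs(normalize_angle(rev - fwd - 180.0)) < 1e-9

    def test_range_is_half_open_at_minus_180(self):
        assert strategy_angle(0.0, -1.0) == 180.0
        assert normalize_angle(225.0) == -135.0
        assert normalize_angle(315.0) == -45.0
        assert normalize_angle(-180.0) == 180.0


class TestCircularDescriptives:
    def test_coincident_angles(self):
        s = circular_summary([30.0, 30.0, 30.0])
        assert s.mean_direction == pytest.approx(30.0)
        assert s.resultant_length == pytest.approx(1.0)

    def test_antipodal_angles_have_no_mean_direction(self):
        mean, r = circular_mean([0.0, 180.0])
        assert mean is None
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair(self):
        mean, r = circular_mean([0.0, 90.0])
        assert mean == pytest.approx(45.0)
        assert r == pytest.approx(math.sqrt(2) / 2)

    def test_against_scipy_circular_routines(self, rng):
        angles = rng.uniform(-180, 180, 25)
        mean, r = circular_mean(angles)
        ref_mean = math.degrees(
            sps.circmean(np.radians(angles), high=math.pi, low=-math.pi))
        ref_r = 1.0 - sps.circvar(np.radians(angles))
        assert normalize_angle(mean - ref_mean) == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(ref_r, abs=1e-12)

    def test_circular_median_on_clustered_data(self):
        # median of a symmetric cluster sits at its centre point
        assert circular_median([40.0, 50.0, 60.0]) == pytest.approx(50.0)

    def test_rotation_equivariance(self, rng):
        angles = rng.uniform(-180, 180, 15)
        shift = 73.0
        m0, r0 = circular_mean(angles)
        m1, r1 = circular_mean(angles + shift)
        assert normalize_angle(m1 - m0 - shift) == pytest.approx(0.0, abs=1e-9)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert rao_spacing_statistic(angles + shift) == pytest.approx(
            rao_spacing_statistic(angles), abs=1e-9)


class TestRaoSpacing:
    def test_even_spacing_gives_zero(self):
        assert rao_spacing_statistic([0.0, 90.0, 180.0, 270.0]) == pytest.approx(0.0)

    def test_coincident_angles_give_maximum(self):
        n = 4
        assert rao_spacing_statistic([10.0] * n) == pytest.approx(360.0 * (1 - 1 / n))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            angles = rng.uniform(0, 360, n)
            assert rao_spacing_statistic(angles) == pytest.approx(
                brute_force_rao(angles), abs=1e-9)

    def test_statistic_needs_two_angles(self):
        with pytest.raises(ValueError):
            rao_spacing_statistic([10.0])

    def test_uniformly_spaced_angles_do_not_reject(self):
        angles = np.arange(16) * 22.5
        res = rao_spacing_test(angles, n_mc=5000, seed=0)
        assert res.p > 0.99
        assert not res.reject

    def test_coincident_angles_reject_strongly(self):
        res = rao_spacing_test([42.0] * 20, n_mc=5000, seed=0)
        assert res.p < 0.001
        assert res.reject

    def test_deterministic_given_seed(self, rng):
        angles = rng.uniform(0, 360, 20)
        a = rao_spacing_test(angles, n_mc=2000, seed=99)
        b = rao_spacing_test(angles, n_mc=2000, seed=99)
        assert (a.p, a.critical_value) == (b.p, b.critical_value)

    def test_refuses_below_four_angles(self):
        with pytest.raises(ValueError):
            rao_spacing_test([0.0, 10.0, 20.0])


class TestAngularHistogram:
    def test_worked_example_angles_land_in_their_bins(self):
        counts, edges = angular_histogram([36.0, -56.0])
        assert counts.sum() == 2
        assert counts[np.searchsorted(edges, 36.0, side="right") - 1] == 1
        assert counts[np.searchsorted(edges, -56.0, side="right") - 1] == 1

    def test_counts_sum_to_n(self, rng):
        angles = rng.uniform(-180, 180, 57)
        counts, edges = angular_histogram(angles)
        assert counts.sum() == 57
        assert len(edges) == 17

    def test_edge_angle_goes_to_upper_bin(self):
        counts, edges = angular_histogram([-157.5])
        assert counts[1] == 1 and counts[0] == 0

    def test_plus_180_wraps_to_first_bin(self):
        counts, _ = angular_histogram([180.0])
        assert counts[0] == 1

    def test_non_divisor_width_rejected(self):
        with pytest.raises(ValueError):
            angular_histogram([0.0], bin_width=50.0)


class TestClassifyStrategy:
    @pytest.mark.parametrize("angle, label, dist", [
        (36.0, "context_novel", 9.0),
        (-56.0, "recency_novel", 11.0),
        (140.0, "recency_familiar", 5.0),
        (-130.0, "context_familiar", 5.0),
    ])
    def test_nearest_ideal_direction(self, angle, label, dist):
        c = classify_strategy(angle)
        assert c.label == label
        assert c.distance == pytest.approx(dist)

    def test_axis_angle_is_reported_as_single_trial_type_preference(self):
        c = classify_strategy(90.0)
        assert c.label is None
        assert c.axis_note == "first_context_trials_only"
        assert c.distance == pytest.approx(45.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_equal_preference_both_types_is_context_novel(self, d):
        assert classify_strategy(strategy_angle(d, d)).label == "context_novel"

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.05, max_value=1.0),
           st.floats(min_value=0.05, max_value=1.0))
    def test_negating_first_context_d2_swaps_context_and_recency(self, a, b):
        base = classify_strategy(strategy_angle(a, b)).label
        flipped = classify_strategy(strategy_angle(-a, b)).label
        assert base == "context_novel"
        assert flipped == "recency_novel"


class TestSessionAngles:
    def test_complete_cohort_yields_two_points_per_animal(self, object_cohort):
        from srtkit.discrimination import score_cohort

        points = session_angles(score_cohort(object_cohort))
        assert len(points) == 20
        assert {p.pair_index for p in points} == {1, 2}

    def test_missing_trial_drops_one_point(self):
        scores = [
            trial_scores(make_trial("test_in_first", trial=1)),
            trial_scores(make_trial("test_in_second", trial=2)),
            trial_scores(make_trial("test_in_second", trial=3)),
        ]
        with pytest.warns(UserWarning, match="incomplete"):
            points = session_angles(scores)
        assert len(points) == 1

    def test_pair_of_same_trial_type_is_design_error(self):
        scores = [
            trial_scores(make_trial("test_in_first", trial=1)),
            trial_scores(make_trial("test_in_first", trial=2)),
        ]
        with pytest.raises(DesignError):
            session_angles(scores)

    def test_zero_zero_pair_dropped_with_warning(self):
        scores = [
            trial_scores(make_trial("test_in_first", t1=0.0, t2=0.0, trial=1)),
            trial_scores(make_trial("test_in_second", trial=2)),
        ]
        with pytest.warns(UserWarning):
            assert session_angles(scores) == []
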