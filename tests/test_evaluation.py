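"""Agreement metrics: hand-checked examples, oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radarvitals.evaluation import (
    RatePairSeries,
    agreement_report,
    bland_altman,
    mae,
    mape,
    recall,
    spearman,
    uncovered_duration,
    within_tolerance,
)
from radarvitals.motion import EpochGrid

from .oracles import spearman_bruteforce

GRID = EpochGrid()


def _pairs(ref, rad):
    return RatePairSeries(GRID, ref, rad)


class TestMae:
    def test_identical_series_is_zero(self):
        assert mae(_pairs([12, 13], [12, 13])) == 0.0

    def test_hand_example(self):
        assert mae(_pairs([10, 12], [11, 12])) == pytest.approx(0.5)

    def test_symmetric(self, rng):
        a, b = rng.uniform(10, 20, 30), rng.uniform(10, 20, 30)
        assert mae(_pairs(a, b)) == pytest.approx(mae(_pairs(b, a)))

    def test_missing_epochs_are_ignored(self):
        assert mae(_pairs([10, None, 12], [11, 13, None])) == pytest.approx(1.0)

    def test_no_complete_pairs_is_undefined(self):
        assert mae(_pairs([None, 10], [10, None])) is None

    def test_bounded_by_max_difference(self, rng):
        a, b = rng.uniform(10, 20, 50), rng.uniform(10, 20, 50)
        assert mae(_pairs(a, b)) <= np.max(np.abs(a - b)) + 1e-12


class TestMape:
    def test_identical_series_is_zero_percent(self):
        assert mape(_pairs([12, 13], [12, 13])) == 0.0

    def test_hand_example(self):
        assert mape(_pairs([10, 20], [11, 19])) == pytest.approx(7.5)

    def test_not_symmetric(self):
        assert mape(_pairs([10], [20])) != mape(_pairs([20], [10]))

    def test_zero_reference_is_undefined(self):
        assert mape(_pairs([0.0, 10.0], [1.0, 10.0])) is None

    def test_relative_scaling_identity(self, rng):
        ref = rng.uniform(10, 20, 40)
        eps = 0.03
        assert mape(_pairs(ref, ref * (1 + eps))) == pytest.approx(100 * eps)


class TestSpearman:
    def test_monotone_relation_is_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(_pairs(x, np.exp(x))) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        assert spearman(_pairs([1, 2, 3, 4], [8, 6, 4, 2])) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert spearman(_pairs([1, 2, 3, 4], [1, 3, 2, 4])) == pytest.approx(0.8)

    def test_matches_bruteforce_rank_implementation(self, rng):
        for _ in range(100):
            x = rng.integers(0, 10, 20).astype(float)  # ties included
            y = rng.integers(0, 10, 20).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(_pairs(x, y)) == pytest.approx(
                spearman_bruteforce(x, y), abs=1e-12
            )

    def test_zero_rank_variance_is_undefined(self):
        assert spearman(_pairs([5, 5, 5], [1, 2, 3])) is None


class TestRecall:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (163_999, 175_425, 93.49),
            (128_728, 175_425, 73.38),
            (143_582, 175_425, 81.85),
            (34_963, 175_425, 19.93),
            (164_393, 175_425, 93.71),
        ],
    )
    def test_two_decimal_presentation_rounding(self, count, total, expected):
        assert round(recall(count, total), 2) == expected

    def test_zero_hits(self):
        assert recall(0, 100) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            recall(5, 0)
        with pytest.raises(ValueError):
            recall(6, 5)


class TestWithinTolerance:
    def test_identical_series_is_100(self):
        pct, count = within_tolerance(_pairs([10, 11], [10, 11]))
        assert (pct, count) == (100.0, 2)

    def test_boundary_is_strict(self):
        pct, count = within_tolerance(
            _pairs([10.0, 10.0, 10.0], [10.5, 11.0, 11.5])
        )
        assert count == 1  # the exact 1.0 difference is excluded
        assert pct == pytest.approx(100.0 / 3.0)

    def test_zero_tolerance_requires_equality(self):
        pct, _ = within_tolerance(_pairs([10, 11], [10, 11.2]), tol_bpm=0.0)
        assert pct == 0.0


class TestUncoveredDuration:
    def test_full_coverage_is_zero(self):
        assert uncovered_duration(np.ones(49, bool), GRID) == 0.0

    def test_no_coverage_is_everything(self):
        d = uncovered_duration(np.zeros(49, bool), GRID, total_duration_s=300.0)
        assert d == 300.0

    def test_two_disjoint_epochs(self):
        starts = np.array([0.0, 120.0])
        d = uncovered_duration(
            np.array([True, True]), GRID, total_duration_s=300.0, epoch_starts=starts
        )
        assert d == pytest.approx(180.0)

    def test_overlap_is_not_double_counted(self):
        starts = np.array([0.0, 5.0, 10.0])
        d = uncovered_duration(
            np.ones(3, bool), GRID, total_duration_s=100.0, epoch_starts=starts
        )
        assert d == pytest.approx(100.0 - 70.0)


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman(_pairs([10, 12, 14], [10, 12, 14]))
        assert ba["mean_diff"] == 0.0
        assert ba["loa_low"] == ba["loa_high"] == 0.0
        assert ba["pct_below"] == ba["pct_above"] == 0.0

    def test_hand_example_plus_minus_one(self):
        ba = bland_altman(_pairs([10.0, 10.0], [11.0, 9.0]))
        assert ba["mean_diff"] == 0.0
        assert ba["loa_high"] == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-6)
        assert ba["loa_low"] == pytest.approx(-1.96 * np.sqrt(2.0), abs=1e-6)

    def test_outside_percentages_sum_below_100(self, rng):
        ref, rad = rng.uniform(50, 90, 200), rng.uniform(50, 90, 200)
        ba = bland_altman(_pairs(ref, rad))
        assert ba["pct_below"] + ba["pct_above"] <= 100.0

    def test_sign_convention_is_reference_minus_radar(self):
        ba = bland_altman(_pairs([10.0, 10.0], [12.0, 12.0]))
        assert ba["mean_diff"] == -2.0  # radar overestimates -> negative

    def test_single_pair_is_undefined(self):
        assert bland_altman(_pairs([10.0, None], [10.0, 11.0])) is None


class TestAgreementReport:
    def test_counts_and_percentages_reconcile(self, rng):
        n = 400
        ref = np.where(rng.uniform(size=n) < 0.9, rng.uniform(10, 20, n), np.nan)
        rad = np.where(rng.uniform(size=n) < 0.7, ref + rng.normal(0, 1, n), np.nan)
        rep = agreement_report(RatePairSeries(GRID, ref, rad))
        assert round(100.0 * rep.recall_psg_count / n, 2) == round(rep.recall_psg, 2)
        assert round(100.0 * rep.recall_radar_count / n, 2) == round(
            rep.recall_radar, 2
        )
        assert rep.mae is not None and rep.bland_altman is not None

    def test_epoch_reordering_leaves_metrics_unchanged(self, rng):
        n = 60
        ref = rng.uniform(10, 20, n)
        rad = ref + rng.normal(0, 0.5, n)
        perm = rng.permutation(n)
        a = agreement_report(RatePairSeries(GRID, ref, rad))
        b = agreement_report(RatePairSeries(GRID, ref[perm], rad[perm]))
        assert a.mae == pytest.approx(b.mae)
        assert a.mape == pytest.approx(b.mape)
        assert a.spearman_rho == pytest.approx(b.spearman_rho)
        assert a.within_1bpm == pytest.approx(b.within_1bpm)

    def test_undefined_metrics_propagate_as_none(self):
        rep = agreement_report(
            RatePairSeries(GRID, [None, 10.0], [12.0, None])
        )
        assert rep.mae is None and rep.mape is None
        assert rep.spearman_rho is None and rep.bland_altman is None
        assert rep.recall_psg == 50.0

    @given(scale=st.floats(0.5, 2.0))
    @settings(max_examples=20, deadline=None)
    def test_mae_scales_linearly_with_differences(self, scale):
        ref = np.array([10.0, 14.0, 18.0])
        rad = ref + np.array([1.0, -2.0, 0.5])
        base = mae(_pairs(ref, rad))
        scaled = mae(_pairs(ref, ref + scale * (rad - ref)))
        assert scaled == pytest.approx(scale * base)
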