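import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emtstrat import (
    ValidationError,
    assign_strata,
    compare_groups,
    euclidean_cutpoint,
    median_split,
    roc_points,
    spearman,
    tps_split,
    tumor_volume,
)
from helpers_oracle import cutpoint_oracle


class TestMedianSplit:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4], ["low", "low", "high", "high"]),
            ([5, 5, 5, 5], ["low"] * 4),
            ([1, 2, 3], ["low", "low", "high"]),  # median itself goes low
        ],
    )
    def test_tie_policy(self, values, expected):
        assert median_split(values).tolist() == expected

    def test_missing_left_unassigned(self):
        out = median_split([1.0, np.nan, 3.0, 4.0])
        assert out.isna().tolist() == [False, True, False, False]

    def test_all_missing_errors(self):
        with pytest.raises(ValidationError):
            median_split([np.nan, np.nan])

    def test_partition_with_high_never_larger(self, rng):
        for _ in range(50):
            vals = rng.integers(0, 5, size=rng.integers(2, 30)).astype(float)
            out = median_split(vals)
            assert (out == "high").sum() <= (out == "low").sum()
            assert ((out == "high") | (out == "low")).all()


class TestTpsSplit:
    @pytest.mark.parametrize("tps,cutoff,expected", [(1, 1, "high"), (0, 1, "low"), (50, 50, "high")])
    def test_inclusive_boundary(self, tps, cutoff, expected):
        assert tps_split([tps], cutoff=cutoff).iloc[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            tps_split([120.0])


class TestAssignStrata:
    def test_combined_labels(self):
        out = assign_strata(pd.Series(["high", "low", None]), pd.Series(["low", "low", "high"]))
        assert out["combined"].tolist()[:2] == ["PD-L1-high/EMT-low", "PD-L1-low/EMT-low"]
        assert pd.isna(out["combined"].iloc[2])


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected_rho",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # rank correlation by hand
        ],
    )
    def test_examples(self, x, y, expected_rho):
        rho, p = spearman(x, y)
        assert rho == pytest.approx(expected_rho)
        assert 0 <= p <= 1

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)

    def test_pairwise_complete_and_min_n(self):
        rho, _ = spearman([1, 2, np.nan, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            spearman([1, 2], [1, 2])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman(x, y)[0]
        assert spearman(np.exp(x), y**3)[0] == pytest.approx(base)


class TestCompareGroups:
    def test_identical_groups_mann_whitney_p_one(self):
        cmp = compare_groups([1, 2, 3], [1, 2, 3], method="mann_whitney")
        assert cmp.p_value == pytest.approx(1.0)

    def test_identical_groups_t_statistic_zero(self):
        cmp = compare_groups([1, 2, 3], [1, 2, 3], method="t_test")
        assert cmp.statistic == 0.0
        assert cmp.p_value == pytest.approx(1.0)

    def test_separated_groups_significant_welch(self):
        cmp = compare_groups([1, 2], [101, 102], method="t_test")
        # Welch t computed directly: t = -100 / sqrt(0.5/2 + 0.5/2)
        assert cmp.statistic == pytest.approx(-100 / np.sqrt(0.5))
        assert cmp.p_value < 0.05

    def test_insufficient_n_errors(self):
        with pytest.raises(ValidationError):
            compare_groups([1], [2, 3], method="t_test")


class TestROC:
    def test_perfect_separation(self):
        pts = roc_points([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).set_index("threshold")
        assert pts.loc[0.5, "sensitivity"] == 1.0
        assert pts.loc[0.5, "specificity"] == 1.0

    def test_sentinel_thresholds(self):
        pts = roc_points([1, 2, 3], [0, 1, 1])
        below, above = pts.iloc[0], pts.iloc[-1]
        assert (below["sensitivity"], below["specificity"]) == (1.0, 0.0)
        assert (above["sensitivity"], above["specificity"]) == (0.0, 1.0)

    def test_monotone_in_threshold(self, rng):
        marker = rng.normal(size=60)
        outcome = rng.integers(0, 2, size=60)
        outcome[:2] = [0, 1]
        pts = roc_points(marker, outcome)
        assert (np.diff(pts["sensitivity"]) <= 1e-12).all()
        assert (np.diff(pts["specificity"]) >= -1e-12).all()

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            roc_points([1, 2, 3], [1, 1, 1])


class TestEuclideanCutpoint:
    def test_perfect_marker_distance_zero(self):
        cp = euclidean_cutpoint([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert cp.distance == 0.0
        assert cp.threshold == 0.5

    def test_small_example_matches_enumeration(self):
        t, sens, spec, dist = cutpoint_oracle([1, 2, 3], [0, 1, 0])
        cp = euclidean_cutpoint([1, 2, 3], [0, 1, 0])
        assert (cp.threshold, cp.sensitivity, cp.specificity, cp.distance) == (t, sens, spec, dist)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 51))
            marker = np.round(rng.normal(size=n), 1)
            outcome = rng.integers(0, 2, size=n)
            outcome[:2] = [0, 1]
            t, sens, spec, dist = cutpoint_oracle(marker, outcome)
            cp = euclidean_cutpoint(marker, outcome)
            assert (cp.threshold, cp.sensitivity, cp.specificity, cp.distance) == (t, sens, spec, dist)

    def test_uninformative_marker_no_crash(self, rng):
        marker = rng.normal(size=200)
        outcome = rng.integers(0, 2, size=200)
        outcome[:2] = [0, 1]
        cp = euclidean_cutpoint(marker, outcome)
        assert 0.0 <= cp.distance <= np.sqrt(2)

    def test_low_predicts_event_direction(self):
        # low marker calls the event; the returned rule is marker <= threshold
        cp = euclidean_cutpoint([10, 20, 80, 90], [1, 1, 0, 0], higher_predicts_event=False)
        assert cp.direction == "<="
        assert cp.distance == 0.0
        assert 20 < cp.threshold < 80


class TestTumorVolume:
    @pytest.mark.parametrize("longest,shortest,expected", [(10, 5, 125.0), (6, 6, 108.0), (0, 0, 0.0)])
    def test_formula(self, longest, shortest, expected):
        assert tumor_volume(longest, shortest) == expected

    def test_negative_errors_and_swap_warns(self):
        with pytest.raises(ValidationError):
            tumor_volume(-1, 1)
        with pytest.warns(UserWarning, match="swapped"):
            tumor_volume(5, 10)
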