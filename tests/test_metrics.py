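"""Imbalance statistics, cutoff schedule and predictability."""

import itertools

import numpy as np
import pytest

from minimsim import (
    ImbalanceRule,
    MarginalTable,
    binary_factor,
    classification_counts,
    imbalance_cutoff,
    factor_imbalance_percent,
    load_worked_example,
    make_design,
    overall_imbalance_percent,
    predictability_fraction,
    run_trial,
    sample_cohort,
    trial_flags,
)
from minimsim.minimisation import TrialResult


class TestCutoffSchedule:
    @pytest.mark.parametrize(
        "n, cutoff",
        [(10, 40.0), (20, 20.0), (30, 10.0), (40, 10.0), (50, 5.0),
         (11, 20.0), (21, 10.0), (49, 10.0), (1000, 5.0)],
    )
    def test_schedule(self, n, cutoff):
        assert imbalance_cutoff(n) == cutoff

    def test_non_increasing_in_n(self):
        cutoffs = [imbalance_cutoff(n) for n in range(1, 200)]
        assert all(a >= b for a, b in zip(cutoffs, cutoffs[1:]))

    def test_rule_threshold_validated(self):
        with pytest.raises(ValueError, match="chance_threshold"):
            ImbalanceRule(chance_threshold=1.5)


class TestOverallImbalance:
    @pytest.mark.parametrize(
        "totals, n, expected",
        [((27, 23), 50, 8.0), ((25, 25), 50, 0.0), ((20, 17, 13), 50, 14.0)],
    )
    def test_values(self, totals, n, expected):
        assert overall_imbalance_percent(totals, n) == pytest.approx(expected)

    def test_minimal_flagged_split_at_50(self):
        assert overall_imbalance_percent((27, 23), 50) >= imbalance_cutoff(50)

    def test_relabelling_invariance(self):
        totals = (20, 17, 13)
        values = {
            overall_imbalance_percent(perm, 50)
            for perm in itertools.permutations(totals)
        }
        assert len(values) == 1

    def test_totals_must_sum_to_n(self):
        with pytest.raises(ValueError, match="sum"):
            overall_imbalance_percent((10, 10), 50)


def _brute_force_factor_imbalance(counts: np.ndarray, totals: np.ndarray) -> float:
    """Independent loop over every (category, arm pair) combination."""
    best = 0.0
    for c in range(counts.shape[0]):
        for i in range(counts.shape[1]):
            for j in range(counts.shape[1]):
                diff = abs(
                    100.0 * counts[c, i] / totals[i] - 100.0 * counts[c, j] / totals[j]
                )
                best = max(best, diff)
    return best


class TestFactorImbalance:
    def test_equal_proportions_zero(self):
        table = MarginalTable.from_counts([[[14, 11], [14, 11]]])
        assert factor_imbalance_percent(table, 0) == pytest.approx(0.0)

    def test_worked_example_age_band(self):
        """Age >= 80: 4 of 10 in group A vs 1 of 10 in group B -> 30 points."""
        table, _ = load_worked_example()
        assert factor_imbalance_percent(table, 1) == pytest.approx(30.0)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(50):
            arms = int(rng.integers(2, 5))
            k = int(rng.integers(2, 5))
            counts = rng.integers(1, 10, size=(k, arms))
            table = MarginalTable.from_counts([counts])
            expected = _brute_force_factor_imbalance(counts, counts.sum(axis=0))
            assert factor_imbalance_percent(table, 0) == pytest.approx(expected)

    def test_category_and_arm_relabelling_invariance(self, rng):
        counts = rng.integers(1, 9, size=(3, 2))
        base = factor_imbalance_percent(MarginalTable.from_counts([counts]), 0)
        for perm in itertools.permutations(range(3)):
            for arm_perm in itertools.permutations(range(2)):
                shuffled = counts[list(perm)][:, list(arm_perm)]
                table = MarginalTable.from_counts([shuffled])
                assert factor_imbalance_percent(table, 0) == pytest.approx(base)

    def test_empty_arm_reports_maximal_with_warning(self):
        table = MarginalTable.from_counts([[[2, 0], [1, 0]]])
        with pytest.warns(UserWarning, match="empty arm"):
            assert factor_imbalance_percent(table, 0) == 100.0


class TestTrialFlags:
    def test_balanced_trial_not_flagged(self, rng):
        d = make_design(2, 50, 1.0, [binary_factor()])
        result = run_trial(d, sample_cohort(d, rng), rng)
        flags = trial_flags(result)
        # P=1 with one binary factor confines every count difference to 1
        assert not flags.overall_imbalanced
        assert not flags.any_factor_imbalanced

    def test_minimal_flagged_split_overall_only(self):
        d = make_design(2, 50, 1.0, [binary_factor()])
        counts = np.array([[14, 12], [13, 11]])  # arm totals 27:23
        table = MarginalTable.from_counts([counts])
        result = TrialResult(d, (), table)
        flags = trial_flags(result)
        assert flags.overall_imbalanced
        assert flags.max_overall_percent == pytest.approx(8.0)
        assert not flags.any_factor_imbalanced

    def test_flags_from_replayed_log_agree(self, rng):
        d = make_design(3, 30, 0.7, [binary_factor(), binary_factor("g", 0.3)])
        result = run_trial(d, sample_cohort(d, rng), rng)
        replayed = TrialResult(d, result.records, result.replay_table())
        assert trial_flags(replayed) == trial_flags(result)

    def test_incomplete_trial_rejected(self):
        d = make_design(2, 50, 1.0, [binary_factor()])
        result = TrialResult(d, (), MarginalTable.for_design(d))
        with pytest.raises(ValueError, match="incomplete"):
            trial_flags(result)


class TestPredictability:
    def test_all_ties_zero(self, rng):
        d = make_design(2, 1, 1.0, [binary_factor()])
        result = run_trial(d, sample_cohort(d, rng), rng)
        assert predictability_fraction(result.records) == 0.0

    def test_complement_of_ties_at_p1(self, rng):
        d = make_design(2, 100, 1.0, [binary_factor(), binary_factor("g")])
        result = run_trial(d, sample_cohort(d, rng), rng)
        counts = classification_counts(result.records)
        assert counts["twist"] == 0
        assert predictability_fraction(result.records) == pytest.approx(
            1.0 - counts["tie"] / 100
        )

    def test_single_deterministic_record(self, rng):
        from minimsim import allocate, load_worked_example

        table, patient = load_worked_example()
        rec = allocate(table, patient, 1.0, rng)
        assert predictability_fraction([rec]) == 1.0

    def test_empty_records_error(self):
        with pytest.raises(ValueError, match="empty"):
            predictability_fraction([])
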