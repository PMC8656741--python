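"""Validation statistics: AUC/DeLong, verdicts, calibration, cutoffs, incidence."""

import numpy as np
import pytest
from scipy import stats as sps

from _oracles import oracle_auc
from nephrisk.errors import InvalidInputError, PairingError, TrainingError
from nephrisk.stats import (
    auc,
    calibration_by_quintile,
    confusion_metrics,
    delong_compare,
    incidence_density,
    verdict_from_summary,
    youden_cutoff,
)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).auc == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_hand_counted_pairs(self):
        # events {0.9, 0.8, 0.7}, non-events {0.75, 0.2}: 5 of 6 concordant
        r = auc([0.9, 0.8, 0.7, 0.75, 0.2], [1, 1, 1, 0, 0])
        assert r.auc == pytest.approx(5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # force ties
            assert auc(scores, labels).auc == pytest.approx(
                oracle_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=500)
        scores = rng.uniform(size=500) + 0.3 * labels
        assert auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=300)
        scores = rng.uniform(size=300) + 0.4 * labels
        r = auc(scores, labels)
        assert r.ci_lower <= r.auc <= r.ci_upper
        assert r.acceptable == (r.auc > 0.70)


class TestDeLongCompare:
    def test_identical_scores_non_inferior_not_superior(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=100)
        scores = rng.uniform(size=100)
        r = delong_compare(scores, scores, labels)
        assert r.delta == 0.0
        assert r.verdict == "non-inferior"
        assert r.p_value == 1.0

    def test_clearly_better_candidate_is_superior(self):
        rng = np.random.default_rng(1)
        n = 600
        labels = rng.integers(0, 2, size=n)
        good = labels + rng.normal(0, 0.4, size=n)  # strong signal
        noise = rng.uniform(size=n)  # no signal
        r = delong_compare(good, noise, labels)
        assert r.delta > 0.05
        assert r.p_value < 0.05
        assert r.verdict == "superior"

    def test_clearly_worse_candidate_is_inferior(self):
        rng = np.random.default_rng(2)
        n = 600
        labels = rng.integers(0, 2, size=n)
        good = labels + rng.normal(0, 0.4, size=n)
        noise = rng.uniform(size=n)
        r = delong_compare(noise, good, labels)
        assert r.verdict == "inferior"

    def test_length_mismatch_rejected(self):
        with pytest.raises(PairingError):
            delong_compare([0.1, 0.2], [0.1], [1, 0])

    def test_null_rejection_rate_is_nominal(self):
        """Under H0 (two independent uninformative scores) the two-sided
        DeLong test rejects at 5% within Monte-Carlo tolerance."""
        rng = np.random.default_rng(20_24)
        reps = 2000
        n = 120
        rejections = 0
        for _ in range(reps):
            labels = np.zeros(n, dtype=int)
            labels[: n // 3] = 1
            a = rng.uniform(size=n)
            b = rng.uniform(size=n)
            if delong_compare(a, b, labels).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestVerdictFixtures:
    """Fixed-sequence verdicts reproduce published summary classifications.

    Deltas below are candidate-minus-comparator (published tables often
    print the opposite sign convention)."""

    @pytest.mark.parametrize(
        "delta,p,expected",
        [
            (0.146, 0.0016, "superior"),  # short-horizon, strong candidate lead
            (0.149, 0.0013, "superior"),
            (-0.012, 0.3255, "non-inferior"),
            (-0.016, 0.2220, "non-inferior"),
            (-0.020, 0.0483, "non-inferior"),  # significant but tiny deficit
            (-0.018, 0.0888, "non-inferior"),
            (-0.030, 0.0105, "non-inferior"),
            (-0.027, 0.0246, "non-inferior"),
        ],
    )
    def test_published_summary_verdicts(self, delta, p, expected):
        assert verdict_from_summary(delta, p) == expected

    def test_deficit_beyond_margin_is_inferior(self):
        assert verdict_from_summary(-0.08, 0.001) == "inferior"

    def test_large_delta_without_significance_stays_non_inferior(self):
        assert verdict_from_summary(0.10, 0.20) == "non-inferior"


class TestCalibration:
    def test_quintile_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(size=103)
        labels = rng.integers(0, 2, size=103)
        chart = calibration_by_quintile(scores, labels)
        assert max(chart.n) - min(chart.n) <= 1
        assert sum(chart.n) == 103

    def test_event_shares_sum_to_one(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(size=200)
        labels = (rng.uniform(size=200) < scores).astype(int)
        chart = calibration_by_quintile(scores, labels)
        assert sum(chart.event_share) == pytest.approx(1.0, abs=1e-9)

    def test_constant_zero_outcome(self):
        chart = calibration_by_quintile(np.linspace(0, 1, 50), np.zeros(50))
        assert all(i == 0.0 for i in chart.incidence)

    def test_ten_records_two_per_bin(self):
        chart = calibration_by_quintile(np.arange(10) / 10, np.zeros(10))
        assert chart.n == (2, 2, 2, 2, 2)

    def test_ties_stay_in_one_bin(self):
        scores = np.array([0.1] * 8 + [0.9, 0.95])
        chart = calibration_by_quintile(scores, np.zeros(10))
        assert chart.n[0] == 8

    def test_calibrated_scores_match_incidence_per_quintile(self):
        """Sampling outcomes from the scores themselves: observed incidence
        tracks the mean score in every quintile."""
        rng = np.random.default_rng(10)
        n = 20_000
        scores = rng.beta(2, 5, size=n)
        labels = (rng.uniform(size=n) < scores).astype(int)
        chart = calibration_by_quintile(scores, labels)
        for ms, inc in zip(chart.mean_score, chart.incidence):
            assert inc == pytest.approx(ms, abs=0.02)


class TestCutoffs:
    def test_separable_data_perfect_youden(self):
        m = youden_cutoff([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.youden == pytest.approx(1.0)

    def test_exhaustive_grid_hand_example(self):
        # events {8,9,10}, non-events {1,2,7} -> cutoff 7, rule score > cutoff
        m = youden_cutoff([8, 9, 10, 1, 2, 7], [1, 1, 1, 0, 0, 0])
        assert m.cutoff == 7
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0

    def test_uninformative_scores_near_zero_youden(self):
        rng = np.random.default_rng(11)
        scores = np.round(rng.uniform(size=400), 2)
        labels = rng.integers(0, 2, size=400)
        assert youden_cutoff(scores, labels).youden < 0.2

    def test_confusion_metric_arithmetic(self):
        m = confusion_metrics(17, 83, 2, 98)
        assert m.ppv == pytest.approx(0.17)
        assert m.false_omission_rate == pytest.approx(0.02)
        ideal = confusion_metrics(10, 0, 0, 10)
        assert ideal.ppv == 1.0 and ideal.false_omission_rate == 0.0
        assert ideal.sensitivity == 1.0 and ideal.specificity == 1.0

    def test_zero_denominator_marks_undefined(self):
        m = confusion_metrics(0, 0, 5, 5)
        assert np.isnan(m.ppv)
        assert m.false_omission_rate == pytest.approx(0.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion_metrics(-1, 0, 0, 0)


class TestIncidence:
    def test_chi_square_quantile_oracle(self):
        est = incidence_density(10, 500)
        assert est.rate_per_100py == pytest.approx(2.0)
        lo = sps.chi2.ppf(0.025, 20) / 2 / 500 * 100
        hi = sps.chi2.ppf(0.975, 22) / 2 / 500 * 100
        assert est.ci_lower == pytest.approx(lo)
        assert est.ci_upper == pytest.approx(hi)
        assert est.ci_lower == pytest.approx(0.96, abs=0.01)
        assert est.ci_upper == pytest.approx(3.68, abs=0.01)

    def test_zero_events(self):
        est = incidence_density(0, 100)
        assert est.rate_per_100py == 0.0
        assert est.ci_lower == 0.0
        assert est.ci_upper > 0.0

    def test_scale_equivariance(self):
        a = incidence_density(10, 500)
        b = incidence_density(10, 1000)
        assert b.rate_per_100py == pytest.approx(a.rate_per_100py / 2)
        assert b.ci_lower == pytest.approx(a.ci_lower / 2)
        assert b.ci_upper == pytest.approx(a.ci_upper / 2)

    def test_coverage_in_simulation(self):
        """Exact Poisson CIs cover the true rate at >= 93% (rate 5/100py)."""
        rng = np.random.default_rng(13)
        true_rate = 5.0
        py = 400.0
        covered = 0
        reps = 1000
        for _ in range(reps):
            events = rng.poisson(true_rate * py / 100)
            est = incidence_density(int(events), py)
            if est.ci_lower <= true_rate <= est.ci_upper:
                covered += 1
        assert covered / reps >= 0.93

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            incidence_density(-1, 100)
        with pytest.raises(InvalidInputError):
            incidence_density(5, 0)
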