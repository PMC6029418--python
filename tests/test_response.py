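import numpy as np
import pytest
from scipy.stats import norm

from mixpop.cohort import PatientRecord
from mixpop.response import (
    anova_trend,
    classify_patients,
    decision_curve,
    survival_bins,
    years_per_log2,
)
from mixpop.simulate import SyntheticConfig, generate_clinical, sample_mixture


def rec(pid, treatment="chemo_only", time=6.0, outcome="alive_at_last_followup"):
    return PatientRecord(pid, treatment=treatment, survival_time=time, outcome=outcome)


class TestClassification:
    def test_paper_rules(self):
        records = [
            rec("died_early", time=3.0, outcome="died_of_disease"),
            rec("other_cause", time=3.0, outcome="died_other_cause"),
            rec("short_followup", time=4.0, outcome="alive_at_last_followup"),
            rec("long_survivor", time=8.0, outcome="alive_at_last_followup"),
            rec("late_death", time=7.0, outcome="died_of_disease"),
            rec("wrong_arm", treatment="none", time=3.0, outcome="died_of_disease"),
        ]
        cls = classify_patients(records)
        got = dict(zip(cls.patient_ids, zip(cls.status, cls.reason)))
        assert got["died_early"] == ("resistant", "none")
        assert got["other_cause"] == ("excluded", "died_other_cause_lt5y")
        assert got["short_followup"] == ("excluded", "followup_lt5y")
        assert got["long_survivor"] == ("sensitive", "none")
        assert got["late_death"] == ("sensitive", "none")
        assert got["wrong_arm"] == ("excluded", "not_in_arm")

    def test_exactly_five_years_is_sensitive(self):
        cls = classify_patients([rec("P", time=5.0, outcome="died_of_disease")])
        assert cls.status[0] == "sensitive"

    def test_excluded_iff_reason(self):
        records = [
            rec(f"P{i}", time=t, outcome=o)
            for i, (t, o) in enumerate(
                [(1, "died_of_disease"), (2, "died_other_cause"),
                 (3, "alive_at_last_followup"), (9, "died_of_disease")]
            )
        ]
        cls = classify_patients(records)
        for s, r in zip(cls.status, cls.reason):
            assert (s == "excluded") == (r != "none")


class TestSurvivalBins:
    def test_all_long_survivors_fill_only_final_bin(self):
        records = [rec(f"P{i}", time=6 + i) for i in range(5)]
        bins = survival_bins(records, np.arange(5.0))
        assert [b.n for b in bins] == [0, 0, 0, 0, 0, 5]
        assert bins[-1].label == ">5"

    def test_death_in_first_half_year_lands_in_year_one_bin(self):
        records = [rec("P", time=0.5, outcome="died_of_disease"),
                   rec("Q", time=6.0)]
        bins = survival_bins(records, np.array([6.0, 8.0]))
        assert bins[0].n == 1
        assert bins[0].mean == pytest.approx(6.0)

    def test_chemo_bin_means_rise_with_survival(self):
        """Under the default generator the chemo arm's mean expression
        increases from early-death bins to long survivors (20 seeds)."""
        wins = 0
        for seed in range(20):
            cfg = SyntheticConfig(n_patients=1980, seed=seed)
            values, labels = sample_mixture(cfg)
            recs = generate_clinical(cfg, values, labels)
            bins = survival_bins(recs, values)
            populated = [b.mean for b in bins if b.n >= 3]
            if len(populated) >= 3 and populated[-1] > populated[0]:
                wins += 1
        assert wins >= 16

    def test_untreated_arm_shows_no_trend(self):
        """Slope is zero outside the chemo arm: trend p uniform."""
        from scipy.stats import kstest

        ps = []
        for seed in range(40):
            cfg = SyntheticConfig(n_patients=1500, seed=seed)
            values, labels = sample_mixture(cfg)
            recs = generate_clinical(cfg, values, labels)
            bins = survival_bins(recs, values, arm="none")
            _, trend = anova_trend(bins)
            ps.append(trend.p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestAnovaTrend:
    def _mk(self, groups):
        from mixpop.response import BinSummary

        return [
            BinSummary(label=str(i + 1), n=len(g), mean=float(np.mean(g)),
                       values=np.asarray(g, float))
            for i, g in enumerate(groups)
        ]

    def test_identical_constant_bins(self):
        anova, trend = anova_trend(self._mk([[2, 2, 2], [2, 2, 2]]))
        assert anova.statistic == 0.0
        assert anova.p == 1.0
        assert trend.p == 1.0

    def test_hand_computed_two_bin_example(self):
        # SSB = 13.5, MSW = 1 -> F = 13.5 on (1, 4) df, p = 0.0213
        anova, _ = anova_trend(self._mk([[1, 2, 3], [4, 5, 6]]))
        assert anova.statistic == pytest.approx(13.5, abs=1e-9)
        assert anova.df == (1, 4)
        assert anova.p == pytest.approx(0.0213, abs=5e-4)

    def test_linear_pattern_favors_trend_over_omnibus(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(mu, 0.5, 12) for mu in (1, 1.35, 1.7, 2.05)]
        anova, trend = anova_trend(self._mk(groups))
        assert trend.p < anova.p

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            anova_trend(self._mk([[1, 2, 3]]))


class TestDecisionCurve:
    def test_perfect_separation(self):
        values = np.array([5.0, 5.5, 5.9, 7.1, 7.5, 8.0])
        status = np.array(
            ["resistant"] * 3 + ["sensitive"] * 3, dtype=object
        )
        dc = decision_curve(values, status, grid=[6.5])
        assert dc.sensitivity[0] == 1.0
        assert dc.specificity[0] == 1.0

    def test_chance_performance_crosses_at_half(self):
        rng = np.random.default_rng(1)
        values = rng.normal(7, 1, 4000)
        status = np.array(
            ["resistant"] * 2000 + ["sensitive"] * 2000, dtype=object
        )
        dc = decision_curve(values, status)
        assert dc.crossover_value == pytest.approx(0.5, abs=0.03)

    def test_symmetric_normal_closed_form(self):
        """Equal classes from N(6, 0.5) and N(7, 0.5) cross at the
        midpoint 6.5 with common rate Phi(1) = 0.841."""
        rng = np.random.default_rng(2)
        n = 20_000
        values = np.concatenate(
            [rng.normal(6.0, 0.5, n), rng.normal(7.0, 0.5, n)]
        )
        status = np.array(["resistant"] * n + ["sensitive"] * n, dtype=object)
        dc = decision_curve(values, status)
        assert dc.crossover_cutoff == pytest.approx(6.5, abs=0.05)
        assert dc.crossover_value == pytest.approx(norm.cdf(1.0), abs=0.02)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        values = rng.normal(7, 1, 400)
        status = np.array(
            ["resistant"] * 200 + ["sensitive"] * 200, dtype=object
        )
        grid = np.linspace(0, 14, 200)
        dc = decision_curve(values, status, grid=grid)
        assert dc.sensitivity[0] == 0.0 and dc.sensitivity[-1] == 1.0
        assert dc.specificity[0] == 1.0 and dc.specificity[-1] == 0.0
        assert np.all(np.diff(dc.sensitivity) >= 0)
        assert np.all(np.diff(dc.specificity) <= 0)

    def test_crossover_interpolation_is_exact(self):
        rng = np.random.default_rng(4)
        values = np.concatenate(
            [rng.normal(6, 0.5, 500), rng.normal(7, 0.5, 500)]
        )
        status = np.array(["resistant"] * 500 + ["sensitive"] * 500, dtype=object)
        dc = decision_curve(values, status)
        s = np.interp(dc.crossover_cutoff, dc.cutoffs, dc.sensitivity)
        q = np.interp(dc.crossover_cutoff, dc.cutoffs, dc.specificity)
        assert abs(s - q) <= 1e-9

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            decision_curve(
                np.array([1.0, 2.0]), np.array(["resistant", "resistant"], dtype=object)
            )


class TestYearsPerLog2:
    def test_exact_linear_relation_inverts_slope(self):
        from mixpop.response import BinSummary

        # mean expression rises 0.4 log2 units per survival year
        bins = [
            BinSummary(str(k), 5, 6.0 + 0.4 * (k - 0.5), np.zeros(5))
            for k in range(1, 6)
        ]
        bins.append(BinSummary(">5", 5, 9.0, np.zeros(5)))
        assert years_per_log2(bins) == pytest.approx(2.5, abs=1e-9)
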