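import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import lapsepipe as lp
from lapsepipe.period_inference import AT_OR_ABOVE_SESOI, BELOW_SESOI

TABLE1 = [(6_107_869, 301_995_418), (830_424, 41_255_775), (13_129_965, 652_436_314)]
TABLE9 = [(454_676, 123_897_496), (118_497, 41_255_775), (2_297_449, 652_436_314)]


class TestPeriodConfig:
    def test_default_valid(self):
        lp.PeriodConfig()

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            lp.PeriodConfig(
                periods={"a": ("2020-01", "2020-06"), "b": ("2020-05", "2020-12")}
            )

    def test_overlap_only_on_excluded_month_ok(self):
        lp.PeriodConfig(
            periods={"a": ("2020-01", "2020-03"), "b": ("2020-03", "2020-06")},
            excluded_months=("2020-03",),
        )

    def test_bad_sesoi(self):
        with pytest.raises(ValueError, match="sesoi"):
            lp.PeriodConfig(sesoi=0.0)


class TestAssignPeriod:
    @pytest.mark.parametrize(
        "ts,expected",
        [
            ("2020-04-15", "peak_covid"),
            ("2020-03-10", "excluded"),
            ("2020-02-29", "pre_covid"),
            ("2019-01-01", "pre_covid"),
            ("2020-06-01", "post_peak"),
            ("2022-12-31T23:59:59", "post_peak"),
            ("2018-12-31", "out_of_scope"),
            ("2023-01-01", "out_of_scope"),
        ],
    )
    def test_default_labels(self, ts, expected):
        assert lp.assign_period([pd.Timestamp(ts)]).tolist() == [expected]


class TestMonthlyRates:
    def _frame(self, month_flags):
        rows, flags = [], []
        i = 0
        for month, flag_list in month_flags.items():
            for flag in flag_list:
                rows.append(
                    ("L1", "I1", "M1", pd.Timestamp(f"{month}-15") + pd.Timedelta(minutes=i))
                )
                flags.append(flag)
                i += 1
        records = pd.DataFrame(rows, columns=["learner_id", "item_id", "module_id", "start_time"])
        return records, pd.Series(flags, dtype=bool)

    def test_unweighted_mean_ignores_volume(self):
        records, flags = self._frame(
            {"2020-01": [True] + [False] * 99, "2020-02": [True] * 3 + [False] * 97}
        )
        monthly, mean = lp.monthly_rates(flags, records)
        assert monthly["rate"].tolist() == pytest.approx([0.01, 0.03])
        assert mean == pytest.approx(0.02)
        # quadruple the volume of one month: pooled monthly rates unchanged
        records2, flags2 = self._frame(
            {"2020-01": ([True] + [False] * 99) * 4, "2020-02": [True] * 3 + [False] * 97}
        )
        _, mean2 = lp.monthly_rates(flags2, records2)
        assert mean2 == pytest.approx(0.02)

    def test_single_month_mean_is_pooled_rate(self):
        records, flags = self._frame({"2021-07": [True, False, False, False]})
        monthly, mean = lp.monthly_rates(flags, records)
        assert mean == monthly["rate"].iloc[0] == 0.25

    def test_constant_pi_within_binomial_band(self):
        pi = 0.06
        cfg = lp.GeneratorConfig(
            n_learners=150,
            n_modules=8,
            items_per_module=10,
            interruption_prob=pi,
            calendar_start="2020-01",
            calendar_end="2020-12",
            seed=37,
        )
        log = lp.generate(cfg)
        monthly, _ = lp.monthly_rates(log.truth["injected"], log.records)
        for _, row in monthly.iterrows():
            se = math.sqrt(pi * (1 - pi) / row["total"])
            assert abs(row["rate"] - pi) < 3 * se


class TestEqualProportionsTest:
    def test_identical_proportions_zero(self):
        chi2, df, p = lp.equal_proportions_test([(10, 100), (20, 200)])
        assert chi2 == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_pearson(self):
        chi2, df, _ = lp.equal_proportions_test([(30, 100), (20, 100)])
        assert chi2 == pytest.approx(8 / 3)
        assert df == 1

    def test_printed_study1_statistic(self):
        chi2, df, p = lp.equal_proportions_test(TABLE1)
        assert round(chi2, 2) == 107.16
        assert df == 2
        assert p < 1e-16

    def test_printed_study5_statistic(self):
        chi2, _, _ = lp.equal_proportions_test(TABLE9)
        assert round(chi2, 1) == 5723.6

    def test_degenerate_pooled_proportion_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            chi2, _, p = lp.equal_proportions_test([(0, 100), (0, 200)])
        assert chi2 == 0.0

    def test_continuity_correction_matches_scipy(self):
        counts = [(30, 100), (20, 100)]
        chi2, _, _ = lp.equal_proportions_test(counts, correction=True)
        table = np.array([[f, t - f] for f, t in counts])
        expected = chi2_contingency(table, correction=True).statistic
        assert chi2 == pytest.approx(expected)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            lp.equal_proportions_test([(1, 10)])
        with pytest.raises(ValueError):
            lp.equal_proportions_test([(1, 0), (1, 10)])
        with pytest.raises(ValueError):
            lp.equal_proportions_test([(11, 10), (1, 10)])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 10_000), st.integers(1, 10_000)).map(
                lambda t: (min(t), max(t))
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_scipy_oracle_sweep(self, counts):
        flagged = sum(f for f, _ in counts)
        total = sum(t for _, t in counts)
        table = np.array([[f, t - f] for f, t in counts])
        if flagged == 0 or flagged == total:
            with pytest.warns(UserWarning):
                chi2, df, _ = lp.equal_proportions_test(counts)
            assert chi2 == 0.0
            return
        chi2, df, p = lp.equal_proportions_test(counts)
        res = chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(res.statistic, rel=1e-10, abs=1e-10)
        assert df == res.dof
        assert p == pytest.approx(res.pvalue, rel=1e-8, abs=1e-12)


class TestCohensH:
    def test_equal_proportions_zero(self):
        assert lp.cohens_h(0.3, 0.3) == 0.0

    def test_printed_table1(self):
        p1 = TABLE1[0][0] / TABLE1[0][1]
        p2 = TABLE1[1][0] / TABLE1[1][1]
        assert round(lp.cohens_h(p1, p2), 5) == 0.00069

    def test_direct_evaluation(self):
        expected = 2 * math.asin(0.5) - 2 * math.asin(0.4)
        assert lp.cohens_h(0.25, 0.16) == pytest.approx(expected)
        assert round(lp.cohens_h(0.25, 0.16), 5) == 0.22416

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lp.cohens_h(1.2, 0.5)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
    )
    def test_antisymmetry_and_range(self, p1, p2):
        h = lp.cohens_h(p1, p2)
        assert h == pytest.approx(-lp.cohens_h(p2, p1))
        assert abs(h) <= math.pi + 1e-12


class TestSesoiVerdict:
    def test_tiny_effect_below(self):
        assert lp.sesoi_verdict(0.0007, 0.5) == BELOW_SESOI

    def test_absolute_value_used(self):
        assert lp.sesoi_verdict(-0.6, 0.5) == AT_OR_ABOVE_SESOI

    def test_boundary_inclusive(self):
        assert lp.sesoi_verdict(0.3, 0.3) == AT_OR_ABOVE_SESOI

    def test_bad_sesoi(self):
        with pytest.raises(ValueError):
            lp.sesoi_verdict(0.1, 0.0)


class TestCombineRates:
    def test_printed_study2_plus_study5(self):
        assert lp.combine_rates(0.02855, 0.00351) == pytest.approx(0.03206)

    def test_printed_study4_plus_study5(self):
        assert lp.combine_rates(0.01214, 0.00351) == pytest.approx(0.01565)

    def test_zero(self):
        assert lp.combine_rates(0.0, 0.0) == 0.0


class TestPeriodReport:
    def test_pooled_rates_consistent_with_flags(self, default_log):
        rec = default_log.records
        thr = lp.make_thresholds(lp.compute_stats(rec))
        cls = lp.classify(rec, thr)
        report = lp.period_report(cls.flags, rec)
        labels = lp.assign_period(rec.loc[cls.flags.index, "start_time"])
        labels.index = cls.flags.index
        for period, row in report.period_table.iterrows():
            mask = labels == period
            assert row["flagged"] == int(cls.flags[mask].sum())
            assert row["total"] == int(mask.sum())
            assert row["rate"] == row["flagged"] / row["total"]
        assert report.df == len(report.period_table) - 1
        assert len(report.pairwise_h) == math.comb(len(report.period_table), 2)
        assert set(report.pairwise_h["verdict"]) <= {BELOW_SESOI, AT_OR_ABOVE_SESOI}

    def test_step_change_recovers_h(self):
        pi1, pi2 = 0.02, 0.12
        common = dict(n_learners=120, n_modules=6, items_per_module=8)
        log1 = lp.generate(
            lp.GeneratorConfig(
                **common, interruption_prob=pi1,
                calendar_start="2019-01", calendar_end="2020-02", seed=41,
            )
        )
        log2 = lp.generate(
            lp.GeneratorConfig(
                **common, interruption_prob=pi2,
                calendar_start="2020-04", calendar_end="2020-05", seed=43,
            )
        )
        records = pd.concat([log1.records, log2.records], ignore_index=True)
        flags = pd.concat([log1.truth, log2.truth], ignore_index=True)["injected"]
        report = lp.period_report(flags, records)
        expected = 2 * math.asin(math.sqrt(pi1)) - 2 * math.asin(math.sqrt(pi2))
        pair = report.pairwise_h.set_index(["period_1", "period_2"]).loc[
            ("pre_covid", "peak_covid"), "h"
        ]
        # ~12k draws per period: h has standard error ~0.01 on this size
        assert pair == pytest.approx(expected, abs=0.03)

    def test_seasonal_periods_config(self, default_log):
        config = lp.PeriodConfig(periods=dict(lp.period_inference.SEASONAL_PERIODS),
                                 excluded_months=())
        report = lp.period_report(default_log.truth["injected"], default_log.records, config)
        assert set(report.period_table.index) <= set(lp.period_inference.SEASONAL_PERIODS)
        assert report.df == len(report.period_table) - 1
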