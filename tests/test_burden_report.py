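"""Catastrophic-expenditure rule, stratum summaries, ratios, breakdowns,
and the arm-comparison statistics."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from screenburden.burden_report import (
    ArmReport,
    CostSummary,
    accumulated_cost_curves,
    arm_totals_and_ratio,
    build_arm_reports,
    che_totals_by_arm,
    classification_breakdown,
    compare_arms_table1,
    cost_factor_regression,
    is_catastrophic,
    percentage,
    site_group,
    summarize,
)
from screenburden.claims_model import Arm, Site
from screenburden.cohort_builder import PerfectCohort
from screenburden.cost_engine import CaseCosts, EconomicParams

from .conftest import make_case, make_episode, make_line_item, make_participant


class TestCatastrophicRule:
    def test_zero_oop_never_catastrophic(self, econ_params):
        assert not is_catastrophic(0.0, econ_params)

    def test_typical_cancer_oop_is_catastrophic(self, econ_params):
        # mean screening-arm esophageal out-of-pocket is ~5,972 USD against
        # a ~3,072 USD capacity to pay
        assert is_catastrophic(5972.0, econ_params)

    def test_boundary_is_strict(self, econ_params):
        boundary = econ_params.che_threshold * econ_params.capacity_to_pay_usd
        assert not is_catastrophic(boundary, econ_params)
        assert is_catastrophic(boundary + 0.01, econ_params)

    def test_raising_threshold_never_raises_count(self, econ_params, small_analysis):
        oops = [c.out_of_pocket_usd for c in small_analysis["costs"].values()]

        def count(threshold):
            p = EconomicParams(che_threshold=threshold)
            return sum(is_catastrophic(o, p) for o in oops)

        counts = [count(t) for t in (0.1, 0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)


class TestSummarize:
    def test_singleton(self):
        s = summarize([10.0])
        assert (s.mean, s.lower_quartile, s.upper_quartile) == (10, 10, 10)

    def test_linear_interpolation_quartiles(self):
        s = summarize([1, 2, 3, 4])
        assert s.mean == pytest.approx(2.5)
        assert s.lower_quartile == pytest.approx(1.75)
        assert s.upper_quartile == pytest.approx(3.25)

    def test_constant_list(self):
        s = summarize([7, 7, 7])
        assert s.mean == s.lower_quartile == s.upper_quartile == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


def _report(arm, group, total, n=10, che=5):
    s = CostSummary(n, 1.0, 1.0, 1.0)
    return ArmReport(arm, group, n, s, s, s, s, che, total)


class TestArmTotalsAndRatio:
    def test_printed_stratum_totals_reproduce_headline_ratios(self):
        reports = [
            _report(Arm.SCREENING, "esophageal", 1_045_119),
            _report(Arm.CONTROL, "esophageal", 428_292),
            _report(Arm.SCREENING, "gastric", 393_261),
            _report(Arm.CONTROL, "gastric", 351_557),
        ]
        ratios = arm_totals_and_ratio(reports)
        assert ratios["esophageal"] == 2.44
        assert ratios["gastric"] == 1.12

    def test_equal_totals_give_unity(self):
        reports = [_report(Arm.SCREENING, "esophageal", 5), _report(Arm.CONTROL, "esophageal", 5)]
        assert arm_totals_and_ratio(reports)["esophageal"] == 1.0

    def test_zero_control_total_is_undefined(self):
        reports = [_report(Arm.SCREENING, "esophageal", 5), _report(Arm.CONTROL, "esophageal", 0)]
        assert arm_totals_and_ratio(reports)["esophageal"] is None


def test_che_counts_sum_to_arm_totals():
    # the four stratum counts of the treatment-cost table
    reports = [
        _report(Arm.CONTROL, "esophageal", 1, n=24, che=21),
        _report(Arm.SCREENING, "esophageal", 1, n=82, che=80),
        _report(Arm.CONTROL, "gastric", 1, n=17, che=15),
        _report(Arm.SCREENING, "gastric", 1, n=24, che=23),
    ]
    totals = che_totals_by_arm(reports)
    assert totals[Arm.SCREENING] == 103
    assert totals[Arm.CONTROL] == 36


class TestSiteGroup:
    @pytest.mark.parametrize(
        "site,group",
        [
            (Site.ESOPHAGEAL, "esophageal"),
            (Site.CARDIAL, "gastric"),
            (Site.NON_CARDIAL_GASTRIC, "gastric"),
            (Site.DUODENAL, "other"),
        ],
    )
    def test_grouping(self, site, group):
        assert site_group(site) == group


class TestAccumulatedCurves:
    def test_single_case_curve_is_flat_after_first_month(self, econ_params):
        anchor = date(2018, 1, 5)
        p = make_participant("A")
        case = make_case("A", diagnosis=date(2018, 1, 1))
        eps = {"A": [make_episode("A", admission=anchor, total=3550, reimbursed=0, los=0)]}
        cohort = PerfectCohort(857, [case], [])
        curves = accumulated_cost_curves(
            cohort, eps, {"A": anchor}, {"A": p}, econ_params
        )
        series = curves[curves.site_group == "esophageal"].cumulative_cost_usd.to_numpy()
        assert series[0] == pytest.approx(1000.0)
        assert np.allclose(series, series[0])

    def test_final_point_equals_stratum_total(self, econ_params, small_analysis):
        curves = accumulated_cost_curves(
            small_analysis["cohort"],
            small_analysis["eps_by"],
            small_analysis["anchors"],
            small_analysis["pidx"],
            econ_params,
            window_months=12,
        )
        reports = build_arm_reports(
            small_analysis["treated"], small_analysis["costs"],
            small_analysis["pidx"], econ_params,
        )
        totals = {(r.arm.value, r.site_group): r.total_treatment_cost for r in reports}
        for (arm, group), sub in curves.groupby(["arm", "site_group"]):
            final = sub.sort_values("month").cumulative_cost_usd.iloc[-1]
            assert final == pytest.approx(totals[(arm, group)], rel=1e-9)

    def test_screening_curve_dominates_for_esophageal(self, econ_params, small_analysis):
        curves = accumulated_cost_curves(
            small_analysis["cohort"], small_analysis["eps_by"],
            small_analysis["anchors"], small_analysis["pidx"], econ_params,
        )
        ec = curves[curves.site_group == "esophageal"].pivot(
            index="month", columns="arm", values="cumulative_cost_usd"
        )
        assert (ec["screening"] > ec["control"]).all()


class TestClassificationBreakdown:
    def test_partition_identity_per_arm(self, econ_params, small_analysis):
        """Per arm, classification means sum to the mean hospitalization
        cost per case."""
        from screenburden.cohort_builder import window_episodes

        windowed = {
            pid: window_episodes(
                small_analysis["eps_by"][pid], small_analysis["anchors"][pid], 12
            )
            for pid in small_analysis["costs"]
        }
        table = classification_breakdown(
            small_analysis["treated"], windowed, small_analysis["pidx"], econ_params
        )
        costs = small_analysis["costs"]
        pidx = small_analysis["pidx"]
        for arm in ("screening", "control"):
            class_sum = table[table.arm == arm].mean_cost_per_case_usd.sum()
            arm_costs = [
                costs[c.participant_id].hospitalization_cost_usd
                for c in small_analysis["treated"]
                if pidx[c.participant_id].arm.value == arm
            ]
            assert class_sum == pytest.approx(np.mean(arm_costs), rel=1e-6)

    def test_radiation_only_in_one_arm(self, econ_params):
        participants = {
            "S1": make_participant("S1", arm=Arm.SCREENING),
            "C1": make_participant("C1", arm=Arm.CONTROL),
        }
        cases = [make_case("S1"), make_case("C1")]
        eps = {
            "S1": [make_episode("S1", line_items=(make_line_item("surgery", 1000),))],
            "C1": [make_episode("C1", line_items=(make_line_item("radiation", 2000),))],
        }
        table = classification_breakdown(cases, eps, participants, econ_params)
        rad = table[table.classification == "radiation"].set_index("arm")
        assert rad.loc["control", "mean_cost_per_case_usd"] > \
            rad.loc["screening", "mean_cost_per_case_usd"]

    def test_unknown_classification_bucketed_as_other(self, econ_params):
        participants = {"S1": make_participant("S1")}
        cases = [make_case("S1")]
        eps = {"S1": [make_episode("S1", line_items=(make_line_item("acupuncture", 10),))]}
        with pytest.warns(UserWarning, match="other"):
            table = classification_breakdown(cases, eps, participants, econ_params)
        assert "other" in set(table.classification)


class TestPercentageFormatter:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(58, 86, 67), (82, 106, 77), (240, 255, 94), (1, 200, 1), (1, 2, 50)],
    )
    def test_rounds_half_away_from_zero(self, num, den, expected):
        assert percentage(num, den) == expected


class TestCompareArms:
    def _cohort_from_sites(self, control_counts, screening_counts):
        participants, cases = {}, []
        i = 0
        for arm, counts in ((Arm.CONTROL, control_counts), (Arm.SCREENING, screening_counts)):
            for site, n in counts.items():
                for _ in range(n):
                    pid = f"P{i}"
                    i += 1
                    participants[pid] = make_participant(pid, arm=arm)
                    cases.append(make_case(pid, site=site))
        return PerfectCohort(857, cases, []), participants

    def test_site_distribution_chi_square(self):
        # counts (24, 9, 8) vs (82, 7, 17): chi2 = 8.060 on 2 df, p = 0.0178
        cohort, participants = self._cohort_from_sites(
            {"esophageal": 24, "cardial": 9, "non_cardial_gastric": 8},
            {"esophageal": 82, "cardial": 7, "non_cardial_gastric": 17},
        )
        table = compare_arms_table1(cohort, participants)
        p = table[table.covariate == "site"].p_value.dropna().iloc[0]
        assert p == pytest.approx(0.01777, abs=2e-4)
        assert p < 0.05

    def test_identical_arms_give_p_one(self):
        cohort, participants = self._cohort_from_sites(
            {"esophageal": 10, "cardial": 10}, {"esophageal": 10, "cardial": 10}
        )
        table = compare_arms_table1(cohort, participants)
        p = table[table.covariate == "site"].p_value.dropna().iloc[0]
        assert p == pytest.approx(1.0)

    def test_two_by_two_uncorrected_statistic(self):
        cohort, participants = self._cohort_from_sites(
            {"esophageal": 10, "cardial": 20}, {"esophageal": 20, "cardial": 10}
        )
        from scipy.stats import chi2_contingency

        chi2, _, _, _ = chi2_contingency([[10, 20], [20, 10]], correction=False)
        table = compare_arms_table1(cohort, participants)
        p = table[table.covariate == "site"].p_value.dropna().iloc[0]
        assert chi2 == pytest.approx(6.666667, abs=1e-4)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(6.666667, 1), abs=1e-6)

    def test_counts_and_percentages_formatted(self, econ_params, small_analysis):
        table = compare_arms_table1(
            small_analysis["cohort"], small_analysis["pidx"], small_analysis["eps_by"]
        )
        stage_rows = table[table.covariate == "stage"]
        assert not stage_rows.empty
        assert stage_rows.control.str.contains(r"\(\d+%\)").all()


class TestCostFactorRegression:
    def test_degenerate_outcome_rejected(self, econ_params):
        ccs = [CaseCosts(f"P{i}", 10000.0, 100.0, 9000.0, 10, 1) for i in range(20)]
        cov = pd.DataFrame({"age": range(20)})
        with pytest.raises(ValueError, match="degenerate outcome"):
            cost_factor_regression(ccs, cov, econ_params)

    def test_strong_effect_recovered(self, econ_params):
        """A true odds ratio of 5 at n=500 is estimated within [3, 8]."""
        rng = np.random.default_rng(42)
        x = rng.integers(0, 2, 500)
        logit = -0.5 + np.log(5.0) * x
        y = rng.random(500) < 1 / (1 + np.exp(-logit))
        ccs = [CaseCosts(f"P{i}", 1.0, 0.0, 0.0, 0, 0) for i in range(500)]
        table = cost_factor_regression(
            ccs, pd.DataFrame({"x": x.astype(float)}), econ_params, outcome=y
        )
        assert 3.0 <= table.odds_ratio.iloc[0] <= 8.0

    def test_null_covariate_ci_covers_one(self, econ_params):
        """Under the null the 95% CI contains OR=1 in at least 90 of 100
        seeded replicates."""
        rng = np.random.default_rng(7)
        covered = 0
        ccs = [CaseCosts(f"P{i}", 1.0, 0.0, 0.0, 0, 0) for i in range(500)]
        for _ in range(100):
            x = rng.normal(size=500)
            y = rng.random(500) < 0.3
            if y.min() == y.max():
                covered += 1
                continue
            table = cost_factor_regression(
                ccs, pd.DataFrame({"x": x}), econ_params, outcome=y
            )
            if table.ci_low.iloc[0] <= 1.0 <= table.ci_high.iloc[0]:
                covered += 1
        assert covered >= 90

    def test_perfect_separation_flagged(self, econ_params):
        y = np.array([0] * 10 + [1] * 10, dtype=bool)
        x = y.astype(float)  # separates perfectly
        ccs = [CaseCosts(f"P{i}", 1.0, 0.0, 0.0, 0, 0) for i in range(20)]
        table = cost_factor_regression(ccs, pd.DataFrame({"x": x}), econ_params, outcome=y)
        assert "separation" in table.note.iloc[0]
        assert np.isnan(table.odds_ratio.iloc[0])


def test_table2_identities_on_synthetic_strata(econ_params, small_analysis):
    """Treatment mean = time mean + hospitalization mean in every stratum,
    and the stratum total equals the sum of its case treatment costs."""
    reports = build_arm_reports(
        small_analysis["treated"], small_analysis["costs"],
        small_analysis["pidx"], econ_params,
    )
    assert reports
    for r in reports:
        assert r.treatment_cost.mean == pytest.approx(
            r.time_cost.mean + r.hospitalization_cost.mean, rel=1e-9
        )
        assert r.che_count <= r.n
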