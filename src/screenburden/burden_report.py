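"""Arm-level burden reporting: catastrophic-expenditure classification,
per-stratum cost summaries with skew-robust quartiles, arm totals and ratios,
accumulated-cost trajectories, expense-classification breakdowns, and the
baseline-comparison and cost-factor statistics.

Catastrophic health expenditure (CHE) follows the WHO operational rule:
out-of-pocket spending strictly exceeding 40% of the household's capacity to
pay, here proxied by the local per-capita disposable income.  Costs are
summarized as mean with lower/upper quartiles because hospitalization costs
are heavy-tailed; quartiles use linear interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .claims_model import (
    Arm,
    CancerCase,
    HospitalizationEpisode,
    NCMS_CLASSIFICATIONS,
    Participant,
    Site,
)
from .cohort_builder import DAYS_PER_MONTH, PerfectCohort
from .cost_engine import CaseCosts, EconomicParams, adjust_and_convert, time_cost

__all__ = [
    "CostSummary",
    "ArmReport",
    "site_group",
    "is_catastrophic",
    "summarize",
    "build_arm_reports",
    "arm_totals_and_ratio",
    "che_totals_by_arm",
    "accumulated_cost_curves",
    "classification_breakdown",
    "compare_arms_table1",
    "cost_factor_regression",
    "percentage",
]

#: Headline site groups: esophageal vs cardial + non-cardial gastric.
#: Rare other sites (duodenal) report under "other".
SITE_GROUPS = ("esophageal", "gastric", "other")


def site_group(site: Site) -> str:
    if site is Site.ESOPHAGEAL:
        return "esophageal"
    if site in (Site.CARDIAL, Site.NON_CARDIAL_GASTRIC):
        return "gastric"
    return "other"


def percentage(numerator: float, denominator: float) -> int:
    """Integer percentage, rounding half away from zero (report style)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def is_catastrophic(oop_usd: float, params: EconomicParams) -> bool:
    """CHE rule: out-of-pocket strictly exceeds threshold x capacity to pay,
    both in USD."""
    if oop_usd < 0:
        raise ValueError("out-of-pocket cost must be >= 0")
    return oop_usd > params.che_threshold * params.capacity_to_pay_usd


@dataclass(frozen=True)
class CostSummary:
    n: int
    mean: float
    lower_quartile: float
    upper_quartile: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("summary requires n >= 1")
        if self.lower_quartile > self.upper_quartile + 1e-9:
            raise ValueError("lower quartile above upper quartile")


def summarize(costs: Sequence[float]) -> CostSummary:
    """Mean with lower/upper quartiles (linear interpolation)."""
    arr = np.asarray(list(costs), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty cost list")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    return CostSummary(n=int(arr.size), mean=float(arr.mean()),
                       lower_quartile=float(q1), upper_quartile=float(q3))


@dataclass
class ArmReport:
    """Per-(arm, site-group) stratum of the treatment-cost table."""

    arm: Arm
    site_group: str
    n: int
    time_cost: CostSummary
    hospitalization_cost: CostSummary
    treatment_cost: CostSummary
    out_of_pocket: CostSummary
    che_count: int
    total_treatment_cost: float

    def __post_init__(self):
        if self.che_count > self.n:
            raise ValueError("CHE count cannot exceed stratum size")

    @property
    def che_fraction(self) -> float:
        return self.che_count / self.n


def build_arm_reports(
    cases: Sequence[CancerCase],
    costs_by_case: Mapping[str, CaseCosts],
    participants: Mapping[str, Participant],
    params: EconomicParams,
) -> list[ArmReport]:
    """Assemble the treatment-cost table strata from per-case costs."""
    buckets: dict[tuple[Arm, str], list[CaseCosts]] = {}
    for case in cases:
        cc = costs_by_case.get(case.participant_id)
        if cc is None:
            continue
        arm = participants[case.participant_id].arm
        buckets.setdefault((arm, site_group(case.site)), []).append(cc)

    reports = []
    for (arm, group), ccs in sorted(buckets.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        reports.append(
            ArmReport(
                arm=arm,
                site_group=group,
                n=len(ccs),
                time_cost=summarize([c.time_cost_usd for c in ccs]),
                hospitalization_cost=summarize([c.hospitalization_cost_usd for c in ccs]),
                treatment_cost=summarize([c.treatment_cost_usd for c in ccs]),
                out_of_pocket=summarize([c.out_of_pocket_usd for c in ccs]),
                che_count=sum(is_catastrophic(c.out_of_pocket_usd, params) for c in ccs),
                total_treatment_cost=float(sum(c.treatment_cost_usd for c in ccs)),
            )
        )
    return reports


def arm_totals_and_ratio(reports: Iterable[ArmReport]) -> dict[str, float | None]:
    """Screening-to-control ratio of total treatment cost per site group,
    rounded to 2 decimals; None where the control total is zero or a stratum
    is missing."""
    totals: dict[str, dict[Arm, float]] = {}
    for r in reports:
        totals.setdefault(r.site_group, {})[r.arm] = r.total_treatment_cost
    out: dict[str, float | None] = {}
    for group, by_arm in totals.items():
        s, c = by_arm.get(Arm.SCREENING), by_arm.get(Arm.CONTROL)
        out[group] = round(s / c, 2) if s is not None and c else None
    return out


def che_totals_by_arm(reports: Iterable[ArmReport]) -> dict[Arm, int]:
    """Families with catastrophic expenditure per arm, summed over strata."""
    out: dict[Arm, int] = {}
    for r in reports:
        out[r.arm] = out.get(r.arm, 0) + r.che_count
    return out


def accumulated_cost_curves(
    cohort: PerfectCohort,
    episodes_by_participant: Mapping[str, Sequence[HospitalizationEpisode]],
    anchors: Mapping[str, object],
    participants: Mapping[str, Participant],
    params: EconomicParams,
    window_months: int = 12,
) -> pd.DataFrame:
    """Cumulative stratum treatment cost (USD) over the observation window.

    Each in-window episode contributes its adjusted total expense plus its
    own time cost to the 30-day bin of its admission; curves are cumulative
    sums over months 1..window, so the final point of each stratum equals
    the stratum's total treatment cost exactly.  Columns: arm, site_group,
    month, cumulative_cost_usd.
    """
    from .cohort_builder import UntreatedCaseError, window_episodes

    monthly: dict[tuple[str, str], np.ndarray] = {}
    for case in cohort.included_cases:
        anchor = anchors.get(case.participant_id)
        if anchor is None:
            continue
        arm = participants[case.participant_id].arm.value
        key = (arm, site_group(case.site))
        bins = monthly.setdefault(key, np.zeros(window_months))
        eps = window_episodes(
            episodes_by_participant.get(case.participant_id, []), anchor, window_months
        )
        for ep in eps:
            m = (ep.admission_date - anchor).days // DAYS_PER_MONTH  # 0-based
            year = ep.service_year
            usd = adjust_and_convert(ep.total_expense, year, params) + adjust_and_convert(
                time_cost(ep.length_of_stay, params, year), year, params
            )
            bins[m] += usd

    rows = []
    for (arm, group), bins in sorted(monthly.items()):
        cum = np.cumsum(bins)
        for m in range(window_months):
            rows.append(
                {"arm": arm, "site_group": group, "month": m + 1,
                 "cumulative_cost_usd": float(cum[m])}
            )
    return pd.DataFrame(rows)


def classification_breakdown(
    cases: Sequence[CancerCase],
    episodes_by_case: Mapping[str, Sequence[HospitalizationEpisode]],
    participants: Mapping[str, Participant],
    params: EconomicParams,
    classifications: Sequence[str] = NCMS_CLASSIFICATIONS,
) -> pd.DataFrame:
    """Mean adjusted cost per case (USD) by expense classification and arm.

    Line items outside the configured nine classes bucket under "other" with
    a warning.  Per arm, the classification means sum to the mean
    hospitalization cost per case whenever line items partition episode
    totals.
    """
    known = set(classifications)
    sums: dict[tuple[str, str], float] = {}
    n_cases: dict[str, int] = {}
    for case in cases:
        arm = participants[case.participant_id].arm.value
        n_cases[arm] = n_cases.get(arm, 0) + 1
        for ep in episodes_by_case.get(case.participant_id, []):
            for li in ep.line_items:
                cls = li.classification
                if cls not in known:
                    warnings.warn(f"unclassified line item {cls!r}; bucketed as 'other'",
                                  stacklevel=2)
                    cls = "other"
                sums[(arm, cls)] = sums.get((arm, cls), 0.0) + adjust_and_convert(
                    li.total, ep.service_year, params
                )

    cols = list(classifications) + (["other"] if any(k[1] == "other" for k in sums) else [])
    rows = []
    for arm, n in sorted(n_cases.items()):
        for cls in cols:
            rows.append(
                {"arm": arm, "classification": cls,
                 "mean_cost_per_case_usd": sums.get((arm, cls), 0.0) / n}
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Arm-comparison statistics
# --------------------------------------------------------------------------


def compare_arms_table1(
    cohort: PerfectCohort,
    participants: Mapping[str, Participant],
    episodes_by_participant: Mapping[str, Sequence[HospitalizationEpisode]] | None = None,
) -> pd.DataFrame:
    """Baseline-characteristics comparison of the two arms of the cohort.

    Categorical covariates: per-arm counts with integer percentages and an
    uncorrected chi-square p-value.  Continuous covariates: per-arm median
    (Q1; Q3) and a two-sided rank-sum p-value.  Covariates with a single
    observed level are noted and skipped.
    """
    rows_by_arm: dict[str, list[dict]] = {a.value: [] for a in Arm}
    for case in cohort.included_cases:
        p = participants[case.participant_id]
        rec = {
            "age_at_diagnosis": p.age_at_enrollment
            + (case.diagnosis_date - p.enrollment_date).days / 365.25,
            "gender": p.gender.value,
            "education": p.education.value,
            "occupation": p.occupation.value,
            "income_per_capita": p.household_income_per_capita,
            "site": case.site.value,
            "stage": case.stage.value,
            "therapy": case.therapy.value,
        }
        if episodes_by_participant is not None:
            eps = episodes_by_participant.get(case.participant_id, [])
            rec["n_hospitalizations"] = len(eps)
            rec["total_los_days"] = sum(ep.length_of_stay for ep in eps)
        rows_by_arm[p.arm.value].append(rec)

    control = pd.DataFrame(rows_by_arm[Arm.CONTROL.value])
    screening = pd.DataFrame(rows_by_arm[Arm.SCREENING.value])
    if control.empty or screening.empty:
        raise ValueError("both arms must be non-empty")

    continuous = ["age_at_diagnosis", "income_per_capita"]
    if "n_hospitalizations" in control.columns:
        continuous += ["n_hospitalizations", "total_los_days"]
    categorical = ["gender", "education", "occupation", "site", "stage", "therapy"]

    def _fmt_median(s: pd.Series) -> str:
        q1, med, q3 = np.percentile(s.to_numpy(dtype=float), [25, 50, 75])
        return f"{med:g} ({q1:g}; {q3:g})"

    out = []
    for cov in continuous:
        stat, p = stats.ranksums(control[cov], screening[cov])
        out.append(
            {"covariate": cov, "level": "median (Q1; Q3)", "test": "rank-sum",
             "control": _fmt_median(control[cov]), "screening": _fmt_median(screening[cov]),
             "p_value": p, "note": ""}
        )
    for cov in categorical:
        table = pd.crosstab(
            pd.Series(
                ["control"] * len(control) + ["screening"] * len(screening), name="arm"
            ),
            pd.concat([control[cov], screening[cov]], ignore_index=True),
        )
        if table.shape[1] < 2:
            out.append({"covariate": cov, "level": "", "test": "chi-square",
                        "control": "", "screening": "", "p_value": np.nan,
                        "note": "single level; test skipped"})
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        for j, level in enumerate(table.columns):
            nc, ns = int(table.loc["control", level]), int(table.loc["screening", level])
            out.append(
                {"covariate": cov, "level": str(level), "test": "chi-square",
                 "control": f"{nc} ({percentage(nc, len(control))}%)",
                 "screening": f"{ns} ({percentage(ns, len(screening))}%)",
                 "p_value": p if j == 0 else np.nan, "note": ""}
            )
    return pd.DataFrame(out)


def cost_factor_regression(
    case_costs: Sequence[CaseCosts],
    covariates: pd.DataFrame,
    params: EconomicParams,
    outcome: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Univariate logistic regressions of a binary cost outcome on each
    covariate.

    The default outcome is catastrophic-expenditure status derived from each
    case's out-of-pocket cost.  Each covariate is fit separately by maximum
    likelihood; categorical covariates expand to dummies against the first
    level.  Perfect separation suppresses the estimate with a flag.  Returns
    odds ratios with 95% CIs and Wald p-values.
    """
    if outcome is None:
        y = np.array(
            [is_catastrophic(c.out_of_pocket_usd, params) for c in case_costs], dtype=float
        )
    else:
        y = np.asarray(list(outcome), dtype=float)
    if len(y) != len(covariates):
        raise ValueError("outcome and covariate table lengths differ")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all cases on one side of the threshold")

    rows = []
    for cov in covariates.columns:
        x = covariates[cov]
        if x.dtype.kind in "OUSb" or isinstance(x.dtype, pd.CategoricalDtype):
            design = pd.get_dummies(x, prefix=cov, drop_first=True, dtype=float)
        else:
            design = x.to_frame().astype(float)
        if design.shape[1] == 0:
            rows.append({"covariate": cov, "term": "", "odds_ratio": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                         "note": "single level; fit skipped"})
            continue
        X = sm.add_constant(design, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            separated = not np.isfinite(fit.bse.iloc[1:]).all() or (
                np.abs(fit.params.iloc[1:]) > 15
            ).any()
        except Exception:
            separated = True
            fit = None
        for term in design.columns:
            if separated or fit is None:
                rows.append({"covariate": cov, "term": term, "odds_ratio": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                             "note": "perfect separation; estimate suppressed"})
                continue
            beta = fit.params[term]
            lo, hi = fit.conf_int().loc[term]
            rows.append({"covariate": cov, "term": term,
                         "odds_ratio": float(np.exp(beta)),
                         "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi)),
                         "p_value": float(fit.pvalues[term]), "note": ""})
    return pd.DataFrame(rows)
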