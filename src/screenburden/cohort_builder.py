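"""Cohort harmonization for staggered-enrollment cluster trials.

In community cluster-randomized trials the two arms enroll at different
times, so naive cost comparison confounds arm with follow-up length.  This
module implements the two harmonization devices used here:

* the *Perfect Cohort*: take the shortest follow-up among all verified cases
  as a uniform cutoff, and keep only cases diagnosed within that many days of
  their own enrollment, so both arms accrue cases over equal-length windows;
* the *standard observation window*: anchor each case at its first cancer
  hospitalization in a secondary or tertiary facility, compute the average
  monthly cost curve since that anchor, and pick the month past which
  average costs have decayed to noise (the curve is L-shaped, near zero by
  about a year, so the pipeline default fixes the window at 12 months).

Months are fixed 30-day bins from the first admission, not calendar months;
an episode's full cost belongs to the bin of its admission date.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .claims_model import (
    UPPER_GI_DIAGNOSIS_PREFIXES,
    CancerCase,
    FacilityTier,
    HospitalizationEpisode,
    Participant,
    followup_days,
)

__all__ = [
    "PerfectCohort",
    "UntreatedCaseError",
    "uniform_followup",
    "build_perfect_cohort",
    "first_treatment_episode",
    "window_episodes",
    "monthly_cost_curve",
    "select_window",
    "selection_bias_table",
    "DAYS_PER_MONTH",
]

#: Fixed month length (days) for cost binning since first hospitalization.
DAYS_PER_MONTH = 30

_TREATMENT_TIERS = (FacilityTier.SECONDARY, FacilityTier.TERTIARY)


class UntreatedCaseError(LookupError):
    """A verified case has no qualifying treatment hospitalization."""


@dataclass
class PerfectCohort:
    uniform_followup_days: int
    included_cases: list[CancerCase]
    excluded_cases: list[CancerCase]

    def __post_init__(self):
        overlap = {c.participant_id for c in self.included_cases} & {
            c.participant_id for c in self.excluded_cases
        }
        if overlap:
            raise ValueError(f"cases both included and excluded: {sorted(overlap)[:5]}")

    @property
    def n_included(self) -> int:
        return len(self.included_cases)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_cases)


def uniform_followup(
    cases: Sequence[CancerCase], participants: Mapping[str, Participant]
) -> int:
    """Shortest follow-up (days) among the verified cases' participants."""
    if not cases:
        raise ValueError("empty case set: cannot determine uniform follow-up")
    return min(followup_days(participants[c.participant_id]) for c in cases)


def build_perfect_cohort(
    cases: Sequence[CancerCase],
    participants: Mapping[str, Participant],
    uniform_days: int,
) -> PerfectCohort:
    """Partition cases by diagnosis within `uniform_days` of enrollment.

    The boundary is included: a case diagnosed exactly `uniform_days` after
    enrollment belongs to the cohort.
    """
    if uniform_days <= 0:
        raise ValueError(f"uniform follow-up must be positive, got {uniform_days}")
    included, excluded = [], []
    for c in cases:
        try:
            p = participants[c.participant_id]
        except KeyError:
            raise KeyError(f"case {c.participant_id} has no matching participant") from None
        delay = (c.diagnosis_date - p.enrollment_date).days
        (included if delay <= uniform_days else excluded).append(c)
    return PerfectCohort(uniform_days, included, excluded)


def first_treatment_episode(
    case: CancerCase,
    episodes: Iterable[HospitalizationEpisode],
    diagnosis_prefixes: Sequence[str] = UPPER_GI_DIAGNOSIS_PREFIXES,
) -> HospitalizationEpisode:
    """The treatment anchor: earliest cancer-coded admission at a secondary
    or tertiary facility.  Ties on admission date break by discharge date,
    then by input order.  Raises :class:`UntreatedCaseError` when nothing
    qualifies."""
    qualifying = [
        ep
        for ep in episodes
        if ep.participant_id == case.participant_id
        and ep.facility_tier in _TREATMENT_TIERS
        and ep.has_upper_gi_diagnosis(diagnosis_prefixes)
    ]
    if not qualifying:
        raise UntreatedCaseError(
            f"case {case.participant_id}: no secondary/tertiary cancer-coded episode"
        )
    order = {id(ep): i for i, ep in enumerate(qualifying)}
    return min(qualifying, key=lambda e: (e.admission_date, e.discharge_date, order[id(e)]))


def window_episodes(
    episodes: Iterable[HospitalizationEpisode],
    anchor,
    window_months: int | None,
    diagnosis_prefixes: Sequence[str] = UPPER_GI_DIAGNOSIS_PREFIXES,
) -> list[HospitalizationEpisode]:
    """Cancer-coded episodes admitted within the observation window
    [anchor, anchor + 30*window_months days); None means unbounded."""
    out = []
    for ep in episodes:
        if not ep.has_upper_gi_diagnosis(diagnosis_prefixes):
            continue
        offset = (ep.admission_date - anchor).days
        if offset < 0:
            continue
        if window_months is not None and offset >= DAYS_PER_MONTH * window_months:
            continue
        out.append(ep)
    return out


def _month_bin(admission, anchor) -> int:
    return (admission - anchor).days // DAYS_PER_MONTH + 1


def monthly_cost_curve(
    cohort: PerfectCohort,
    episodes_by_participant: Mapping[str, Sequence[HospitalizationEpisode]],
    participants: Mapping[str, Participant],
) -> pd.DataFrame:
    """Average treatment cost per patient under observation, by month since
    first hospitalization.

    Month m covers days [30(m-1), 30m) after each case's own anchor; a
    patient counts in the month-m denominator iff alive and uncensored
    through the bin start (follow-up >= 30(m-1) days after the anchor).
    Costs are nominal total expenses of cancer-coded episodes, assigned
    wholly to the admission bin.  Returns columns month, total_cost,
    n_under_observation, average_cost; months with an empty denominator
    report average 0.
    """
    anchors: dict[str, object] = {}
    totals: dict[int, float] = {}
    for case in cohort.included_cases:
        eps = episodes_by_participant.get(case.participant_id, [])
        try:
            anchor = first_treatment_episode(case, eps).admission_date
        except UntreatedCaseError:
            warnings.warn(
                f"case {case.participant_id} untreated; dropped from cost curve",
                stacklevel=2,
            )
            continue
        anchors[case.participant_id] = anchor
        for ep in window_episodes(eps, anchor, None):
            m = _month_bin(ep.admission_date, anchor)
            totals[m] = totals.get(m, 0.0) + ep.total_expense

    if not anchors:
        return pd.DataFrame(columns=["month", "total_cost", "n_under_observation", "average_cost"])

    # Extend through each case's observation horizon (capped at 10 years) so
    # the trailing near-zero months of the L-shaped curve are visible.
    horizon = max(
        (participants[pid].end_of_followup - anchor).days // DAYS_PER_MONTH + 1
        for pid, anchor in anchors.items()
    )
    max_month = min(max(max(totals, default=1), horizon), 120)
    rows = []
    for m in range(1, max_month + 1):
        n_obs = sum(
            1
            for pid, anchor in anchors.items()
            if (participants[pid].end_of_followup - anchor).days >= DAYS_PER_MONTH * (m - 1)
        )
        total = totals.get(m, 0.0)
        rows.append(
            {
                "month": m,
                "total_cost": total,
                "n_under_observation": n_obs,
                "average_cost": total / n_obs if n_obs else 0.0,
            }
        )
    return pd.DataFrame(rows)


def select_window(curve: pd.DataFrame, epsilon_fraction: float = 0.05) -> int:
    """Smallest m such that every later month's average cost is below
    epsilon_fraction of the month-1 average; falls back to the last month
    with a warning when the curve never settles."""
    if curve.empty:
        raise ValueError("empty cost curve")
    avg = curve.sort_values("month")["average_cost"].to_numpy(dtype=float)
    if not np.any(avg > 0):
        raise ValueError("all-zero cost curve: no window can be selected")
    threshold = epsilon_fraction * avg[0]
    below = avg < threshold
    for m in range(1, len(avg)):
        if below[m:].all():
            return m
    last = len(avg)
    warnings.warn(f"cost curve never decays below threshold; window = {last}", stacklevel=2)
    return last


def _covariate_frame(
    cases: Sequence[CancerCase], participants: Mapping[str, Participant]
) -> pd.DataFrame:
    rows = []
    for c in cases:
        p = participants[c.participant_id]
        rows.append(
            {
                "age": p.age_at_enrollment,
                "detection_mode": c.detection_mode.value,
                "gender": p.gender.value,
                "education": p.education.value,
                "occupation": p.occupation.value,
                "site": c.site.value,
            }
        )
    return pd.DataFrame(rows)


def selection_bias_table(
    cohort: PerfectCohort, participants: Mapping[str, Participant]
) -> pd.DataFrame:
    """Compare included vs excluded cases on baseline covariates.

    Categorical covariates use an uncorrected chi-square test on the
    contingency table; continuous covariates use the two-sided Wilcoxon
    rank-sum test.  Single-level covariates are skipped with a note.  Raw
    p-values, no multiplicity correction.
    """
    if not cohort.included_cases or not cohort.excluded_cases:
        raise ValueError("both cohort partitions must be non-empty")
    inc = _covariate_frame(cohort.included_cases, participants)
    exc = _covariate_frame(cohort.excluded_cases, participants)

    rows = []
    for cov in ["age", "detection_mode", "gender", "education", "occupation", "site"]:
        if cov == "age":
            stat, p = stats.ranksums(inc[cov], exc[cov])
            rows.append({"covariate": cov, "test": "rank-sum", "statistic": stat,
                         "p_value": p, "note": ""})
            continue
        table = pd.crosstab(
            pd.Series(["included"] * len(inc) + ["excluded"] * len(exc), name="group"),
            pd.concat([inc[cov], exc[cov]], ignore_index=True),
        )
        if table.shape[1] < 2:
            rows.append({"covariate": cov, "test": "chi-square", "statistic": np.nan,
                         "p_value": np.nan, "note": "single level; test skipped"})
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"covariate": cov, "test": "chi-square", "statistic": chi2,
                     "p_value": p, "note": ""})
    return pd.DataFrame(rows)
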