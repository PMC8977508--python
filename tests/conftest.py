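"""Shared fixtures: compact synthetic datasets and record builders."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from screenburden.claims_model import (
    Arm,
    CancerCase,
    CostLineItem,
    HospitalizationEpisode,
    Participant,
)
from screenburden.cost_engine import EconomicParams
from screenburden.synthetic_claims import GeneratorConfig, generate


def make_participant(
    pid="P1",
    arm=Arm.SCREENING,
    enrollment=date(2012, 1, 1),
    end=date(2018, 12, 31),
    age=60.0,
    gender="male",
    education="primary_or_below",
    occupation="manual_worker",
    income=2500.0,
) -> Participant:
    return Participant(pid, arm, enrollment, end, age, gender, education, occupation, income)


def make_case(
    pid="P1",
    site="esophageal",
    mode="screen_detected",
    diagnosis=date(2012, 2, 1),
    stage="0-I",
    therapy="single_radical_resection",
) -> CancerCase:
    return CancerCase(pid, site, mode, diagnosis, stage, therapy)


def make_episode(
    pid="P1",
    tier="secondary",
    admission=date(2012, 2, 10),
    los=10,
    code="C15.3",
    total=10000.0,
    reimbursed=5000.0,
    line_items=(),
) -> HospitalizationEpisode:
    return HospitalizationEpisode(
        participant_id=pid,
        facility_tier=tier,
        admission_date=admission,
        discharge_date=admission + timedelta(days=los),
        discharge_diagnosis_code=code,
        total_expense=total,
        reimbursed_expense=reimbursed,
        out_of_pocket_expense=total - reimbursed,
        line_items=line_items,
    )


def make_line_item(classification="surgery", amount=1000.0, service=date(2012, 2, 10)):
    return CostLineItem(service, classification, 1.0, amount, amount / 2)


@pytest.fixture(scope="session")
def econ_params() -> EconomicParams:
    return EconomicParams()


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    # Compact study: fewer participants with enriched incidence so a few
    # hundred cases exist and both arms are populated.
    return GeneratorConfig(seed=20240915, n_per_arm=2500, incidence_multiplier=8.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_dataset, econ_params):
    """Intermediate pipeline products on the compact dataset: cohort,
    treatment anchors, and per-case costs over a 12-month window."""
    import warnings

    from screenburden import cohort_builder as cb
    from screenburden import cost_engine
    from screenburden.claims_model import verify_case

    pidx = small_dataset.participant_index()
    eps_by = small_dataset.episodes_by_participant()
    verified = [
        c for c in small_dataset.cases if verify_case(eps_by.get(c.participant_id, []))
    ]
    u = cb.uniform_followup(verified, pidx)
    cohort = cb.build_perfect_cohort(verified, pidx, u)
    anchors, treated = {}, []
    for case in cohort.included_cases:
        try:
            anchors[case.participant_id] = cb.first_treatment_episode(
                case, eps_by.get(case.participant_id, [])
            ).admission_date
            treated.append(case)
        except cb.UntreatedCaseError:
            pass
    costs = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for case in treated:
            in_window = cb.window_episodes(
                eps_by[case.participant_id], anchors[case.participant_id], 12
            )
            costs[case.participant_id] = cost_engine.case_costs(
                case, in_window, econ_params
            )
    return {
        "pidx": pidx,
        "eps_by": eps_by,
        "verified": verified,
        "cohort": cohort,
        "anchors": anchors,
        "treated": treated,
        "costs": costs,
        "window": 12,
    }
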