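"""Domain types and rule-based case verification for insurance-claims cost data.

The analysis operates on three tables: a participant roster for a two-arm
screening trial, a table of upper-gastrointestinal cancer cases, and a table
of hospitalization claims with nested line-item cost details.  Records are
validated on construction; cross-record consistency (a case's diagnosis date
falling inside its participant's follow-up interval) is checked when tables
are read or assembled into a :class:`ClaimsDataset`.

Case verification follows the rural public-insurance (NCMS) record-matching
rule: a participant's claims constitute a treated upper-G.I. cancer case if
any hospitalization carries an upper-G.I. diagnosis code (ICD-10 blocks C15,
C16, D00, K22, matched by prefix) or any expense line item belongs to a
configured set of cancer-directed therapy classifications.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Arm",
    "Site",
    "DetectionMode",
    "Stage",
    "Therapy",
    "FacilityTier",
    "NCMS_CLASSIFICATIONS",
    "UPPER_GI_DIAGNOSIS_PREFIXES",
    "DEFAULT_THERAPY_CLASSIFICATIONS",
    "MONEY_TOLERANCE",
    "InvariantError",
    "SchemaError",
    "CostLineItem",
    "HospitalizationEpisode",
    "CancerCase",
    "Participant",
    "ClaimsDataset",
    "verify_case",
    "followup_days",
    "read_tables",
    "write_tables",
]


class Arm(str, enum.Enum):
    SCREENING = "screening"
    CONTROL = "control"


class Site(str, enum.Enum):
    ESOPHAGEAL = "esophageal"
    CARDIAL = "cardial"
    NON_CARDIAL_GASTRIC = "non_cardial_gastric"
    DUODENAL = "duodenal"


class DetectionMode(str, enum.Enum):
    SCREEN_DETECTED = "screen_detected"
    CLINICALLY_DIAGNOSED = "clinically_diagnosed"


class Stage(str, enum.Enum):
    STAGE_0_I = "0-I"
    STAGE_II = "II"
    STAGE_III = "III"
    STAGE_IV = "IV"
    UNKNOWN = "unknown"


class Therapy(str, enum.Enum):
    ENDOSCOPIC = "endoscopic"
    SINGLE_RADICAL_RESECTION = "single_radical_resection"
    RADICAL_PLUS_ADJUVANT = "radical_plus_adjuvant"
    RADIO_CHEMO_ONLY = "radio_chemo_only"
    SUPPORTIVE = "supportive"


class FacilityTier(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Education(str, enum.Enum):
    PRIMARY_OR_BELOW = "primary_or_below"
    MIDDLE_OR_ABOVE = "middle_or_above"


class Occupation(str, enum.Enum):
    MANUAL_WORKER = "manual_worker"
    TECHNICAL_STAFF = "technical_staff"
    OTHER = "other"


#: The nine expense classifications of the rural insurance claims system.
#: The scheme pre-defines nine classes but their official names are not
#: public; this default enumeration is a documented stand-in and is
#: configurable wherever it is consumed.
NCMS_CLASSIFICATIONS: tuple[str, ...] = (
    "bed",
    "nursing",
    "diagnostics",
    "imaging",
    "laboratory",
    "surgery",
    "radiation",
    "medication_chemo",
    "medication_other",
)

#: ICD-10 blocks identifying upper-G.I. cancer or related precancerous
#: lesions; matched as prefixes, so "C15.3" matches "C15".
UPPER_GI_DIAGNOSIS_PREFIXES: tuple[str, ...] = ("C15", "C16", "D00", "K22")

#: Line-item classifications treated as cancer-directed therapy for the
#: purposes of case verification.
DEFAULT_THERAPY_CLASSIFICATIONS: frozenset[str] = frozenset(
    {"surgery", "radiation", "medication_chemo"}
)

#: Absolute tolerance (CNY) for money identities such as
#: out_of_pocket = total - reimbursed.
MONEY_TOLERANCE = 0.01


class InvariantError(ValueError):
    """A record violates a domain invariant."""


class SchemaError(ValueError):
    """An input file does not match the documented column schema."""


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


@dataclass(frozen=True)
class CostLineItem:
    """One service line of a hospitalization claim."""

    service_date: date
    classification: str
    quantity: float
    unit_cost: float
    out_of_pocket_portion: float

    def __post_init__(self):
        object.__setattr__(self, "service_date", _as_date(self.service_date))
        if self.quantity < 0:
            raise InvariantError(f"negative quantity {self.quantity}")
        if self.unit_cost < 0:
            raise InvariantError(f"negative unit cost {self.unit_cost}")
        if self.out_of_pocket_portion > self.quantity * self.unit_cost + MONEY_TOLERANCE:
            raise InvariantError(
                "out-of-pocket portion exceeds line total: "
                f"{self.out_of_pocket_portion} > {self.quantity} x {self.unit_cost}"
            )

    @property
    def total(self) -> float:
        return self.quantity * self.unit_cost


@dataclass(frozen=True)
class HospitalizationEpisode:
    """One claims record: a single inpatient stay with its expense split."""

    participant_id: str
    facility_tier: FacilityTier
    admission_date: date
    discharge_date: date
    discharge_diagnosis_code: str
    total_expense: float
    reimbursed_expense: float
    out_of_pocket_expense: float
    line_items: tuple[CostLineItem, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "facility_tier", FacilityTier(self.facility_tier))
        object.__setattr__(self, "admission_date", _as_date(self.admission_date))
        object.__setattr__(self, "discharge_date", _as_date(self.discharge_date))
        object.__setattr__(self, "line_items", tuple(self.line_items))
        if self.discharge_date < self.admission_date:
            raise InvariantError(
                f"episode for {self.participant_id}: discharge "
                f"{self.discharge_date} before admission {self.admission_date}"
            )
        if self.total_expense < 0:
            raise InvariantError(f"negative total expense {self.total_expense}")
        gap = self.total_expense - self.reimbursed_expense - self.out_of_pocket_expense
        if abs(gap) > MONEY_TOLERANCE:
            raise InvariantError(
                f"episode for {self.participant_id}: out-of-pocket "
                f"{self.out_of_pocket_expense} != total {self.total_expense} "
                f"- reimbursed {self.reimbursed_expense}"
            )

    @property
    def length_of_stay(self) -> int:
        """Inpatient days, discharge minus admission."""
        return (self.discharge_date - self.admission_date).days

    @property
    def service_year(self) -> int:
        return self.admission_date.year

    def has_upper_gi_diagnosis(
        self, prefixes: Sequence[str] = UPPER_GI_DIAGNOSIS_PREFIXES
    ) -> bool:
        code = self.discharge_diagnosis_code.strip().upper()
        return any(code.startswith(p) for p in prefixes)


@dataclass(frozen=True)
class CancerCase:
    """A verified upper-G.I. cancer with its clinical characteristics."""

    participant_id: str
    site: Site
    detection_mode: DetectionMode
    diagnosis_date: date
    stage: Stage
    therapy: Therapy

    def __post_init__(self):
        object.__setattr__(self, "site", Site(self.site))
        object.__setattr__(self, "detection_mode", DetectionMode(self.detection_mode))
        object.__setattr__(self, "diagnosis_date", _as_date(self.diagnosis_date))
        object.__setattr__(self, "stage", Stage(self.stage))
        object.__setattr__(self, "therapy", Therapy(self.therapy))


@dataclass(frozen=True)
class Participant:
    """One trial participant with arm membership and follow-up interval."""

    participant_id: str
    arm: Arm
    enrollment_date: date
    end_of_followup: date
    age_at_enrollment: float
    gender: Gender
    education: Education
    occupation: Occupation
    household_income_per_capita: float

    def __post_init__(self):
        object.__setattr__(self, "arm", Arm(self.arm))
        object.__setattr__(self, "gender", Gender(self.gender))
        object.__setattr__(self, "education", Education(self.education))
        object.__setattr__(self, "occupation", Occupation(self.occupation))
        object.__setattr__(self, "enrollment_date", _as_date(self.enrollment_date))
        object.__setattr__(self, "end_of_followup", _as_date(self.end_of_followup))
        if self.end_of_followup < self.enrollment_date:
            raise InvariantError(
                f"participant {self.participant_id}: end of follow-up "
                f"{self.end_of_followup} before enrollment {self.enrollment_date}"
            )


def followup_days(p: Participant) -> int:
    """Follow-up length in whole days, end of follow-up minus enrollment."""
    return (p.end_of_followup - p.enrollment_date).days


def verify_case(
    episodes: Iterable[HospitalizationEpisode],
    therapy_codes: frozenset[str] | set[str] = DEFAULT_THERAPY_CLASSIFICATIONS,
    diagnosis_prefixes: Sequence[str] = UPPER_GI_DIAGNOSIS_PREFIXES,
) -> bool:
    """Decide whether a participant's claims constitute a treated upper-G.I. case.

    True iff any episode's discharge diagnosis starts with one of the
    configured ICD prefixes, or any line item carries a classification in the
    configured therapy set.  An empty episode list is simply unverified
    (False), not an error.  The rule is monotone: adding episodes can only
    turn False into True.
    """
    for ep in episodes:
        if ep.has_upper_gi_diagnosis(diagnosis_prefixes):
            return True
        if any(li.classification in therapy_codes for li in ep.line_items):
            return True
    return False


@dataclass
class ClaimsDataset:
    """The three analysis tables plus convenience indexes."""

    participants: list[Participant]
    cases: list[CancerCase]
    episodes: list[HospitalizationEpisode]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        by_id = {p.participant_id: p for p in self.participants}
        if len(by_id) != len(self.participants):
            raise InvariantError("duplicate participant_id in roster")
        bad = [c.participant_id for c in self.cases if c.participant_id not in by_id]
        if bad:
            raise InvariantError(f"cases reference unknown participants: {bad[:5]}")
        out_of_interval = [
            c.participant_id
            for c in self.cases
            if not (
                by_id[c.participant_id].enrollment_date
                <= c.diagnosis_date
                <= by_id[c.participant_id].end_of_followup
            )
        ]
        if out_of_interval:
            raise InvariantError(
                "diagnosis date outside participant follow-up interval for: "
                f"{out_of_interval[:5]}"
            )
        bad_ep = [e.participant_id for e in self.episodes if e.participant_id not in by_id]
        if bad_ep:
            raise InvariantError(f"episodes reference unknown participants: {bad_ep[:5]}")

    def participant_index(self) -> dict[str, Participant]:
        return {p.participant_id: p for p in self.participants}

    def episodes_by_participant(self) -> dict[str, list[HospitalizationEpisode]]:
        idx: dict[str, list[HospitalizationEpisode]] = {}
        for e in self.episodes:
            idx.setdefault(e.participant_id, []).append(e)
        for eps in idx.values():
            eps.sort(key=lambda e: (e.admission_date, e.discharge_date))
        return idx


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Column dictionary (CSV, UTF-8, header row; dates ISO-8601):
#   participants.csv: participant_id, arm, enrollment_date, end_of_followup,
#       age_at_enrollment, gender, education, occupation,
#       household_income_per_capita
#   cases.csv: participant_id, site, detection_mode, diagnosis_date, stage,
#       therapy
#   episodes.csv: participant_id, facility_tier, admission_date,
#       discharge_date, discharge_diagnosis_code, total_expense,
#       reimbursed_expense, out_of_pocket_expense, line_items (JSON array of
#       objects with keys service_date, classification, quantity, unit_cost,
#       out_of_pocket_portion)
# ---------------------------------------------------------------------------

_PARTICIPANT_COLS = [
    "participant_id", "arm", "enrollment_date", "end_of_followup",
    "age_at_enrollment", "gender", "education", "occupation",
    "household_income_per_capita",
]
_CASE_COLS = [
    "participant_id", "site", "detection_mode", "diagnosis_date", "stage", "therapy",
]
_EPISODE_COLS = [
    "participant_id", "facility_tier", "admission_date", "discharge_date",
    "discharge_diagnosis_code", "total_expense", "reimbursed_expense",
    "out_of_pocket_expense", "line_items",
]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _build_rows(df: pd.DataFrame, builder, path) -> list:
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(builder(row))
        except (InvariantError, ValueError, KeyError) as exc:
            raise SchemaError(f"{path}, row {i + 2}: {exc}") from exc
    return records


def read_tables(
    participants_path, cases_path, episodes_path
) -> tuple[list[Participant], list[CancerCase], list[HospitalizationEpisode]]:
    """Read the three CSV tables into validated, typed records.

    Raises :class:`SchemaError` naming the file and (1-based, header
    included) row on any malformed or invariant-violating record, and
    :class:`InvariantError` on cross-table inconsistencies.
    """
    pdf = pd.read_csv(participants_path, dtype=str)
    _check_columns(pdf, _PARTICIPANT_COLS, participants_path)
    participants = _build_rows(
        pdf,
        lambda r: Participant(
            participant_id=r.participant_id,
            arm=r.arm,
            enrollment_date=r.enrollment_date,
            end_of_followup=r.end_of_followup,
            age_at_enrollment=float(r.age_at_enrollment),
            gender=r.gender,
            education=r.education,
            occupation=r.occupation,
            household_income_per_capita=float(r.household_income_per_capita),
        ),
        participants_path,
    )

    cdf = pd.read_csv(cases_path, dtype=str)
    _check_columns(cdf, _CASE_COLS, cases_path)
    cases = _build_rows(
        cdf,
        lambda r: CancerCase(
            participant_id=r.participant_id,
            site=r.site,
            detection_mode=r.detection_mode,
            diagnosis_date=r.diagnosis_date,
            stage=r.stage,
            therapy=r.therapy,
        ),
        cases_path,
    )

    edf = pd.read_csv(episodes_path, dtype=str)
    _check_columns(edf, _EPISODE_COLS, episodes_path)

    def _episode(r):
        items = json.loads(r.line_items) if isinstance(r.line_items, str) and r.line_items else []
        return HospitalizationEpisode(
            participant_id=r.participant_id,
            facility_tier=r.facility_tier,
            admission_date=r.admission_date,
            discharge_date=r.discharge_date,
            discharge_diagnosis_code=r.discharge_diagnosis_code,
            total_expense=float(r.total_expense),
            reimbursed_expense=float(r.reimbursed_expense),
            out_of_pocket_expense=float(r.out_of_pocket_expense),
            line_items=tuple(CostLineItem(**item) for item in items),
        )

    episodes = _build_rows(edf, _episode, episodes_path)

    ClaimsDataset(participants, cases, episodes)  # cross-table validation
    return participants, cases, episodes


def write_tables(
    dataset: ClaimsDataset, out_dir
) -> tuple[Path, Path, Path]:
    """Write the three tables as CSV; nested line items serialize to JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ppath, cpath, epath = out / "participants.csv", out / "cases.csv", out / "episodes.csv"

    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "arm": p.arm.value,
                "enrollment_date": p.enrollment_date.isoformat(),
                "end_of_followup": p.end_of_followup.isoformat(),
                "age_at_enrollment": p.age_at_enrollment,
                "gender": p.gender.value,
                "education": p.education.value,
                "occupation": p.occupation.value,
                "household_income_per_capita": p.household_income_per_capita,
            }
            for p in dataset.participants
        ],
        columns=_PARTICIPANT_COLS,
    ).to_csv(ppath, index=False)

    pd.DataFrame(
        [
            {
                "participant_id": c.participant_id,
                "site": c.site.value,
                "detection_mode": c.detection_mode.value,
                "diagnosis_date": c.diagnosis_date.isoformat(),
                "stage": c.stage.value,
                "therapy": c.therapy.value,
            }
            for c in dataset.cases
        ],
        columns=_CASE_COLS,
    ).to_csv(cpath, index=False)

    pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "facility_tier": e.facility_tier.value,
                "admission_date": e.admission_date.isoformat(),
                "discharge_date": e.discharge_date.isoformat(),
                "discharge_diagnosis_code": e.discharge_diagnosis_code,
                "total_expense": e.total_expense,
                "reimbursed_expense": e.reimbursed_expense,
                "out_of_pocket_expense": e.out_of_pocket_expense,
                "line_items": json.dumps(
                    [
                        {
                            "service_date": li.service_date.isoformat(),
                            "classification": li.classification,
                            "quantity": li.quantity,
                            "unit_cost": li.unit_cost,
                            "out_of_pocket_portion": li.out_of_pocket_portion,
                        }
                        for li in e.line_items
                    ]
                ),
            }
            for e in dataset.episodes
        ],
        columns=_EPISODE_COLS,
    ).to_csv(epath, index=False)

    return ppath, cpath, epath
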