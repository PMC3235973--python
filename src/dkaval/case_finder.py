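"""Computer case definition for incident diabetic ketoacidosis (DKA).

Potential cases are cohort members with an inpatient encounter during
follow-up carrying any diagnosis in the DKA code set (ICD-9 250.1x,
ICD-10 E10.1–E14.1) in any diagnosis position; outpatient and
emergency-only encounters never trigger. Only the first (incident)
qualifying admission per person is retained, and persons with a
DKA-coded claim of any setting during the baseline window are excluded
as prevalent.

The index date is the hospital admission date, unless an emergency-room
claim with any diabetes diagnosis (ICD-9 250.xx) occurred on the day
prior to admission, in which case the index date is reset to that
emergency visit's date.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Sequence

from .claims_model import ClaimsDatabase, CodePattern, any_code_matches
from .cohort_builder import CohortMember, _index_db, _PersonClaims, ONE_DAY

__all__ = [
    "DKA_CODES",
    "ER_DIABETES_CODES_ICD9",
    "ER_DIABETES_CODES_ICD10",
    "CaseFinderConfig",
    "PotentialCase",
    "find_potential_cases",
    "resolve_index_date",
]

DKA_CODES = (CodePattern("250.1", "icd9"), CodePattern("E1x.1", "icd10"))
ER_DIABETES_CODES_ICD9 = (CodePattern("250x", "icd9"),)
ER_DIABETES_CODES_ICD10 = (CodePattern("E1x", "icd10"),)


@dataclasses.dataclass
class CaseFinderConfig:
    dka_codes: tuple[CodePattern, ...] = DKA_CODES
    er_diabetes_codes: tuple[CodePattern, ...] = ER_DIABETES_CODES_ICD9
    #: The prior-day reset rule cites only ICD-9; ICD-10 matching is opt-in.
    include_icd10_er_reset: bool = False
    #: Require no DKA-coded claim (any setting) in baseline (incidence).
    require_incident: bool = True
    baseline_days: int = 365

    def er_patterns(self) -> tuple[CodePattern, ...]:
        if self.include_icd10_er_reset:
            return self.er_diabetes_codes + ER_DIABETES_CODES_ICD10
        return self.er_diabetes_codes


@dataclasses.dataclass
class PotentialCase:
    person_id: str
    admission_date: dt.date
    index_date: dt.date
    encounter_id: int
    exposure_group: str


def _resolve_index_date(
    claims: _PersonClaims,
    admission_date: dt.date,
    config: CaseFinderConfig,
    earliest_allowed: dt.date | None = None,
) -> dt.date:
    prior = admission_date - ONE_DAY
    if earliest_allowed is not None and prior < earliest_allowed:
        return admission_date
    patterns = config.er_patterns()
    for start, _end, setting, dx, _eid in claims.encounters:
        if setting == "emergency" and start == prior and any_code_matches(dx, patterns):
            return prior
    return admission_date


def resolve_index_date(
    person_id: str,
    admission_date: dt.date,
    db: ClaimsDatabase,
    config: CaseFinderConfig | None = None,
) -> dt.date:
    """Admission date, or the day prior when an ER diabetes claim sits there."""
    config = config or CaseFinderConfig()
    claims = _index_db(db)[person_id]
    return _resolve_index_date(claims, admission_date, config)


def find_potential_cases(
    cohort: Sequence[CohortMember],
    db: ClaimsDatabase,
    config: CaseFinderConfig | None = None,
) -> list[PotentialCase]:
    """Apply the computer case definition over a built cohort.

    Returns at most one :class:`PotentialCase` per person (the incident
    event), sorted by person_id. Deterministic: same-day competing
    admissions resolve to the lowest encounter id.
    """
    config = config or CaseFinderConfig()
    index = _index_db(db)
    cases: list[PotentialCase] = []
    for member in sorted(cohort, key=lambda m: m.person_id):
        claims = index.get(member.person_id)
        if claims is None:
            continue
        if config.require_incident:
            baseline_start = member.qualifying_fill_date - dt.timedelta(
                days=config.baseline_days
            )
            prevalent = any(
                baseline_start <= start <= member.qualifying_fill_date
                and any_code_matches(dx, config.dka_codes)
                for start, _end, _setting, dx, _eid in claims.encounters
            )
            if prevalent:
                continue
        triggers = [
            (start, eid)
            for start, _end, setting, dx, eid in claims.encounters
            if setting == "inpatient"
            and dx
            and member.followup_start <= start <= member.followup_end
            and any_code_matches(dx, config.dka_codes)
        ]
        if not triggers:
            continue
        admission, encounter_id = min(triggers)
        index_date = _resolve_index_date(
            claims, admission, config, earliest_allowed=member.followup_start
        )
        cases.append(
            PotentialCase(
                person_id=member.person_id,
                admission_date=admission,
                index_date=index_date,
                encounter_id=encounter_id,
                exposure_group=member.exposure_group,
            )
        )
    return cases
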