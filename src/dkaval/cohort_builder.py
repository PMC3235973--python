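"""New-user (incident-user) cohort construction for a psychotropic study.

The cohort consists of children and youth (6–24 years) who newly initiate
an antipsychotic or a control psychotropic (mood stabilizer, ADHD drug,
antidepressant, benzodiazepine) after a 365-day washout with no study-drug
fill. Eligibility at the qualifying fill requires continuous enrollment
over the 365-day baseline, baseline health-care utilization, no exclusion
diagnosis (schizophrenia/psychosis, diabetes, pregnancy, PCOS,
life-threatening illness) in baseline, and no hospital stay overlapping
the 30 days before qualification. Follow-up runs from the day after the
fill to the earliest of: study end, the day before the 25th birthday,
disenrollment, death, an exclusion diagnosis arising during follow-up, or
365 days past the last day of current drug use.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .claims_model import (
    ClaimsDatabase,
    ClaimsModelError,
    CodePattern,
    STUDY_DRUG_CLASSES,
    any_code_matches,
)

__all__ = [
    "CohortConfig",
    "CohortMember",
    "EligibilityResult",
    "DEFAULT_EXCLUSION_CODES",
    "find_qualifying_fills",
    "check_eligibility",
    "compute_followup",
    "build_cohort",
    "age_in_years",
    "cohort_to_frame",
    "cohort_from_frame",
]

ONE_DAY = dt.timedelta(days=1)

#: Baseline exclusion code families. Small, documented stand-ins for the
#: full administrative code lists, sufficient for family-level matching.
DEFAULT_EXCLUSION_CODES: dict[str, tuple[CodePattern, ...]] = {
    "schizophrenia_psychosis": (
        CodePattern("295", "icd9"),
        CodePattern("297", "icd9"),
        CodePattern("298", "icd9"),
        CodePattern("F2x", "icd10"),
    ),
    "diabetes": (
        CodePattern("250", "icd9"),
        CodePattern("E1x", "icd10"),
    ),
    "pregnancy": (
        CodePattern("V22", "icd9"),
        CodePattern("64x", "icd9"),
        CodePattern("65x", "icd9"),
        CodePattern("Z33", "icd10"),
    ),
    "pcos": (
        CodePattern("256.4", "icd9"),
        CodePattern("E28.2", "icd10"),
    ),
    "life_threatening": (
        CodePattern("042", "icd9"),
        CodePattern("14x", "icd9"),
        CodePattern("15x", "icd9"),
        CodePattern("16x", "icd9"),
        CodePattern("17x", "icd9"),
        CodePattern("18x", "icd9"),
        CodePattern("19x", "icd9"),
        CodePattern("20x", "icd9"),
        CodePattern("C", "icd10"),
    ),
}

#: Reasons, highest precedence first, used to break ties when several
#: termination events land on the same day.
END_REASON_PRECEDENCE = (
    "death",
    "disenrollment",
    "age_25",
    "criteria_failure",
    "use_lapse",
    "study_end",
)


@dataclasses.dataclass
class CohortConfig:
    """Tunable parameters of cohort construction (all windows in days)."""

    study_start: dt.date = dt.date(1996, 1, 1)
    study_end: dt.date = dt.date(2007, 12, 31)
    washout_days: int = 365
    min_age: int = 6
    max_age: int = 24
    baseline_days: int = 365
    prior_hospitalization_days: int = 30
    post_use_extension_days: int = 365
    use_grace_days: int = 0
    require_baseline_outpatient: bool = True
    #: Literal reading of the "no prescription filled more than 90 days
    #: prior" clause: additionally require no fill of *any* class in
    #: [q-365, q-91]. Off by default; the 365-day washout governs.
    require_90day_free: bool = False
    exclusion_codes: Mapping[str, tuple[CodePattern, ...]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_CODES)
    )
    #: Exclusion sets re-evaluated during follow-up. The diabetes family is
    #: deliberately absent: a diabetes-coded claim during follow-up is the
    #: outcome pathway, not a censoring event.
    followup_criteria: tuple[str, ...] = (
        "schizophrenia_psychosis",
        "pregnancy",
        "pcos",
        "life_threatening",
    )

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        for field in (
            "washout_days",
            "baseline_days",
            "prior_hospitalization_days",
            "post_use_extension_days",
        ):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.use_grace_days < 0:
            raise ValueError("use_grace_days must be non-negative")


@dataclasses.dataclass
class EligibilityResult:
    person_id: str
    eligible: bool
    failed_criteria: list[str]


@dataclasses.dataclass
class CohortMember:
    person_id: str
    qualifying_fill_date: dt.date
    drug_class: str
    exposure_group: str  # "antipsychotic" | "control"
    followup_start: dt.date
    followup_end: dt.date
    end_reason: str


def age_in_years(birth_date: dt.date, on: dt.date) -> int:
    """Completed calendar years of age on a given date."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _birthday(birth_date: dt.date, years: int) -> dt.date:
    try:
        return birth_date.replace(year=birth_date.year + years)
    except ValueError:  # Feb 29
        return dt.date(birth_date.year + years, 3, 1)


def _merge_spans(spans: Sequence[tuple[dt.date, dt.date]]) -> list[tuple[dt.date, dt.date]]:
    """Normalize enrollment spans: sort and merge overlapping/adjacent ones."""
    merged: list[tuple[dt.date, dt.date]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1] + ONE_DAY:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# Per-person claim views (avoids re-filtering whole tables inside loops)
# ---------------------------------------------------------------------------

class _PersonClaims:
    __slots__ = ("person", "spans", "fills", "encounters", "death_date")

    def __init__(self, person: pd.Series, spans, fills, encounters, death_date):
        self.person = person
        self.spans = spans              # merged [(start, end)]
        self.fills = fills              # list of (fill_date, drug_class, days_supply)
        self.encounters = encounters    # list of (start, end, setting, dx_codes, encounter_id)
        self.death_date = death_date


def _index_db(db: ClaimsDatabase) -> dict[str, _PersonClaims]:
    spans_by, fills_by, enc_by = {}, {}, {}
    for row in db.enrollment.itertuples(index=False):
        spans_by.setdefault(row.person_id, []).append((row.start_date, row.end_date))
    for row in db.pharmacy.itertuples(index=False):
        fills_by.setdefault(row.person_id, []).append(
            (row.fill_date, row.drug_class, int(row.days_supply))
        )
    for row in db.encounters.itertuples(index=False):
        enc_by.setdefault(row.person_id, []).append(
            (row.start_date, row.end_date, row.setting, row.dx_codes, int(row.encounter_id))
        )
    deaths = dict(zip(db.deaths["person_id"], db.deaths["death_date"]))
    index = {}
    for row in db.persons.itertuples(index=False):
        pid = row.person_id
        index[pid] = _PersonClaims(
            person=row,
            spans=_merge_spans(spans_by.get(pid, [])),
            fills=sorted(fills_by.get(pid, [])),
            encounters=sorted(enc_by.get(pid, []), key=lambda e: (e[0], e[4])),
            death_date=deaths.get(pid),
        )
    return index


# ---------------------------------------------------------------------------
# Qualifying fills and washout
# ---------------------------------------------------------------------------

def find_qualifying_fills(
    fills: Sequence[tuple[dt.date, str, int]], config: CohortConfig
) -> list[tuple[dt.date, str, str]]:
    """Return (date, drug_class, exposure_group) for every new-use fill.

    A study-drug fill qualifies iff no study-drug fill occurred in the
    ``washout_days`` days strictly before it (and, with
    ``require_90day_free``, no fill of any class in the window more than
    90 days before).
    """
    fills = sorted(fills)
    out = []
    for fill_date, drug_class, _supply in fills:
        if drug_class not in STUDY_DRUG_CLASSES:
            continue
        window_start = fill_date - dt.timedelta(days=config.washout_days)
        broken = any(
            other_class in STUDY_DRUG_CLASSES
            and window_start <= other_date <= fill_date - ONE_DAY
            for other_date, other_class, _s in fills
        )
        if not broken and config.require_90day_free:
            cutoff = fill_date - dt.timedelta(days=91)
            broken = any(
                window_start <= other_date <= cutoff for other_date, _c, _s in fills
            )
        if not broken:
            group = "antipsychotic" if drug_class == "antipsychotic" else "control"
            out.append((fill_date, drug_class, group))
    return out


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def _check_eligibility(
    claims: _PersonClaims, qualifying_date: dt.date, config: CohortConfig
) -> EligibilityResult:
    failures: list[str] = []
    q = qualifying_date
    if not (config.study_start <= q <= config.study_end):
        failures.append("outside_study_window")

    age = age_in_years(claims.person.birth_date, q)
    if not (config.min_age <= age <= config.max_age):
        failures.append("age")

    baseline_start = q - dt.timedelta(days=config.baseline_days)
    covered = any(start <= baseline_start and end >= q for start, end in claims.spans)
    if not covered:
        failures.append("enrollment_gap")

    if config.require_baseline_outpatient:
        has_visit = any(
            setting == "outpatient" and baseline_start <= start <= q - ONE_DAY
            for start, _end, setting, _dx, _eid in claims.encounters
        )
        if not has_visit:
            failures.append("baseline_utilization")

    hosp_start = q - dt.timedelta(days=config.prior_hospitalization_days)
    in_hospital = any(
        setting == "inpatient" and start <= q - ONE_DAY and end >= hosp_start
        for start, end, setting, _dx, _eid in claims.encounters
    )
    if in_hospital:
        failures.append("recent_hospitalization")

    for name, patterns in config.exclusion_codes.items():
        hit = any(
            baseline_start <= start <= q - ONE_DAY and any_code_matches(dx, patterns)
            for start, _end, _setting, dx, _eid in claims.encounters
        )
        if hit:
            failures.append(f"dx_{name}")

    return EligibilityResult(
        person_id=claims.person.person_id,
        eligible=not failures,
        failed_criteria=failures,
    )


def check_eligibility(
    person_id: str, qualifying_date: dt.date, db: ClaimsDatabase, config: CohortConfig
) -> EligibilityResult:
    """Evaluate every inclusion criterion at the qualifying date.

    All failures are collected (no short-circuit). Raises
    :class:`ClaimsModelError` if the person is absent from the database.
    """
    index = _index_db(db)
    if person_id not in index:
        raise ClaimsModelError(f"person {person_id!r} not found in database")
    return _check_eligibility(index[person_id], qualifying_date, config)


# ---------------------------------------------------------------------------
# Follow-up
# ---------------------------------------------------------------------------

def _last_use_day(
    fills: Sequence[tuple[dt.date, str, int]], qualifying_date: dt.date, config: CohortConfig
) -> dt.date:
    """Last covered day of the continuous-use episode begun at qualification.

    Current use runs from fill date through fill date + days_supply − 1;
    a refill starting no more than ``use_grace_days`` + 1 day after the
    covered period extends the episode.
    """
    end = None
    for fill_date, drug_class, supply in fills:
        if drug_class not in STUDY_DRUG_CLASSES or fill_date < qualifying_date:
            continue
        fill_end = fill_date + dt.timedelta(days=supply - 1)
        if end is None:
            end = fill_end
        elif fill_date <= end + dt.timedelta(days=1 + config.use_grace_days):
            end = max(end, fill_end)
        else:
            break
    assert end is not None, "qualifying fill must be present in fills"
    return end


def _compute_followup(
    claims: _PersonClaims, qualifying_date: dt.date, config: CohortConfig
) -> tuple[dt.date, str]:
    start = qualifying_date + ONE_DAY
    candidates: list[tuple[dt.date, str]] = [(config.study_end, "study_end")]

    candidates.append(
        (_birthday(claims.person.birth_date, config.max_age + 1) - ONE_DAY, "age_25")
    )

    span = next((s for s in claims.spans if s[0] <= qualifying_date <= s[1]), None)
    if span is not None:
        candidates.append((span[1], "disenrollment"))
    else:  # not enrolled at qualification: degenerate, ends immediately
        candidates.append((qualifying_date, "disenrollment"))

    if claims.death_date is not None:
        candidates.append((claims.death_date, "death"))

    last_use = _last_use_day(claims.fills, qualifying_date, config)
    candidates.append(
        (last_use + dt.timedelta(days=config.post_use_extension_days), "use_lapse")
    )

    followup_patterns = [
        pat
        for name in config.followup_criteria
        for pat in config.exclusion_codes.get(name, ())
    ]
    failure_dates = [
        enc_start
        for enc_start, _end, _setting, dx, _eid in claims.encounters
        if enc_start > qualifying_date and any_code_matches(dx, followup_patterns)
    ]
    if failure_dates:
        candidates.append((min(failure_dates), "criteria_failure"))

    end = min(date for date, _ in candidates)
    reason = min(
        (reason for date, reason in candidates if date == end),
        key=END_REASON_PRECEDENCE.index,
    )
    return end, reason


def compute_followup(
    person_id: str, qualifying_date: dt.date, db: ClaimsDatabase, config: CohortConfig
) -> tuple[dt.date, str]:
    """Follow-up end date and reason for an eligible member.

    The end is the minimum over the candidate termination events; same-day
    ties resolve by fixed precedence
    (death > disenrollment > age_25 > criteria_failure > use_lapse > study_end).
    """
    index = _index_db(db)
    if person_id not in index:
        raise ClaimsModelError(f"person {person_id!r} not found in database")
    return _compute_followup(index[person_id], qualifying_date, config)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def build_cohort(
    db: ClaimsDatabase,
    config: CohortConfig | None = None,
    return_exclusions: bool = False,
):
    """Build the new-user cohort: one member per person, first eligible
    qualifying fill, ordered by person_id.

    With ``return_exclusions=True`` also returns a tally
    ``{criterion: count}`` over all rejected qualifying fills.
    """
    config = config or CohortConfig()
    index = _index_db(db)
    members: list[CohortMember] = []
    tally: dict[str, int] = {}
    for pid in sorted(index):
        claims = index[pid]
        for fill_date, drug_class, group in find_qualifying_fills(claims.fills, config):
            result = _check_eligibility(claims, fill_date, config)
            if not result.eligible:
                for crit in result.failed_criteria:
                    tally[crit] = tally.get(crit, 0) + 1
                continue
            end, reason = _compute_followup(claims, fill_date, config)
            start = fill_date + ONE_DAY
            if end < start:  # no follow-up time at all
                tally["no_followup_time"] = tally.get("no_followup_time", 0) + 1
                continue
            members.append(
                CohortMember(
                    person_id=pid,
                    qualifying_fill_date=fill_date,
                    drug_class=drug_class,
                    exposure_group=group,
                    followup_start=start,
                    followup_end=end,
                    end_reason=reason,
                )
            )
            break  # first eligible qualifying fill only
    if return_exclusions:
        return members, tally
    return members


# ---------------------------------------------------------------------------
# CSV round-trip for cohort members
# ---------------------------------------------------------------------------

_MEMBER_COLUMNS = [
    "person_id",
    "qualifying_fill_date",
    "drug_class",
    "exposure_group",
    "followup_start",
    "followup_end",
    "end_reason",
]


def cohort_to_frame(members: Iterable[CohortMember]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(m) for m in members], columns=_MEMBER_COLUMNS
    )


def cohort_from_frame(frame: pd.DataFrame) -> list[CohortMember]:
    members = []
    for row in frame.itertuples(index=False):
        members.append(
            CohortMember(
                person_id=row.person_id,
                qualifying_fill_date=_as_date(row.qualifying_fill_date),
                drug_class=row.drug_class,
                exposure_group=row.exposure_group,
                followup_start=_as_date(row.followup_start),
                followup_end=_as_date(row.followup_end),
                end_reason=row.end_reason,
            )
        )
    return members


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))
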