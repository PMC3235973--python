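"""Gold-standard clinical adjudication of abstracted medical records.

A flagged hospitalization is confirmed as diabetic ketoacidosis when the
abstracted record shows a random blood glucose above 250 mg/dL together
with laboratory evidence of metabolic acidosis: blood pH below 7.25
(venous) or below 7.30 (arterial or capillary), or blood bicarbonate
below 15 mmol/L. A discharge diagnosis of DKA is recorded as a satisfied
criterion but, under the default ``strict`` policy, never suffices on its
own: records with severe hyperglycemia but no laboratory acidosis are not
confirmed even when a DKA discharge diagnosis was given. The alternative
``dx_fallback`` policy lets the discharge diagnosis decide only when no
pH and no bicarbonate were recorded at all.

Records whose abstraction is incomplete (chart not located, facility
refused) are not adjudicable — a distinct state from not-confirmed — and
are excluded from predictive-value denominators upstream.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .claims_model import CodePattern, any_code_matches, format_dx_field, parse_dx_field
from .case_finder import DKA_CODES

__all__ = [
    "GLUCOSE_THRESHOLD_MG_DL",
    "PH_THRESHOLDS",
    "BICARBONATE_THRESHOLD_MMOL_L",
    "ABSTRACTION_STATUSES",
    "AbstractedRecord",
    "AdjudicationResult",
    "NotAdjudicableError",
    "meets_acidosis",
    "adjudicate",
    "adjudicate_all",
    "read_abstractions",
    "write_abstractions",
]

GLUCOSE_THRESHOLD_MG_DL = 250.0
PH_THRESHOLDS = {"venous": 7.25, "arterial": 7.30, "capillary": 7.30}
BICARBONATE_THRESHOLD_MMOL_L = 15.0

ABSTRACTION_STATUSES = ("complete", "record_not_located", "facility_refused")
POLICIES = ("strict", "dx_fallback")


class NotAdjudicableError(Exception):
    """The record's abstraction is incomplete; it cannot be adjudicated."""


@dataclasses.dataclass
class AbstractedRecord:
    """Chart-abstraction result for one flagged case.

    ``glucose_mg_dl`` is the maximum random glucose recorded during the
    episode; ``bicarbonate_mmol_l`` the minimum bicarbonate; ``ph_values``
    every recorded blood pH with its specimen type. Stratum attributes
    (age at index, gender, ADHD diagnosis, exposure group) ride along for
    stratified predictive-value analyses.
    """

    person_id: str
    abstraction_status: str = "complete"
    glucose_mg_dl: float | None = None
    ph_values: tuple[tuple[float, str], ...] = ()
    bicarbonate_mmol_l: float | None = None
    discharge_dx: tuple[tuple[str, str], ...] = ()
    age_years: int | None = None
    gender: str | None = None
    adhd_dx: bool | None = None
    exposure_group: str | None = None
    index_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.abstraction_status not in ABSTRACTION_STATUSES:
            raise ValueError(f"unknown abstraction_status {self.abstraction_status!r}")
        if self.glucose_mg_dl is not None and self.glucose_mg_dl < 0:
            raise ValueError("glucose_mg_dl must be non-negative")
        self.ph_values = tuple((float(v), s) for v, s in self.ph_values)
        for value, specimen in self.ph_values:
            if specimen not in PH_THRESHOLDS:
                raise ValueError(f"unknown pH specimen {specimen!r}")
            if not (6.5 < value < 8.0):
                raise ValueError(f"implausible blood pH {value!r}")
        self.discharge_dx = tuple(self.discharge_dx)

    @property
    def complete(self) -> bool:
        return self.abstraction_status == "complete"


@dataclasses.dataclass
class AdjudicationResult:
    person_id: str
    confirmed: bool
    criteria_met: frozenset[str]  # subset of {glucose, ph, bicarbonate, discharge_dx}
    policy: str


def meets_acidosis(record: AbstractedRecord) -> bool:
    """Laboratory acidosis: any pH below its specimen threshold, or
    bicarbonate < 15 mmol/L. Missing labs count as no evidence."""
    for value, specimen in record.ph_values:
        if value < PH_THRESHOLDS[specimen]:
            return True
    if (
        record.bicarbonate_mmol_l is not None
        and record.bicarbonate_mmol_l < BICARBONATE_THRESHOLD_MMOL_L
    ):
        return True
    return False


def adjudicate(
    record: AbstractedRecord,
    policy: str = "strict",
    dka_codes: tuple[CodePattern, ...] = DKA_CODES,
) -> AdjudicationResult:
    """Apply the confirmation rule to a completely abstracted record.

    Raises :class:`NotAdjudicableError` on incomplete abstractions.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    if not record.complete:
        raise NotAdjudicableError(
            f"record for {record.person_id!r} has status {record.abstraction_status!r}"
        )

    criteria: set[str] = set()
    hyperglycemia = (
        record.glucose_mg_dl is not None and record.glucose_mg_dl > GLUCOSE_THRESHOLD_MG_DL
    )
    if hyperglycemia:
        criteria.add("glucose")
    if any(v < PH_THRESHOLDS[s] for v, s in record.ph_values):
        criteria.add("ph")
    if (
        record.bicarbonate_mmol_l is not None
        and record.bicarbonate_mmol_l < BICARBONATE_THRESHOLD_MMOL_L
    ):
        criteria.add("bicarbonate")
    if any_code_matches(record.discharge_dx, dka_codes):
        criteria.add("discharge_dx")

    confirmed = hyperglycemia and ({"ph", "bicarbonate"} & criteria != set())
    if not confirmed and policy == "dx_fallback":
        no_acid_labs = not record.ph_values and record.bicarbonate_mmol_l is None
        confirmed = hyperglycemia and no_acid_labs and "discharge_dx" in criteria

    return AdjudicationResult(
        person_id=record.person_id,
        confirmed=confirmed,
        criteria_met=frozenset(criteria),
        policy=policy,
    )


def adjudicate_all(
    records: Iterable[AbstractedRecord], policy: str = "strict"
) -> tuple[pd.DataFrame, list[str]]:
    """Adjudicate every complete record; skip incomplete ones.

    Returns a DataFrame (person_id, confirmed, criteria_met, and the
    stratum attributes) plus the list of person_ids whose abstraction was
    incomplete.
    """
    rows, skipped = [], []
    for record in records:
        if not record.complete:
            skipped.append(record.person_id)
            continue
        result = adjudicate(record, policy=policy)
        rows.append(
            {
                "person_id": record.person_id,
                "confirmed": result.confirmed,
                "criteria_met": ";".join(sorted(result.criteria_met)),
                "exposure_group": record.exposure_group,
                "age_years": record.age_years,
                "gender": record.gender,
                "adhd_dx": record.adhd_dx,
            }
        )
    columns = [
        "person_id",
        "confirmed",
        "criteria_met",
        "exposure_group",
        "age_years",
        "gender",
        "adhd_dx",
    ]
    return pd.DataFrame(rows, columns=columns), skipped


# ---------------------------------------------------------------------------
# CSV round-trip for abstracted records
# ---------------------------------------------------------------------------

_ABSTRACTION_COLUMNS = [
    "person_id",
    "abstraction_status",
    "glucose_mg_dl",
    "ph_values",
    "bicarbonate_mmol_l",
    "discharge_dx",
    "age_years",
    "gender",
    "adhd_dx",
    "exposure_group",
    "index_date",
]


def _format_ph(values: Sequence[tuple[float, str]]) -> str:
    return ";".join(f"{specimen}:{value:g}" for value, specimen in values)


def _parse_ph(raw: str) -> tuple[tuple[float, str], ...]:
    if not raw:
        return ()
    out = []
    for item in raw.split(";"):
        specimen, _, value = item.partition(":")
        out.append((float(value), specimen))
    return tuple(out)


def write_abstractions(records: Iterable[AbstractedRecord], path: str | Path) -> Path:
    rows = []
    for r in records:
        rows.append(
            {
                "person_id": r.person_id,
                "abstraction_status": r.abstraction_status,
                "glucose_mg_dl": "" if r.glucose_mg_dl is None else f"{r.glucose_mg_dl:g}",
                "ph_values": _format_ph(r.ph_values),
                "bicarbonate_mmol_l": (
                    "" if r.bicarbonate_mmol_l is None else f"{r.bicarbonate_mmol_l:g}"
                ),
                "discharge_dx": format_dx_field(r.discharge_dx),
                "age_years": "" if r.age_years is None else int(r.age_years),
                "gender": r.gender or "",
                "adhd_dx": "" if r.adhd_dx is None else ("true" if r.adhd_dx else "false"),
                "exposure_group": r.exposure_group or "",
                "index_date": "" if r.index_date is None else r.index_date.isoformat(),
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=_ABSTRACTION_COLUMNS).to_csv(path, index=False)
    return path


def read_abstractions(path: str | Path) -> list[AbstractedRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AbstractedRecord(
                person_id=row.person_id,
                abstraction_status=row.abstraction_status,
                glucose_mg_dl=float(row.glucose_mg_dl) if row.glucose_mg_dl else None,
                ph_values=_parse_ph(row.ph_values),
                bicarbonate_mmol_l=(
                    float(row.bicarbonate_mmol_l) if row.bicarbonate_mmol_l else None
                ),
                discharge_dx=parse_dx_field(row.discharge_dx),
                age_years=int(row.age_years) if row.age_years else None,
                gender=row.gender or None,
                adhd_dx={"true": True, "false": False}.get(row.adhd_dx),
                exposure_group=row.exposure_group or None,
                index_date=(
                    dt.date.fromisoformat(row.index_date) if row.index_date else None
                ),
            )
        )
    return records
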