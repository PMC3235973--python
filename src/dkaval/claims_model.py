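"""Domain model for a Medicaid-like administrative claims database.

The claims database is five flat tables — persons, enrollment spans,
pharmacy fills, medical encounters, and death records — held as pandas
DataFrames inside a :class:`ClaimsDatabase` with referential integrity.
This module also provides ICD-9/ICD-10 code normalization and family
("code set") matching, which is how claims-research case definitions such
as "any diagnosis of 250.1x" are expressed, and CSV readers/writers so a
database round-trips losslessly through plain text.

Conventions
-----------
* Dates are day-granular :class:`datetime.date` objects; every interval
  (enrollment span, hospital stay) is closed ``[start, end]``.
* Diagnosis codes on an encounter are stored as an ordered tuple of
  ``(code, system)`` pairs with ``system`` in ``{"icd9", "icd10"}``; in CSV
  they are serialized as ``"icd9:250.11;icd9:276.51"``.
* Code patterns use truncated-prefix semantics: pattern ``250.1`` accepts
  every code in the 250.1x family. The wildcard ``x`` in a pattern matches
  any single digit (or a literal ``X``), so ``E1x.1`` covers the
  E10.1–E14.1 ketoacidosis families.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ClaimsModelError",
    "CodeParseError",
    "CodePatternError",
    "IntegrityError",
    "CodePattern",
    "ClaimsDatabase",
    "normalize_code",
    "match_code",
    "any_code_matches",
    "read_claims_db",
    "write_claims_db",
    "parse_dx_field",
    "format_dx_field",
]

GENDERS = ("male", "female")
RACES = ("caucasian", "african_american", "other")
SETTINGS = ("inpatient", "outpatient", "emergency")
DRUG_CLASSES = (
    "antipsychotic",
    "mood_stabilizer",
    "adhd_drug",
    "antidepressant",
    "benzodiazepine",
    "other",
)
#: Classes whose initiation defines cohort entry (everything but "other").
STUDY_DRUG_CLASSES = DRUG_CLASSES[:-1]
CODE_SYSTEMS = ("icd9", "icd10")

PERSON_COLUMNS = ["person_id", "birth_date", "gender", "race", "urban", "adhd_dx"]
ENROLLMENT_COLUMNS = ["person_id", "start_date", "end_date"]
PHARMACY_COLUMNS = ["person_id", "fill_date", "drug_class", "days_supply"]
ENCOUNTER_COLUMNS = ["encounter_id", "person_id", "setting", "start_date", "end_date", "dx_codes"]
DEATH_COLUMNS = ["person_id", "death_date"]

TABLE_FILENAMES = {
    "persons": "persons.csv",
    "enrollment": "enrollment.csv",
    "pharmacy": "pharmacy.csv",
    "encounters": "encounters.csv",
    "deaths": "deaths.csv",
}


class ClaimsModelError(Exception):
    """Base error for the claims domain model."""


class CodeParseError(ClaimsModelError):
    """A raw ICD code string could not be canonicalized."""


class CodePatternError(ClaimsModelError):
    """A code pattern is malformed (bad character or wildcard position)."""


class IntegrityError(ClaimsModelError):
    """A referential-integrity or invariant violation in the database."""


# ---------------------------------------------------------------------------
# ICD code handling
# ---------------------------------------------------------------------------

def _strip_code(raw: str) -> str:
    """Uppercase and remove at most one dot; reject other punctuation."""
    s = raw.strip().upper()
    if not s:
        raise CodeParseError("empty ICD code")
    s = s.replace(".", "", 1)
    if not s.isalnum():
        raise CodeParseError(f"malformed ICD code {raw!r}")
    return s


def _category_length(dotless: str, system: str) -> int:
    # ICD-9 external-cause codes (E800-E999) have a 4-character category;
    # everything else (including ICD-10) splits after 3 characters.
    if system == "icd9" and dotless[:1] == "E":
        return 4
    return 3


def normalize_code(raw: str, system: str) -> str:
    """Canonicalize an ICD code: uppercase, dotted form (``25011 → 250.11``).

    Idempotent; raises :class:`CodeParseError` on non-alphanumeric input.
    """
    if system not in CODE_SYSTEMS:
        raise CodeParseError(f"unknown code system {system!r}")
    s = _strip_code(raw)
    k = _category_length(s, system)
    if len(s) <= k:
        return s
    return s[:k] + "." + s[k:]


@dataclasses.dataclass(frozen=True)
class CodePattern:
    """A truncated-prefix ICD family pattern, e.g. ``250.1`` or ``E1x.1``.

    The wildcard ``x`` matches any single digit (or literal ``X``), so a
    pattern always matches itself. Matching is prefix-based on the dotless
    form: ``250.1`` accepts 250.1, 250.10, ..., 250.13.
    """

    pattern: str
    system: str

    def __post_init__(self) -> None:
        if self.system not in CODE_SYSTEMS:
            raise CodePatternError(f"unknown code system {self.system!r}")
        try:
            dotless = _strip_code(self.pattern)
        except CodeParseError as exc:
            raise CodePatternError(str(exc)) from None
        if dotless[0] == "X":
            raise CodePatternError(
                f"pattern {self.pattern!r}: wildcard not allowed in first position"
            )
        object.__setattr__(self, "_dotless", dotless)

    @property
    def dotless(self) -> str:
        return self._dotless  # type: ignore[attr-defined]

    def matches(self, code: str, system: str | None = None) -> bool:
        """True iff ``code`` (any dot formatting) falls under this family."""
        if system is not None and system != self.system:
            return False
        c = _strip_code(code)
        p = self.dotless
        if len(p) > len(c):
            return False
        for pc, cc in zip(p, c):
            if pc == "X":
                if not (cc.isdigit() or cc == "X"):
                    return False
            elif pc != cc:
                return False
        return True


def match_code(code: str, system: str, pattern: CodePattern) -> bool:
    """Match one code against one pattern; the code systems must agree."""
    if system not in CODE_SYSTEMS:
        raise CodeParseError(f"unknown code system {system!r}")
    if system != pattern.system:
        raise ValueError(
            f"code system mismatch: code is {system}, pattern is {pattern.system}"
        )
    return pattern.matches(code)


def any_code_matches(
    dx_codes: Iterable[tuple[str, str]], patterns: Iterable[CodePattern]
) -> bool:
    """True iff any (code, system) pair falls under any same-system pattern."""
    pats = tuple(patterns)
    for code, system in dx_codes:
        for pat in pats:
            if pat.system == system and pat.matches(code):
                return True
    return False


# ---------------------------------------------------------------------------
# Diagnosis-list serialization
# ---------------------------------------------------------------------------

def format_dx_field(dx_codes: Sequence[tuple[str, str]]) -> str:
    return ";".join(f"{system}:{code}" for code, system in dx_codes)


def parse_dx_field(raw: str) -> tuple[tuple[str, str], ...]:
    if raw is None or raw == "" or (isinstance(raw, float) and pd.isna(raw)):
        return ()
    out = []
    for item in str(raw).split(";"):
        system, _, code = item.partition(":")
        if system not in CODE_SYSTEMS or not code:
            raise CodeParseError(f"malformed dx entry {item!r}")
        out.append((normalize_code(code, system), system))
    return tuple(out)


# ---------------------------------------------------------------------------
# The database container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClaimsDatabase:
    """Five claims tables with referential integrity on ``person_id``."""

    persons: pd.DataFrame
    enrollment: pd.DataFrame
    pharmacy: pd.DataFrame
    encounters: pd.DataFrame
    deaths: pd.DataFrame

    @classmethod
    def empty(cls) -> "ClaimsDatabase":
        return cls(
            persons=pd.DataFrame(columns=PERSON_COLUMNS),
            enrollment=pd.DataFrame(columns=ENROLLMENT_COLUMNS),
            pharmacy=pd.DataFrame(columns=PHARMACY_COLUMNS),
            encounters=pd.DataFrame(columns=ENCOUNTER_COLUMNS),
            deaths=pd.DataFrame(columns=DEATH_COLUMNS),
        )

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "enrollment": self.enrollment,
            "pharmacy": self.pharmacy,
            "encounters": self.encounters,
            "deaths": self.deaths,
        }

    def sorted(self) -> "ClaimsDatabase":
        """A copy with every table in canonical row order (the written order)."""
        return ClaimsDatabase(
            persons=self.persons.sort_values("person_id", kind="stable").reset_index(drop=True),
            enrollment=self.enrollment.sort_values(
                ["person_id", "start_date", "end_date"], kind="stable"
            ).reset_index(drop=True),
            pharmacy=self.pharmacy.sort_values(
                ["person_id", "fill_date", "drug_class"], kind="stable"
            ).reset_index(drop=True),
            encounters=self.encounters.sort_values("encounter_id", kind="stable").reset_index(
                drop=True
            ),
            deaths=self.deaths.sort_values("person_id", kind="stable").reset_index(drop=True),
        )

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on the first invariant violation."""
        persons = self.persons
        if persons["person_id"].duplicated().any():
            dup = persons.loc[persons["person_id"].duplicated(), "person_id"].iloc[0]
            raise IntegrityError(f"persons: duplicate person_id {dup!r}")
        known = set(persons["person_id"])
        for name in ("enrollment", "pharmacy", "encounters", "deaths"):
            table = getattr(self, name)
            for i, pid in table["person_id"].items():
                if pid not in known:
                    raise IntegrityError(f"{name} row {i}: unknown person_id {pid!r}")
        for i, row in self.enrollment.iterrows():
            if row["start_date"] > row["end_date"]:
                raise IntegrityError(f"enrollment row {i}: start_date after end_date")
        for i, row in self.encounters.iterrows():
            if row["start_date"] > row["end_date"]:
                raise IntegrityError(f"encounters row {i}: start_date after end_date")
        if len(self.pharmacy) and (self.pharmacy["days_supply"] < 1).any():
            i = self.pharmacy.index[self.pharmacy["days_supply"] < 1][0]
            raise IntegrityError(f"pharmacy row {i}: days_supply < 1")
        if self.deaths["person_id"].duplicated().any():
            dup = self.deaths.loc[self.deaths["person_id"].duplicated(), "person_id"].iloc[0]
            raise IntegrityError(f"deaths: more than one record for person_id {dup!r}")
        # birth precedes all dated records
        birth = dict(zip(persons["person_id"], persons["birth_date"]))
        for name, col in (
            ("enrollment", "start_date"),
            ("pharmacy", "fill_date"),
            ("encounters", "start_date"),
            ("deaths", "death_date"),
        ):
            table = getattr(self, name)
            for i, row in table.iterrows():
                if row[col] < birth[row["person_id"]]:
                    raise IntegrityError(
                        f"{name} row {i}: {col} precedes birth_date of {row['person_id']!r}"
                    )

    def equals(self, other: "ClaimsDatabase") -> bool:
        a, b = self.sorted(), other.sorted()
        for name in a.tables():
            left = getattr(a, name).astype(object)
            right = getattr(b, name).astype(object)
            if not left.equals(right):
                return False
        return True


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_DATE_COLUMNS = {
    "persons": ["birth_date"],
    "enrollment": ["start_date", "end_date"],
    "pharmacy": ["fill_date"],
    "encounters": ["start_date", "end_date"],
    "deaths": ["death_date"],
}
_BOOL_COLUMNS = {"persons": ["urban", "adhd_dx"]}


def _parse_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for col in _DATE_COLUMNS[table]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            i = df.index[bad][0]
            raise CodeParseError(
                f"{table} row {i}, column {col}: unparseable date {df.loc[i, col]!r}"
            )
        df[col] = parsed.dt.date
    return df


def _parse_bools(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for col in _BOOL_COLUMNS.get(table, []):
        mapped = df[col].astype(str).str.lower().map({"true": True, "false": False})
        if mapped.isna().any():
            i = df.index[mapped.isna()][0]
            raise CodeParseError(
                f"{table} row {i}, column {col}: expected true/false, got {df.loc[i, col]!r}"
            )
        df[col] = mapped
    return df


def read_claims_db(directory: str | Path) -> ClaimsDatabase:
    """Read the five-table CSV layout from ``directory`` and validate it.

    Raises :class:`IntegrityError` for orphan person ids (naming table and
    row) and :class:`CodeParseError` for unparseable dates or codes.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for table, filename in TABLE_FILENAMES.items():
        path = directory / filename
        if not path.exists():
            raise FileNotFoundError(f"missing claims table file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        expected = {
            "persons": PERSON_COLUMNS,
            "enrollment": ENROLLMENT_COLUMNS,
            "pharmacy": PHARMACY_COLUMNS,
            "encounters": ENCOUNTER_COLUMNS,
            "deaths": DEATH_COLUMNS,
        }[table]
        if list(df.columns) != expected:
            raise IntegrityError(
                f"{table}: header {list(df.columns)} does not match schema {expected}"
            )
        df = _parse_dates(df, table)
        df = _parse_bools(df, table)
        frames[table] = df
    frames["pharmacy"]["days_supply"] = frames["pharmacy"]["days_supply"].astype(int)
    enc = frames["encounters"]
    enc["encounter_id"] = enc["encounter_id"].astype(int)
    enc["dx_codes"] = enc["dx_codes"].map(parse_dx_field)
    db = ClaimsDatabase(
        persons=frames["persons"],
        enrollment=frames["enrollment"],
        pharmacy=frames["pharmacy"],
        encounters=enc,
        deaths=frames["deaths"],
    )
    db.validate()
    return db


def write_claims_db(db: ClaimsDatabase, directory: str | Path) -> dict[str, Path]:
    """Write ``db`` as five CSV files; round-trips through ``read_claims_db``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    canonical = db.sorted()
    for table, df in canonical.tables().items():
        df = df.copy()
        for col in _DATE_COLUMNS[table]:
            df[col] = df[col].map(lambda d: d.isoformat() if pd.notna(d) else "")
        for col in _BOOL_COLUMNS.get(table, []):
            df[col] = df[col].map(lambda b: "true" if b else "false")
        if table == "encounters":
            df["dx_codes"] = df["dx_codes"].map(format_dx_field)
        path = directory / TABLE_FILENAMES[table]
        df.to_csv(path, index=False)
        out[table] = path
    return out
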