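"""Canonical data model for individual-based bear monitoring records.

Two record types are exchanged as CSV:

* ``BearYear`` — one monitored female in one hunting-season year. The ``year``
  field indexes the hunting-season year (the season starts in late August), so
  ``survived`` refers to the interval from year ``t`` to year ``t + 1``.
* ``Litter`` — one reproductive event with its realized maternal-care
  duration (1.5 or 2.5 years, or lost before weaning).

CSV dialect: comma-separated, UTF-8, "." decimal separator, integer years,
booleans serialized as ``true``/``false``. Missing values are empty fields;
an *unknown* tactic or parity is an explicit token, not an empty field, so
"unobserved" and "not applicable" remain distinguishable.

All invariants listed on the types are checked on read; violations raise
:class:`ValidationError` naming the offending row and rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BearYear",
    "Litter",
    "SchemaError",
    "ValidationError",
    "age_class_of",
    "read_bear_years",
    "write_bear_years",
    "read_litters",
    "write_litters",
    "T15",
    "T25",
    "UNKNOWN",
    "LOST",
    "AGE_CLASSES",
]

# Tactic / status / cause tokens used throughout the package.
T15 = "T15"
T25 = "T25"
UNKNOWN = "unknown"
LOST = "lost"  # litter lost before weaning

TACTICS = (T15, T25)
STATUSES = ("solitary", "with_offspring", "with_mother")
CAUSES = ("none", "hunting", "other")
AGE_CLASSES = ("1", "2", "3", "4-8", "9+")
PROTECTED_STATUSES = ("with_offspring", "with_mother")


class SchemaError(ValueError):
    """A required CSV column is missing or the header is malformed."""


class ValidationError(ValueError):
    """A row violates a documented record invariant."""


def age_class_of(age: int) -> str:
    """Map an integer age (years >= 1) to its demographic age class."""
    if age < 1:
        raise ValidationError(f"age must be >= 1, got {age}")
    if age <= 3:
        return str(age)
    if age <= 8:
        return "4-8"
    return "9+"


@dataclass(frozen=True)
class BearYear:
    """One monitored female bear in one hunting-season year.

    ``recruits`` is the number of yearling daughters produced this year
    (range 0-3), or ``None`` when not applicable/observed.
    """

    bear_id: str
    year: int
    age: int
    tactic: str  # T15 | T25 | unknown
    status: str  # solitary | with_offspring | with_mother
    survived: bool
    cause_of_death: str  # none | hunting | other
    available_for_hunting: bool
    recruits: int | None = None

    @property
    def age_class(self) -> str:
        return age_class_of(self.age)

    def validate(self) -> None:
        if self.tactic not in TACTICS + (UNKNOWN,):
            raise ValidationError(f"tactic must be one of {TACTICS + (UNKNOWN,)}, got {self.tactic!r}")
        if self.status not in STATUSES:
            raise ValidationError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.cause_of_death not in CAUSES:
            raise ValidationError(f"cause_of_death must be one of {CAUSES}, got {self.cause_of_death!r}")
        age_class_of(self.age)
        if self.survived and self.cause_of_death != "none":
            raise ValidationError("survived records must have cause_of_death = none")
        if not self.survived and self.cause_of_death == "none":
            raise ValidationError("non-survived records must have cause_of_death hunting or other")
        if self.status in PROTECTED_STATUSES and self.available_for_hunting:
            # family-group members are protected by law during the hunting
            # season; a hunting death of a protected female is an accidental
            # kill and keeps available_for_hunting = false
            raise ValidationError(
                f"status {self.status!r} implies available_for_hunting = false (legal protection)"
            )
        if self.recruits is not None and self.recruits not in (0, 1, 2, 3):
            raise ValidationError(f"recruits must be in 0..3 when present, got {self.recruits}")


@dataclass(frozen=True)
class Litter:
    """One reproductive event of one mother.

    ``care_duration`` is 1.5 or 2.5 (years of maternal care until family
    breakup) or the token ``"lost"`` for litters lost before weaning; lost
    litters carry no weaning year. ``mother_primiparous`` may be ``None``
    (explicitly unknown parity).
    """

    litter_id: str
    mother_id: str
    birth_year: int
    weaning_year: int | None
    care_duration: float | str  # 1.5 | 2.5 | "lost"
    litter_size: int
    mother_primiparous: bool | None = None

    def validate(self) -> None:
        if self.care_duration == LOST:
            if self.weaning_year is not None:
                raise ValidationError("lost litters must not carry a weaning_year")
        elif self.care_duration in (1.5, 2.5):
            if self.weaning_year is None:
                raise ValidationError("weaned litters require a weaning_year")
            gap = self.weaning_year - self.birth_year
            expected = 1 if self.care_duration == 1.5 else 2
            if gap != expected:
                raise ValidationError(
                    f"care_duration {self.care_duration} requires weaning_year - birth_year = "
                    f"{expected}, got {gap}"
                )
        else:
            raise ValidationError(
                f"care_duration must be 1.5, 2.5 or {LOST!r}, got {self.care_duration!r}"
            )
        if self.litter_size not in (1, 2, 3, 4):
            raise ValidationError(f"litter_size must be in 1..4, got {self.litter_size}")


BEAR_YEAR_COLUMNS = (
    "bear_id",
    "year",
    "age",
    "tactic",
    "status",
    "survived",
    "cause_of_death",
    "available_for_hunting",
    "recruits",
)
LITTER_COLUMNS = (
    "litter_id",
    "mother_id",
    "birth_year",
    "weaning_year",
    "care_duration",
    "litter_size",
    "mother_primiparous",
)

_BOOL = {"true": True, "false": False}


def _parse_bool(value: str, column: str, line: int) -> bool:
    try:
        return _BOOL[value.strip().lower()]
    except KeyError:
        raise ValidationError(f"line {line}: column {column!r} must be true/false, got {value!r}")


def _fmt_bool(value: bool) -> str:
    return "true" if value else "false"


def _check_header(header: Sequence[str], expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_bear_years(path) -> list[BearYear]:
    """Read and validate bear-year records from CSV, preserving row order."""
    records: list[BearYear] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        _check_header(reader.fieldnames, BEAR_YEAR_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            try:
                rec = BearYear(
                    bear_id=row["bear_id"],
                    year=int(row["year"]),
                    age=int(row["age"]),
                    tactic=row["tactic"],
                    status=row["status"],
                    survived=_parse_bool(row["survived"], "survived", i),
                    cause_of_death=row["cause_of_death"],
                    available_for_hunting=_parse_bool(
                        row["available_for_hunting"], "available_for_hunting", i
                    ),
                    recruits=int(row["recruits"]) if row["recruits"] not in ("", None) else None,
                )
                rec.validate()
            except ValidationError as err:
                raise ValidationError(f"{path}: line {i}: {err}") from None
            except (KeyError, TypeError, ValueError) as err:
                raise ValidationError(f"{path}: line {i}: malformed row ({err})") from None
            records.append(rec)
    return records


def write_bear_years(records: Iterable[BearYear], path) -> None:
    """Write bear-year records as CSV (documented column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(BEAR_YEAR_COLUMNS)
        for rec in records:
            rec.validate()
            writer.writerow(
                [
                    rec.bear_id,
                    rec.year,
                    rec.age,
                    rec.tactic,
                    rec.status,
                    _fmt_bool(rec.survived),
                    rec.cause_of_death,
                    _fmt_bool(rec.available_for_hunting),
                    "" if rec.recruits is None else rec.recruits,
                ]
            )


def read_litters(path) -> list[Litter]:
    """Read and validate litter records from CSV, preserving row order."""
    litters: list[Litter] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        _check_header(reader.fieldnames, LITTER_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            try:
                care_raw = row["care_duration"].strip()
                care: float | str = LOST if care_raw == LOST else float(care_raw)
                parity_raw = row["mother_primiparous"].strip().lower()
                if parity_raw == UNKNOWN:
                    parity = None
                else:
                    parity = _parse_bool(parity_raw, "mother_primiparous", i)
                rec = Litter(
                    litter_id=row["litter_id"],
                    mother_id=row["mother_id"],
                    birth_year=int(row["birth_year"]),
                    weaning_year=int(row["weaning_year"]) if row["weaning_year"] != "" else None,
                    care_duration=care,
                    litter_size=int(row["litter_size"]),
                    mother_primiparous=parity,
                )
                rec.validate()
            except ValidationError as err:
                raise ValidationError(f"{path}: line {i}: {err}") from None
            except (KeyError, TypeError, ValueError) as err:
                raise ValidationError(f"{path}: line {i}: malformed row ({err})") from None
            litters.append(rec)
    return litters


def write_litters(litters: Iterable[Litter], path) -> None:
    """Write litter records as CSV (documented column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LITTER_COLUMNS)
        for rec in litters:
            rec.validate()
            writer.writerow(
                [
                    rec.litter_id,
                    rec.mother_id,
                    rec.birth_year,
                    "" if rec.weaning_year is None else rec.weaning_year,
                    rec.care_duration,
                    rec.litter_size,
                    UNKNOWN if rec.mother_primiparous is None else _fmt_bool(rec.mother_primiparous),
                ]
            )
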