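"""Domain types for pharmacy claims and patient rosters, plus delimited-text I/O.

Every downstream stage (PDC computation, cohort assembly, effect estimation)
consumes the types defined here.  Dates are ISO-8601 in files and converted to
integer day offsets internally so that all interval arithmetic is exact integer
arithmetic; day intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DrugClass",
    "Group",
    "Sex",
    "FillRecord",
    "PatientRecord",
    "StudyWindow",
    "FormatError",
    "ValidationError",
    "read_fills",
    "write_fills",
    "read_patients",
    "write_patients",
    "write_results",
    "read_results",
    "date_to_day",
    "day_to_date",
]

#: Epoch for integer day offsets.  Any fixed date works; all arithmetic is
#: relative, so the choice is invisible to users.
EPOCH = _dt.date(2000, 1, 1)


def date_to_day(d: _dt.date) -> int:
    """Convert a calendar date to an integer day offset from the epoch."""
    return (d - EPOCH).days


def day_to_date(day: int) -> _dt.date:
    """Inverse of :func:`date_to_day`."""
    return EPOCH + _dt.timedelta(days=int(day))


class DrugClass(enum.Enum):
    ANTIHYPERTENSIVE = "antihypertensive"
    ANTIHYPERLIPIDEMIC = "antihyperlipidemic"


class Group(enum.Enum):
    INTERVENTION = "intervention"
    CONTROL = "control"


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


class FormatError(ValueError):
    """File-level problem: missing/unknown columns, unreadable header."""


class ValidationError(ValueError):
    """Row-level problems, collected and raised with line numbers."""

    def __init__(self, message: str, rows: Sequence[tuple[int, str]] = ()):
        super().__init__(message)
        #: (line number, description) pairs for every offending row.
        self.rows = list(rows)


@dataclass(frozen=True)
class FillRecord:
    """One pharmacy claim: who filled what subclass, when, for how many days.

    ``days_supply`` is the number of days the dispensed quantity is intended
    to cover; it must be >= 1.
    """

    patient_id: str
    drug_class: DrugClass
    subclass: str
    fill_date: _dt.date
    days_supply: int

    def __post_init__(self):
        if self.days_supply < 1:
            raise ValidationError(
                f"days_supply must be >= 1, got {self.days_supply}"
            )

    @property
    def fill_day(self) -> int:
        return date_to_day(self.fill_date)


@dataclass(frozen=True)
class PatientRecord:
    """Roster entry: arm assignment, demographics, covariates, enrollment.

    ``bmi`` may be missing (None); members with a missing covariate used by an
    adjusted model are excluded from that model with a logged count.
    ``charlson`` is carried as an opaque comorbidity covariate.
    """

    patient_id: str
    group: Group
    age: int
    sex: Sex
    race_white: bool
    diabetes: bool
    bmi: float | None
    pcp_visits_per_year: float
    charlson: float
    enroll_start: _dt.date
    enroll_end: _dt.date

    def __post_init__(self):
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.enroll_start >= self.enroll_end:
            raise ValidationError(
                f"enroll_start must precede enroll_end "
                f"({self.enroll_start} >= {self.enroll_end})"
            )

    def covariates(self) -> dict[str, float | None]:
        return {
            "age": float(self.age),
            "sex_female": float(self.sex is Sex.FEMALE),
            "race_white": float(self.race_white),
            "diabetes": float(self.diabetes),
            "bmi": self.bmi,
            "pcp_visits_per_year": self.pcp_visits_per_year,
            "charlson": self.charlson,
        }


@dataclass(frozen=True)
class StudyWindow:
    """A half-open observation window ``[start, start + length_days)``."""

    start: _dt.date
    length_days: int = 365

    def __post_init__(self):
        if self.length_days < 1:
            raise ValidationError(
                f"length_days must be >= 1, got {self.length_days}"
            )

    @property
    def start_day(self) -> int:
        return date_to_day(self.start)

    @property
    def end_day(self) -> int:
        """First day *after* the window (half-open end)."""
        return self.start_day + self.length_days

    @property
    def end(self) -> _dt.date:
        return day_to_date(self.end_day)

    def contains_day(self, day: int) -> bool:
        return self.start_day <= day < self.end_day


FILL_COLUMNS = ["patient_id", "drug_class", "subclass", "fill_date", "days_supply"]
PATIENT_COLUMNS = [
    "patient_id",
    "group",
    "age",
    "sex",
    "race_white",
    "diabetes",
    "bmi",
    "pcp_visits_per_year",
    "charlson",
    "enroll_start",
    "enroll_end",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_date(text: str) -> _dt.date:
    # ISO-8601 only; locale-independent by construction.
    return _dt.date.fromisoformat(text.strip())


def _check_header(header: Sequence[str], expected: Sequence[str], path) -> None:
    if list(header) != list(expected):
        missing = set(expected) - set(header)
        extra = set(header) - set(expected)
        raise FormatError(
            f"{path}: header mismatch (missing={sorted(missing)}, "
            f"unknown={sorted(extra)}, order must be {expected})"
        )


def read_fills(path: str | Path) -> list[FillRecord]:
    """Read a fills CSV into validated :class:`FillRecord` rows.

    Row order is preserved.  Invalid rows are collected and reported together
    in a single :class:`ValidationError` carrying line numbers.
    """
    path = Path(path)
    records: list[FillRecord] = []
    bad: list[tuple[int, str]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected header row")
        _check_header(header, FILL_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                pid, cls, sub, date, supply = row
                days = int(supply)
                if days < 1:
                    raise ValueError(f"days_supply must be >= 1, got {days}")
                records.append(
                    FillRecord(
                        patient_id=pid,
                        drug_class=DrugClass(cls),
                        subclass=sub,
                        fill_date=_parse_date(date),
                        days_supply=days,
                    )
                )
            except (ValueError, ValidationError) as exc:
                bad.append((lineno, str(exc)))
    if bad:
        raise ValidationError(
            f"{path}: {len(bad)} invalid fill row(s): "
            + "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:10]),
            rows=bad,
        )
    return records


def write_fills(records: Iterable[FillRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FILL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.drug_class.value,
                    r.subclass,
                    r.fill_date.isoformat(),
                    r.days_supply,
                ]
            )


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read a patient roster CSV; duplicate patient ids are rejected."""
    path = Path(path)
    records: list[PatientRecord] = []
    bad: list[tuple[int, str]] = []
    seen: dict[str, int] = {}
    dupes: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected header row")
        _check_header(header, PATIENT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                (pid, grp, age, sex, white, diab, bmi, visits, charl,
                 estart, eend) = row
                if pid in seen:
                    dupes.append(pid)
                    continue
                seen[pid] = lineno
                records.append(
                    PatientRecord(
                        patient_id=pid,
                        group=Group(grp),
                        age=int(age),
                        sex=Sex(sex),
                        race_white=_BOOL[white.strip().lower()],
                        diabetes=_BOOL[diab.strip().lower()],
                        bmi=None if bmi.strip() == "" else float(bmi),
                        pcp_visits_per_year=float(visits),
                        charlson=float(charl),
                        enroll_start=_parse_date(estart),
                        enroll_end=_parse_date(eend),
                    )
                )
            except KeyError as exc:
                bad.append((lineno, f"unparseable boolean {exc}"))
            except (ValueError, ValidationError) as exc:
                bad.append((lineno, str(exc)))
    if dupes:
        raise ValidationError(
            f"{path}: duplicate patient_id(s): {sorted(set(dupes))}"
        )
    if bad:
        raise ValidationError(
            f"{path}: {len(bad)} invalid roster row(s): "
            + "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:10]),
            rows=bad,
        )
    return records


def write_patients(records: Iterable[PatientRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.group.value,
                    r.age,
                    r.sex.value,
                    str(r.race_white).lower(),
                    str(r.diabetes).lower(),
                    "" if r.bmi is None else repr(r.bmi),
                    repr(r.pcp_visits_per_year),
                    repr(r.charlson),
                    r.enroll_start.isoformat(),
                    r.enroll_end.isoformat(),
                ]
            )


def write_results(results: dict, path: str | Path) -> None:
    """Write an analysis bundle as JSON plus a human-readable table.

    ``results`` is a mapping with an ``"effects"`` list; each entry is a
    mapping with keys {comparison, class, period, estimate, ci_low, ci_high,
    p, method}.  Floats are serialized with full ``repr`` precision so the
    write/read round-trip is bit-exact.  A sibling ``.txt`` file mirrors the
    layout of a two-arm comparison table.
    """
    path = Path(path)
    with path.open("w") as fh:
        json.dump(results, fh, indent=2, allow_nan=True)
        fh.write("\n")
    lines = [
        f"{'comparison':<40} {'class':<20} {'period':<10} "
        f"{'estimate':>9} {'95% CI':>17} {'p':>6} method"
    ]
    for e in results.get("effects", []):
        est = e.get("estimate")
        lo, hi = e.get("ci_low"), e.get("ci_high")
        p = e.get("p")
        ci = (
            f"({lo:.2f}, {hi:.2f})"
            if lo is not None and hi is not None
            and math.isfinite(lo) and math.isfinite(hi)
            else "(n/a)"
        )
        lines.append(
            f"{e.get('comparison', ''):<40} {e.get('class', ''):<20} "
            f"{e.get('period', ''):<10} "
            f"{est:>9.4f} {ci:>17} "
            f"{format_p(p) if p is not None else 'n/a':>6} {e.get('method', '')}"
        )
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)


def format_p(p: float) -> str:
    """Report-style p: two decimals, no leading zero (".04"); "<.001" floor."""
    if not math.isfinite(p):
        return "n/a"
    if p < 0.001:
        return "<.001"
    return f"{p:.2f}".lstrip("0") if p < 1 else "1.0"
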