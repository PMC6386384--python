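"""Core domain types for GUMCAD-coded sexual-health attendance data.

The unit of observation is one attendance: one person at one provider on one
calendar day, carrying up to 12 GUMCAD sexual-health activity codes plus
reproductive-health and contraception codes. Records are exchanged as plain
CSV (one row per attendance, ``;``-delimited code lists inside a cell).

Money is carried as exact :class:`decimal.Decimal` GBP throughout; figures
are rounded to whole pounds only at presentation.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field, replace
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Setting",
    "Gender",
    "VisitType",
    "AttendanceRecord",
    "CodeSets",
    "DEFAULT_CODE_SETS",
    "TariffSchedule",
    "DEFAULT_TARIFFS",
    "StudyPeriod",
    "PERIOD_BASELINE",
    "ROLLOUT_QUARTER",
    "PERIOD_ONLINE",
    "DEFAULT_PERIODS",
    "SchemaError",
    "RowParseError",
    "ConfigError",
    "read_records",
    "write_records",
    "round_gbp",
    "base_code",
    "RECORD_COLUMNS",
]


class SchemaError(ValueError):
    """The CSV header does not match the documented record schema."""


class RowParseError(ValueError):
    """A CSV row could not be parsed; message carries the 1-based line number."""


class ConfigError(ValueError):
    """Invalid configuration value."""


class Setting(str, enum.Enum):
    GUM_CLINIC = "gum_clinic"
    COMMUNITY_CLINIC = "community_clinic"
    ONLINE = "online"

    @property
    def is_clinic(self) -> bool:
        return self is not Setting.ONLINE


class Gender(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER = "other"


class VisitType(str, enum.Enum):
    FIRST = "first"
    FOLLOWUP = "followup"


_MODIFIER_RE = re.compile(r"^\s*([^(]+?)\s*(?:\(.*\))?\s*$")


def base_code(code: str) -> str:
    """Strip an optional parenthesised site modifier: ``C4 (R,O)`` -> ``C4``.

    GUMCAD prints some diagnosis codes with site modifiers (rectal/oral);
    matching is by base code so ``B``, ``B(R)`` and ``B(R,O)`` are the same
    diagnosis.
    """
    m = _MODIFIER_RE.match(code)
    return m.group(1) if m else code.strip()


@dataclass(frozen=True)
class CodeSets:
    """GUMCAD code vocabulary used to classify attendances.

    ``test_codes`` are the composite STI screen codes (chlamydia, gonorrhoea,
    HIV, syphilis); ``diagnosis_codes`` the corresponding new-diagnosis codes.
    ``treatment_elsewhere_codes`` mark treatment for a diagnosis made at
    another service and are excluded from diagnosis counting.
    """

    test_codes: frozenset[str] = frozenset({"T1", "T2", "T3", "T4", "T7", "T8", "TT"})
    diagnosis_codes: frozenset[str] = frozenset(
        {"A1", "A2", "A3", "A4", "A5", "B(R,O)", "C4(R,O)", "H1", "H1a", "H1b"}
    )
    treatment_elsewhere_codes: frozenset[str] = frozenset()
    triple_site_code: str = "TT"
    genital_test_code: str = "T4"
    # codes recognised as legitimate non-test clinic activity (treatment,
    # examination); anything outside the vocabulary is flagged on read
    other_activity_codes: frozenset[str] = frozenset({"TREAT", "EXAM"})

    def __post_init__(self) -> None:
        if self.test_codes & self.diagnosis_codes:
            raise ConfigError("test_codes and diagnosis_codes must be disjoint")

    @property
    def _test_bases(self) -> frozenset[str]:
        return frozenset(base_code(c) for c in self.test_codes)

    @property
    def _diagnosis_bases(self) -> frozenset[str]:
        return frozenset(base_code(c) for c in self.diagnosis_codes)

    @property
    def _treatment_elsewhere_bases(self) -> frozenset[str]:
        return frozenset(base_code(c) for c in self.treatment_elsewhere_codes)

    def is_test(self, code: str) -> bool:
        return base_code(code) in self._test_bases

    def is_diagnosis(self, code: str) -> bool:
        b = base_code(code)
        return b in self._diagnosis_bases and b not in self._treatment_elsewhere_bases

    def is_treatment_elsewhere(self, code: str) -> bool:
        return base_code(code) in self._treatment_elsewhere_bases

    def is_known(self, code: str) -> bool:
        b = base_code(code)
        return (
            b in self._test_bases
            or b in self._diagnosis_bases
            or b in self._treatment_elsewhere_bases
            or b in frozenset(base_code(c) for c in self.other_activity_codes)
        )


DEFAULT_CODE_SETS = CodeSets()


def _money(x: str | float | int | Decimal) -> Decimal:
    return Decimal(str(x)).quantize(Decimal("0.01"))


@dataclass(frozen=True)
class TariffSchedule:
    """Unit prices (GBP) from the London integrated sexual-health tariff.

    ``primary_simple`` is the stand-alone simple STI test tariff;
    ``additional_complex`` the tariff for testing delivered alongside a
    costlier activity; ``msm_triple`` the flat triple-site (genital, rectal,
    oral) tariff. ``clinic_reference_cost`` and ``online_price`` feed the
    scenario and cross-area models.
    """

    primary_simple: Decimal = Decimal("80.58")
    additional_complex: Decimal = Decimal("56.11")
    msm_triple: Decimal = Decimal("70.24")
    online_price: Decimal = Decimal("30")
    clinic_reference_cost: Decimal = Decimal("66")

    def __post_init__(self) -> None:
        for name in (
            "primary_simple",
            "additional_complex",
            "msm_triple",
            "online_price",
            "clinic_reference_cost",
        ):
            v = _money(getattr(self, name))
            if v <= 0:
                raise ConfigError(f"tariff {name} must be strictly positive")
            object.__setattr__(self, name, v)


DEFAULT_TARIFFS = TariffSchedule()


@dataclass(frozen=True)
class StudyPeriod:
    """A named analysis window measured in whole calendar quarters."""

    name: str
    start_date: date
    end_date: date
    n_quarters: int

    @property
    def n_months(self) -> int:
        return 3 * self.n_quarters

    def contains(self, d: date) -> bool:
        return self.start_date <= d <= self.end_date


PERIOD_BASELINE = StudyPeriod("period1", date(2014, 1, 1), date(2014, 12, 31), 4)
ROLLOUT_QUARTER = StudyPeriod("rollout", date(2015, 1, 1), date(2015, 3, 31), 1)
PERIOD_ONLINE = StudyPeriod("period2", date(2015, 4, 1), date(2016, 6, 30), 5)
DEFAULT_PERIODS = {p.name: p for p in (PERIOD_BASELINE, ROLLOUT_QUARTER, PERIOD_ONLINE)}


@dataclass
class AttendanceRecord:
    """One person-provider-day attendance event.

    ``ordered_only`` marks an online self-sampling kit that was dispatched
    but never returned; such records carry no codes and enter only the
    return-rate accounting, never positivity or costing.
    """

    person_id: str
    visit_date: date
    setting: Setting
    provider_id: str
    age_years: int
    gender: Gender
    msm: bool
    prisoner: bool
    area_code: str
    visit_type: VisitType
    sti_codes: list[str] = field(default_factory=list)
    repro_codes: list[str] = field(default_factory=list)
    contraception_codes: list[str] = field(default_factory=list)
    ordered_only: bool = False

    def all_codes(self) -> list[str]:
        return [*self.sti_codes, *self.repro_codes, *self.contraception_codes]

    def replace(self, **kw) -> "AttendanceRecord":
        return replace(self, **kw)


RECORD_COLUMNS = [
    "person_id",
    "visit_date",
    "setting",
    "provider_id",
    "age_years",
    "gender",
    "msm",
    "prisoner",
    "area_code",
    "visit_type",
    "sti_codes",
    "repro_codes",
    "contraception_codes",
    "ordered_only",
]

# ordered_only is an extension column for online order-only events; files
# without it are read with the flag defaulting to false.
_MANDATORY_COLUMNS = RECORD_COLUMNS[:-1]


def _join_codes(codes: Sequence[str]) -> str:
    return ";".join(codes)


def _split_codes(cell: str) -> list[str]:
    return [c for c in cell.split(";") if c] if cell else []


def _bool_out(b: bool) -> str:
    return "true" if b else "false"


def _bool_in(s: str, line_no: int, col: str) -> bool:
    s = s.strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise RowParseError(f"line {line_no}: cannot parse boolean {col}={s!r}")


def write_records(records: Iterable[AttendanceRecord], path: str | Path) -> None:
    """Write records as CSV with the documented column order.

    Inverse of :func:`read_records`: the round trip is the identity on valid
    records.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RECORD_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.person_id,
                    r.visit_date.isoformat(),
                    r.setting.value,
                    r.provider_id,
                    r.age_years,
                    r.gender.value,
                    _bool_out(r.msm),
                    _bool_out(r.prisoner),
                    r.area_code,
                    r.visit_type.value,
                    _join_codes(r.sti_codes),
                    _join_codes(r.repro_codes),
                    _join_codes(r.contraception_codes),
                    _bool_out(r.ordered_only),
                ]
            )


def read_records(
    path: str | Path, code_sets: CodeSets | None = None
) -> tuple[list[AttendanceRecord], list[str]]:
    """Read an attendance-record CSV.

    Returns ``(records, warnings)``. Codes outside the configured vocabulary
    are preserved verbatim and reported as warnings, one per occurrence.

    Raises
    ------
    SchemaError
        if a mandatory column is missing from the header.
    RowParseError
        if a row has an unparseable date, age or enum (message names the
        1-based line number).
    """
    cs = code_sets or DEFAULT_CODE_SETS
    records: list[AttendanceRecord] = []
    warnings: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing mandatory column {col!r}")
        for line_no, row in enumerate(reader, start=2):
            try:
                visit_date = date.fromisoformat(row["visit_date"].strip())
            except ValueError as exc:
                raise RowParseError(
                    f"line {line_no}: unparseable visit_date {row['visit_date']!r}"
                ) from exc
            try:
                age = int(row["age_years"])
            except ValueError as exc:
                raise RowParseError(
                    f"line {line_no}: unparseable age_years {row['age_years']!r}"
                ) from exc
            try:
                setting = Setting(row["setting"].strip())
                gender = Gender(row["gender"].strip())
                visit_type = VisitType(row["visit_type"].strip())
            except ValueError as exc:
                raise RowParseError(f"line {line_no}: {exc}") from exc
            sti = _split_codes(row["sti_codes"])
            for c in sti:
                if not cs.is_known(c):
                    warnings.append(f"line {line_no}: unknown code {c!r}")
            records.append(
                AttendanceRecord(
                    person_id=row["person_id"],
                    visit_date=visit_date,
                    setting=setting,
                    provider_id=row["provider_id"],
                    age_years=age,
                    gender=gender,
                    msm=_bool_in(row["msm"], line_no, "msm"),
                    prisoner=_bool_in(row["prisoner"], line_no, "prisoner"),
                    area_code=row["area_code"],
                    visit_type=visit_type,
                    sti_codes=sti,
                    repro_codes=_split_codes(row["repro_codes"]),
                    contraception_codes=_split_codes(row["contraception_codes"]),
                    ordered_only=_bool_in(row.get("ordered_only", ""), line_no, "ordered_only"),
                )
            )
    return records, warnings


def round_gbp(x: Decimal | float | int) -> Decimal:
    """Round to the nearest whole pound (half up), for presentation."""
    return Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)


def quarter_of(d: date) -> tuple[int, int]:
    """Calendar quarter of a date as ``(year, quarter)``; Q1 = Jan-Mar."""
    return d.year, (d.month - 1) // 3 + 1


def quarter_label(d: date) -> str:
    y, q = quarter_of(d)
    return f"{y}Q{q}"


def quarters_between(start: date, end: date) -> int:
    """Number of calendar quarters from start's quarter to end's, inclusive."""
    (y0, q0), (y1, q1) = quarter_of(start), quarter_of(end)
    return (y1 - y0) * 4 + (q1 - q0) + 1
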