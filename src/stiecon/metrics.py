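"""Visit classification and quarterly testing/positivity summaries.

Positivity here is the composite measure over the four screened infections
(chlamydia, gonorrhoea, syphilis, HIV): diagnoses divided by test-or-diagnosis
episodes. Clinic diagnoses are not always tied to a test episode, so the
denominator counts any record bearing a test *or* a diagnosis code; online
records count only when the kit was returned.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .model import (
    AttendanceRecord,
    CodeSets,
    DEFAULT_CODE_SETS,
    Setting,
    base_code,
    quarter_label,
)

__all__ = [
    "Complexity",
    "SiteScope",
    "SettingGroup",
    "VisitClassification",
    "QuarterSummary",
    "classify_visit",
    "quarterly_summaries",
    "online_share",
    "percent_change",
    "online_return_rate",
]


class Complexity(str, enum.Enum):
    SIMPLE = "simple"
    COMPLEX = "complex"


class SiteScope(str, enum.Enum):
    GENITAL = "genital"
    TRIPLE_SITE = "triple_site"


class SettingGroup(str, enum.Enum):
    CLINIC = "clinic"
    ONLINE = "online"
    ALL = "all"


@dataclass(frozen=True)
class VisitClassification:
    has_test: bool
    has_diagnosis: bool
    complexity: Complexity
    site_scope: SiteScope
    setting: Setting


@dataclass(frozen=True)
class QuarterSummary:
    """One cell block of the quarterly activity table.

    ``positivity`` is ``n_diagnoses / n_tests_or_diagnoses``, or ``None``
    when the denominator is zero (undefined, not 0%).
    """

    quarter: str
    setting_group: SettingGroup
    n_tests_or_diagnoses: int
    n_diagnoses: int

    @property
    def positivity(self) -> float | None:
        if self.n_tests_or_diagnoses == 0:
            return None
        return self.n_diagnoses / self.n_tests_or_diagnoses


def classify_visit(
    record: AttendanceRecord, code_sets: CodeSets | None = None
) -> VisitClassification:
    """Label one harmonised attendance.

    A visit is *complex* when any code (STI, reproductive or contraception
    list) falls outside the test and diagnosis vocabularies — testing was
    delivered alongside another clinical activity. Online visits are always
    simple since the service offers nothing beyond the test. Triple-site
    applies when the TT (genital + rectal + oral) code is present.
    """
    cs = code_sets or DEFAULT_CODE_SETS
    codes = record.all_codes()
    has_test = any(cs.is_test(c) for c in codes)
    has_diagnosis = any(cs.is_diagnosis(c) for c in codes)
    if record.setting is Setting.ONLINE:
        complexity = Complexity.SIMPLE
    else:
        complexity = (
            Complexity.COMPLEX
            if any(not (cs.is_test(c) or cs.is_diagnosis(c)) for c in codes)
            else Complexity.SIMPLE
        )
    triple = any(base_code(c) == base_code(cs.triple_site_code) for c in record.sti_codes)
    return VisitClassification(
        has_test=has_test,
        has_diagnosis=has_diagnosis,
        complexity=complexity,
        site_scope=SiteScope.TRIPLE_SITE if triple else SiteScope.GENITAL,
        setting=record.setting,
    )


def _counts_in_denominator(r: AttendanceRecord, cs: CodeSets) -> bool:
    if r.ordered_only:
        return False
    return any(cs.is_test(c) or cs.is_diagnosis(c) for c in r.all_codes())


def quarterly_summaries(
    records: list[AttendanceRecord], code_sets: CodeSets | None = None
) -> list[QuarterSummary]:
    """Per-quarter, per-setting-group test/diagnosis counts and positivity.

    Input should already be harmonised and deduplicated. For each calendar
    quarter three rows are produced — clinic (GUM + community), online
    (returned kits only) and the pooled total — ordered by quarter then
    group. Records outside any configured window still count into their own
    calendar quarter; nothing is silently dropped.
    """
    cs = code_sets or DEFAULT_CODE_SETS
    denom: dict[tuple[str, SettingGroup], int] = {}
    diag: dict[tuple[str, SettingGroup], int] = {}
    quarters: list[str] = []
    for r in records:
        if not _counts_in_denominator(r, cs):
            continue
        q = quarter_label(r.visit_date)
        if q not in quarters:
            quarters.append(q)
        group = SettingGroup.ONLINE if r.setting is Setting.ONLINE else SettingGroup.CLINIC
        has_diag = any(cs.is_diagnosis(c) for c in r.all_codes())
        for g in (group, SettingGroup.ALL):
            denom[q, g] = denom.get((q, g), 0) + 1
            if has_diag:
                diag[q, g] = diag.get((q, g), 0) + 1
    out: list[QuarterSummary] = []
    for q in sorted(quarters):
        for g in (SettingGroup.CLINIC, SettingGroup.ONLINE, SettingGroup.ALL):
            out.append(
                QuarterSummary(
                    quarter=q,
                    setting_group=g,
                    n_tests_or_diagnoses=denom.get((q, g), 0),
                    n_diagnoses=diag.get((q, g), 0),
                )
            )
    return out


def online_share(summaries: list[QuarterSummary], quarter: str) -> float:
    """Fraction of the quarter's test-or-diagnosis episodes done online.

    Raises ``LookupError`` if the quarter is absent from the summaries.
    """
    rows = {s.setting_group: s for s in summaries if s.quarter == quarter}
    if not rows:
        raise LookupError(f"no summaries for quarter {quarter!r}")
    n_online = rows[SettingGroup.ONLINE].n_tests_or_diagnoses if SettingGroup.ONLINE in rows else 0
    n_clinic = rows[SettingGroup.CLINIC].n_tests_or_diagnoses if SettingGroup.CLINIC in rows else 0
    total = n_online + n_clinic
    if total == 0:
        return 0.0
    return n_online / total


def percent_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``; requires ``before > 0``."""
    if before <= 0:
        raise ValueError(f"percent_change needs before > 0, got {before}")
    return 100.0 * (after - before) / before


def online_return_rate(records: list[AttendanceRecord]) -> float | None:
    """Returned kits / dispatched kits, from *raw* (pre-harmonisation) records.

    Order-only events carry no codes and are removed by the no-codes
    exclusion, so the return rate must be measured before harmonisation.
    Returns ``None`` when no kit was dispatched.
    """
    dispatched = sum(1 for r in records if r.setting is Setting.ONLINE)
    if dispatched == 0:
        return None
    returned = sum(1 for r in records if r.setting is Setting.ONLINE and not r.ordered_only)
    return returned / dispatched
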