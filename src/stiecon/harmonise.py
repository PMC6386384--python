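"""Harmonise raw attendance records into one analysable event stream.

Three stages, applied in order:

1. **Exclusions** — drop records with no codes at all, ages outside 16-99,
   or a prisoner flag (the data-cleaning rules of the source dataset).
2. **Same-day collapse** — one record per person per provider per day; code
   lists are merged as an order-preserving union.
3. **Six-week deduplication** — clinic diagnoses are not tied to a specific
   test episode, so within each provider a person contributes at most one
   test-or-diagnosis record per six-week window, keeping the record with the
   most diagnosis codes.

Every stage is conservative of counts: the :class:`HarmonisationReport`
identity ``n_output = n_input - exclusions - collapsed - removed`` is
asserted at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .model import AttendanceRecord, CodeSets, ConfigError, DEFAULT_CODE_SETS

__all__ = [
    "HarmonisationReport",
    "apply_exclusions",
    "collapse_same_day",
    "deduplicate_six_week",
    "harmonise",
]

DedupScope = Literal["provider", "person"]


@dataclass
class HarmonisationReport:
    n_input: int = 0
    n_excluded_no_codes: int = 0
    n_excluded_age: int = 0
    n_excluded_prisoner: int = 0
    n_collapsed_same_day: int = 0
    n_removed_6week: int = 0
    n_output: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_no_codes + self.n_excluded_age + self.n_excluded_prisoner

    def check(self) -> None:
        expected = (
            self.n_input - self.n_excluded - self.n_collapsed_same_day - self.n_removed_6week
        )
        if self.n_output != expected:
            raise AssertionError(
                f"harmonisation count identity violated: n_output={self.n_output}, "
                f"expected {expected}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_excluded_no_codes": self.n_excluded_no_codes,
            "n_excluded_age": self.n_excluded_age,
            "n_excluded_prisoner": self.n_excluded_prisoner,
            "n_collapsed_same_day": self.n_collapsed_same_day,
            "n_removed_6week": self.n_removed_6week,
            "n_output": self.n_output,
        }


def apply_exclusions(
    records: list[AttendanceRecord],
) -> tuple[list[AttendanceRecord], HarmonisationReport]:
    """Drop no-code, under-16, 100-plus and prisoner records.

    Each dropped record is counted under the first matching reason, checked
    in the order no-codes, age, prisoner. Retained records pass through
    unchanged.
    """
    report = HarmonisationReport(n_input=len(records))
    kept: list[AttendanceRecord] = []
    for r in records:
        if not r.all_codes():
            report.n_excluded_no_codes += 1
        elif r.age_years < 16 or r.age_years >= 100:
            report.n_excluded_age += 1
        elif r.prisoner:
            report.n_excluded_prisoner += 1
        else:
            kept.append(r)
    report.n_output = len(kept)
    report.check()
    return kept, report


def _union_preserving_order(lists: list[list[str]]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for codes in lists:
        for c in codes:
            if c not in seen:
                seen.add(c)
                out.append(c)
    return out


def collapse_same_day(records: list[AttendanceRecord]) -> list[AttendanceRecord]:
    """Merge to one record per (person, provider, day).

    Code lists become the de-duplicated union in input order; all other
    fields are taken from the group's first record in input order. Output
    preserves the input order of group first-occurrences.
    """
    groups: dict[tuple[str, str, object], list[AttendanceRecord]] = {}
    order: list[tuple[str, str, object]] = []
    for r in records:
        key = (r.person_id, r.provider_id, r.visit_date)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    out: list[AttendanceRecord] = []
    for key in order:
        grp = groups[key]
        first = grp[0]
        if len(grp) == 1:
            out.append(first)
        else:
            out.append(
                first.replace(
                    sti_codes=_union_preserving_order([g.sti_codes for g in grp]),
                    repro_codes=_union_preserving_order([g.repro_codes for g in grp]),
                    contraception_codes=_union_preserving_order(
                        [g.contraception_codes for g in grp]
                    ),
                )
            )
    return out


def _n_diagnosis_codes(r: AttendanceRecord, cs: CodeSets) -> int:
    return sum(1 for c in r.all_codes() if cs.is_diagnosis(c))


def _bears_test_or_diagnosis(r: AttendanceRecord, cs: CodeSets) -> bool:
    return any(cs.is_test(c) or cs.is_diagnosis(c) for c in r.all_codes())


def deduplicate_six_week(
    records: list[AttendanceRecord],
    code_sets: CodeSets | None = None,
    window_days: int = 42,
    scope: DedupScope = "provider",
) -> tuple[list[AttendanceRecord], HarmonisationReport]:
    """Restrict to one test-or-diagnosis record per person per six weeks.

    Within each (person, provider) group — or per person across providers
    when ``scope='person'`` — records are sorted by date and resolved
    greedily: the selection pool is the maximal run of records strictly
    within ``window_days`` days of the earliest unresolved record (half-open
    window, so a record exactly ``window_days`` later is outside it). From
    the pool exactly one record is kept: the one with the most diagnosis
    codes, ties broken by earliest date, then by stable input order. Any
    record dated strictly within ``window_days`` days after the *kept*
    record is also suppressed, so retained records are always at least
    ``window_days`` days apart and the operation is idempotent. Records
    bearing no test or diagnosis code pass through untouched.
    """
    cs = code_sets or DEFAULT_CODE_SETS
    if window_days < 1:
        raise ConfigError(f"window_days must be >= 1, got {window_days}")
    if scope not in ("provider", "person"):
        raise ConfigError(f"unknown dedup scope {scope!r}")

    report = HarmonisationReport(n_input=len(records))
    keep_idx: set[int] = set()
    groups: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        if not _bears_test_or_diagnosis(r, cs):
            keep_idx.add(i)
            continue
        key = (r.person_id, r.provider_id) if scope == "provider" else (r.person_id,)
        groups.setdefault(key, []).append(i)

    for idxs in groups.values():
        idxs_sorted = sorted(idxs, key=lambda i: (records[i].visit_date, i))
        pos = 0
        while pos < len(idxs_sorted):
            anchor_date = records[idxs_sorted[pos]].visit_date
            cluster = [idxs_sorted[pos]]
            nxt = pos + 1
            while (
                nxt < len(idxs_sorted)
                and (records[idxs_sorted[nxt]].visit_date - anchor_date).days < window_days
            ):
                cluster.append(idxs_sorted[nxt])
                nxt += 1
            # most diagnosis codes, then earliest date, then input order
            best = min(
                cluster,
                key=lambda i: (-_n_diagnosis_codes(records[i], cs), records[i].visit_date, i),
            )
            keep_idx.add(best)
            # everything within the window of the kept record is spoken for
            best_date = records[best].visit_date
            while (
                nxt < len(idxs_sorted)
                and (records[idxs_sorted[nxt]].visit_date - best_date).days < window_days
            ):
                nxt += 1
            pos = nxt

    kept = [r for i, r in enumerate(records) if i in keep_idx]
    report.n_removed_6week = len(records) - len(kept)
    report.n_output = len(kept)
    report.check()
    return kept, report


def harmonise(
    records: list[AttendanceRecord],
    code_sets: CodeSets | None = None,
    window_days: int = 42,
    scope: DedupScope = "provider",
) -> tuple[list[AttendanceRecord], HarmonisationReport]:
    """Run exclusions, same-day collapse and six-week deduplication in order."""
    excluded, rep1 = apply_exclusions(records)
    collapsed = collapse_same_day(excluded)
    deduped, rep2 = deduplicate_six_week(collapsed, code_sets, window_days, scope)
    report = HarmonisationReport(
        n_input=rep1.n_input,
        n_excluded_no_codes=rep1.n_excluded_no_codes,
        n_excluded_age=rep1.n_excluded_age,
        n_excluded_prisoner=rep1.n_excluded_prisoner,
        n_collapsed_same_day=len(excluded) - len(collapsed),
        n_removed_6week=rep2.n_removed_6week,
        n_output=len(deduped),
    )
    report.check()
    return deduped, report
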