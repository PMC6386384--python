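"""Exclusion filters, same-day collapse, and the six-week deduplication rule.

The deduplication is checked against an independent set-based restatement of
the rule (repeatedly take the earliest remaining event, resolve its whole
window, remove it) on random small instances.
"""

from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from stiecon import (
    CodeSets,
    ConfigError,
    DEFAULT_CODE_SETS,
    apply_exclusions,
    collapse_same_day,
    deduplicate_six_week,
    harmonise,
)

from conftest import make_record

D0 = date(2015, 3, 1)


def _n_diag(rec, cs):
    return sum(1 for c in rec.all_codes() if cs.is_diagnosis(c))


def brute_force_dedup(records, cs=DEFAULT_CODE_SETS, window_days=42):
    """Set-based restatement of the one-per-six-weeks rule.

    Repeatedly take the earliest remaining test/diagnosis event of each
    (person, provider) group, gather everything strictly within the window
    of it, keep the best record of that set, and discard the rest together
    with anything strictly within the window after the kept record.
    """
    keep = set()
    groups = {}
    for i, r in enumerate(records):
        if any(cs.is_test(c) or cs.is_diagnosis(c) for c in r.all_codes()):
            groups.setdefault((r.person_id, r.provider_id), []).append(i)
        else:
            keep.add(i)
    for idxs in groups.values():
        remaining = set(idxs)
        while remaining:
            anchor = min(remaining, key=lambda i: (records[i].visit_date, i))
            window = {
                i
                for i in remaining
                if (records[i].visit_date - records[anchor].visit_date).days < window_days
            }
            best = sorted(
                window,
                key=lambda i: (-_n_diag(records[i], cs), records[i].visit_date, i),
            )[0]
            keep.add(best)
            shadow = {
                i
                for i in remaining
                if (records[i].visit_date - records[best].visit_date).days < window_days
            }
            remaining -= window | shadow
    return [r for i, r in enumerate(records) if i in keep]


class TestExclusions:
    @pytest.mark.parametrize(
        "age,kept", [(15, False), (16, True), (99, True), (100, False)]
    )
    def test_age_boundaries(self, age, kept):
        out, _ = apply_exclusions([make_record(age_years=age, sti_codes=["T4"])])
        assert bool(out) is kept

    def test_prisoner_and_no_code_records_dropped(self):
        recs = [
            make_record(person_id="A", sti_codes=["T4"], prisoner=True),
            make_record(person_id="B"),  # no codes at all
            make_record(person_id="C", repro_codes=["R1"]),  # codes in another list
        ]
        out, report = apply_exclusions(recs)
        assert [r.person_id for r in out] == ["C"]
        assert report.n_excluded_prisoner == 1
        assert report.n_excluded_no_codes == 1

    def test_first_matching_reason_wins(self):
        # no codes AND prisoner AND under-age: counted once, as no-codes
        rec = make_record(prisoner=True, age_years=14)
        _, report = apply_exclusions([rec])
        assert report.n_excluded_no_codes == 1
        assert report.n_excluded_age == 0
        assert report.n_excluded_prisoner == 0

    def test_empty_input_gives_all_zero_report(self):
        out, report = apply_exclusions([])
        assert out == []
        assert all(v == 0 for v in report.as_dict().values())


class TestSameDayCollapse:
    def test_same_day_codes_union_in_input_order(self):
        a = make_record(sti_codes=["T4"])
        b = make_record(sti_codes=["C4", "T4"])
        (merged,) = collapse_same_day([a, b])
        assert merged.sti_codes == ["T4", "C4"]

    def test_non_code_fields_come_from_first_record(self):
        a = make_record(age_years=30, sti_codes=["T4"])
        b = make_record(age_years=31, sti_codes=["C4"])
        (merged,) = collapse_same_day([a, b])
        assert merged.age_years == 30

    def test_different_days_unchanged(self):
        a = make_record(visit_date=D0, sti_codes=["T4"])
        b = make_record(visit_date=D0 + timedelta(days=1), sti_codes=["T4"])
        assert collapse_same_day([a, b]) == [a, b]

    def test_different_providers_not_merged(self):
        a = make_record(provider_id="CLINIC_A", sti_codes=["T4"])
        b = make_record(provider_id="CLINIC_B", sti_codes=["C4"])
        assert len(collapse_same_day([a, b])) == 2

    def test_identical_duplicates_become_one(self):
        a = make_record(sti_codes=["T4"])
        out = collapse_same_day([a, a])
        assert out == [a]


class TestSixWeekDedup:
    def test_keeps_record_with_most_diagnosis_codes(self):
        a = make_record(visit_date=D0, sti_codes=["T4"])
        b = make_record(visit_date=D0 + timedelta(days=30), sti_codes=["T4", "C4"])
        out, report = deduplicate_six_week([a, b])
        assert out == [b]
        assert report.n_removed_6week == 1

    def test_window_is_half_open_at_42_days(self):
        a = make_record(visit_date=D0, sti_codes=["T4"])
        b = make_record(visit_date=D0 + timedelta(days=42), sti_codes=["T4"])
        out, _ = deduplicate_six_week([a, b])
        assert out == [a, b]

    def test_tie_keeps_earliest(self):
        a = make_record(visit_date=D0 + timedelta(days=10), sti_codes=["T4"])
        b = make_record(visit_date=D0, sti_codes=["T4"])
        out, _ = deduplicate_six_week([a, b])
        assert out == [b]

    def test_single_record_kept(self):
        a = make_record(sti_codes=["T4"])
        assert deduplicate_six_week([a])[0] == [a]

    def test_records_without_test_or_diagnosis_pass_through(self):
        a = make_record(sti_codes=["TREAT"])
        b = make_record(visit_date=D0, sti_codes=["T4"])
        c = make_record(visit_date=D0 + timedelta(days=5), sti_codes=["T4"])
        out, _ = deduplicate_six_week([a, b, c])
        assert a in out and len(out) == 2

    def test_treatment_elsewhere_only_record_passes_through_uncounted(self):
        cs = CodeSets(treatment_elsewhere_codes=frozenset({"C4"}))
        a = make_record(visit_date=D0, sti_codes=["C4"])  # treated-elsewhere only
        b = make_record(visit_date=D0 + timedelta(days=3), sti_codes=["T4"])
        c = make_record(visit_date=D0 + timedelta(days=6), sti_codes=["T4"])
        out, _ = deduplicate_six_week([a, b, c], cs)
        assert a in out  # not a test/diagnosis record under this vocabulary
        assert len(out) == 2

    def test_provider_scope_keeps_cross_clinic_pairs(self):
        a = make_record(provider_id="CLINIC_A", visit_date=D0, sti_codes=["T4"])
        b = make_record(provider_id="CLINIC_B", visit_date=D0 + timedelta(days=5), sti_codes=["T4"])
        out_provider, _ = deduplicate_six_week([a, b], scope="provider")
        out_person, _ = deduplicate_six_week([a, b], scope="person")
        assert len(out_provider) == 2
        assert len(out_person) == 1

    @pytest.mark.parametrize("bad", [0, -5])
    def test_window_must_be_positive(self, bad):
        with pytest.raises(ConfigError):
            deduplicate_six_week([], window_days=bad)

    def test_scope_must_be_known(self):
        with pytest.raises(ConfigError):
            deduplicate_six_week([], scope="economy")


# random small instances: one person, up to 6 events in a 120-day span
_events = st.lists(
    st.tuples(st.integers(0, 119), st.integers(0, 2), st.booleans()),
    min_size=0,
    max_size=6,
)


def _build(events, persons=("P1",)):
    recs = []
    for pid in persons:
        for day, n_diag, has_test in events:
            codes = (["T4"] if has_test else []) + ["C4", "A1"][:n_diag]
            recs.append(
                make_record(
                    person_id=pid,
                    visit_date=D0 + timedelta(days=day),
                    sti_codes=codes,
                )
            )
    return recs


@settings(max_examples=300, derandomize=True)
@given(_events)
def test_dedup_matches_brute_force_oracle(events):
    recs = _build(events)
    got, _ = deduplicate_six_week(recs)
    expected = brute_force_dedup(recs)
    assert got == expected


@settings(max_examples=200, derandomize=True)
@given(_events)
def test_dedup_is_idempotent_and_window_clean(events):
    recs = _build(events)
    once, _ = deduplicate_six_week(recs)
    twice, report = deduplicate_six_week(once)
    assert twice == once
    assert report.n_removed_6week == 0
    kept = [
        r for r in once
        if any(DEFAULT_CODE_SETS.is_test(c) or DEFAULT_CODE_SETS.is_diagnosis(c)
               for c in r.all_codes())
    ]
    dates = sorted(r.visit_date for r in kept)
    assert all((b - a).days >= 42 for a, b in zip(dates, dates[1:]))


def test_full_harmonise_report_identity(paper_cohort):
    records, report = harmonise(paper_cohort)
    assert report.n_output == len(records)
    assert report.n_output == (
        report.n_input
        - report.n_excluded
        - report.n_collapsed_same_day
        - report.n_removed_6week
    )
    assert report.n_output <= report.n_input
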