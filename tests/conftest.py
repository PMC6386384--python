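from datetime import date

import pytest

from stiecon import (
    AttendanceRecord,
    Gender,
    Setting,
    VisitType,
    default_paper_config,
    harmonise,
    synthesize_cohort,
)


def make_record(
    person_id="P1",
    visit_date=date(2014, 2, 10),
    setting=Setting.GUM_CLINIC,
    provider_id="CLINIC_A",
    age_years=30,
    gender=Gender.FEMALE,
    msm=False,
    prisoner=False,
    area_code="E01000001",
    visit_type=VisitType.FIRST,
    sti_codes=None,
    repro_codes=None,
    contraception_codes=None,
    ordered_only=False,
):
    return AttendanceRecord(
        person_id=person_id,
        visit_date=visit_date,
        setting=setting,
        provider_id=provider_id,
        age_years=age_years,
        gender=gender,
        msm=msm,
        prisoner=prisoner,
        area_code=area_code,
        visit_type=visit_type,
        sti_codes=list(sti_codes) if sti_codes else [],
        repro_codes=list(repro_codes) if repro_codes else [],
        contraception_codes=list(contraception_codes) if contraception_codes else [],
        ordered_only=ordered_only,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def paper_cohort():
    """One 20,000-person cohort at the observed-service study conditions."""
    return synthesize_cohort(default_paper_config(seed=2014, n_persons=20_000))


@pytest.fixture(scope="session")
def harmonised_cohort(paper_cohort):
    records, report = harmonise(paper_cohort)
    return records, report
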