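"""Synthetic attendance-record cohorts with the structure the analysis assumes.

The generator emulates an inner-city sexual-health economy observed over two
eras: a clinic-only baseline, then a period in which an online self-sampling
service takes a configurable share of testing. Per-setting positivity, the
simple/complex clinic visit mix, MSM triple-site testing, the online kit
return rate, repeat testers (to exercise the six-week deduplication) and
exclusion-triggering records (no codes, under-16, 100+, prisoner) are all
explicit, recoverable parameters.

Positivity is a configured marginal probability, not an emergent epidemic
quantity. A repeat tester's two visits belong to one infection episode and
share a single positivity draw, so deduplication (which prefers the record
with the most diagnosis codes) leaves the configured marginal intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from random import Random

from .model import (
    AttendanceRecord,
    ConfigError,
    Gender,
    Setting,
    VisitType,
    quarter_of,
    quarters_between,
)

__all__ = ["SyntheticConfig", "synthesize_cohort", "default_paper_config"]

_DIAGNOSIS_CHOICES = ("C4", "A1", "B", "H1")
_COMPLEX_ACTIVITY_CHOICES = ("TREAT", "EXAM")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``online_uptake_by_quarter`` gives, for each calendar quarter from
    ``online_start`` to ``study_end``, the probability that a testing episode
    in that quarter is ordered online (a dispatched kit; only ``return_rate``
    of dispatches complete). ``repeat_tester_fraction`` of persons test a
    second time 7-41 days after the first, at the same provider.
    """

    seed: int = 0
    n_persons: int = 20_000
    study_start: date = date(2014, 1, 1)
    study_end: date = date(2016, 6, 30)
    online_start: date = date(2015, 4, 1)
    clinic_positivity: float = 0.10
    online_positivity: float = 0.07
    # one entry per calendar quarter from online_start to study_end;
    # None means no online uptake at all (clinic-only stream)
    online_uptake_by_quarter: tuple[float, ...] | None = None
    simple_visit_fraction: float = 0.39
    msm_fraction: float = 0.105
    return_rate: float = 0.75
    repeat_tester_fraction: float = 0.10
    exclusion_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "no_codes": 0.010,
            "under_16": 0.004,
            "over_99": 0.001,
            "prisoner": 0.002,
        }
    )

    def __post_init__(self) -> None:
        if not (self.study_start < self.online_start <= self.study_end):
            raise ConfigError("require study_start < online_start <= study_end")
        if self.online_uptake_by_quarter is None:
            n_q = quarters_between(self.online_start, self.study_end)
            object.__setattr__(self, "online_uptake_by_quarter", (0.0,) * n_q)
        probs = {
            "clinic_positivity": self.clinic_positivity,
            "online_positivity": self.online_positivity,
            "simple_visit_fraction": self.simple_visit_fraction,
            "msm_fraction": self.msm_fraction,
            "return_rate": self.return_rate,
            "repeat_tester_fraction": self.repeat_tester_fraction,
            **{f"exclusion_fractions[{k}]": v for k, v in self.exclusion_fractions.items()},
            **{
                f"online_uptake_by_quarter[{i}]": v
                for i, v in enumerate(self.online_uptake_by_quarter)
            },
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name}={p} is not a probability in [0, 1]")
        expected = quarters_between(self.online_start, self.study_end)
        if len(self.online_uptake_by_quarter) != expected:
            raise ConfigError(
                f"online_uptake_by_quarter must have {expected} entries "
                f"(quarters from online_start to study_end), "
                f"got {len(self.online_uptake_by_quarter)}"
            )
        if self.n_persons < 0:
            raise ConfigError("n_persons must be non-negative")
        unknown = set(self.exclusion_fractions) - {"no_codes", "under_16", "over_99", "prisoner"}
        if unknown:
            raise ConfigError(f"unknown exclusion fractions: {sorted(unknown)}")


def default_paper_config(seed: int = 0, n_persons: int = 20_000) -> SyntheticConfig:
    """Study conditions calibrated to the observed London service.

    Clinic positivity 10%, online positivity 7%, kit return rate 75%, and an
    online uptake set so that completed online tests make up ~37% of all
    completed tests in the online era. Uptake applies to dispatched kits, of
    which only the return-rate fraction complete, so a target completed share
    sigma needs uptake u = sigma / (sigma + R(1 - sigma)).
    """
    sigma, rate = 0.37, 0.75
    uptake = sigma / (sigma + rate * (1.0 - sigma))
    n_q = quarters_between(date(2015, 4, 1), date(2016, 6, 30))
    return SyntheticConfig(
        seed=seed,
        n_persons=n_persons,
        online_uptake_by_quarter=(uptake,) * n_q,
    )


def _uniform_date(rng: Random, start: date, end: date) -> date:
    return date.fromordinal(rng.randint(start.toordinal(), end.toordinal()))


def _uptake_for(cfg: SyntheticConfig, d: date) -> float:
    idx = quarters_between(cfg.online_start, d) - 1
    return cfg.online_uptake_by_quarter[idx]


def synthesize_cohort(config: SyntheticConfig) -> list[AttendanceRecord]:
    """Generate one cohort of attendance records, deterministic in the seed.

    Each non-excluded person tests once (twice for repeat testers) at a date
    uniform over the study window. Clinic visits carry T4 (or TT for MSM),
    one extra activity code when complex, and a diagnosis code when the
    episode is positive. Online orders on/after ``online_start`` become
    either a completed test (simple, test + optional diagnosis codes) or an
    order-only record with no codes and ``ordered_only`` set.
    """
    rng = Random(config.seed)
    records: list[AttendanceRecord] = []
    excl = config.exclusion_fractions

    for i in range(config.n_persons):
        pid = f"P{i:07d}"
        area = f"E01{rng.randrange(100_000):06d}"
        u = rng.random()
        threshold = 0.0
        persona = "tester"
        for kind in ("no_codes", "under_16", "over_99", "prisoner"):
            threshold += excl.get(kind, 0.0)
            if u < threshold:
                persona = kind
                break

        if persona != "tester":
            records.append(_exclusion_record(rng, config, pid, area, persona))
            continue

        msm = rng.random() < config.msm_fraction
        gender = Gender.MALE if msm else (Gender.MALE if rng.random() < 0.5 else Gender.FEMALE)
        age = rng.randint(16, 65)
        clinic_provider = rng.choice(("CLINIC_A", "CLINIC_B", "COMMUNITY_A"))
        clinic_setting = (
            Setting.COMMUNITY_CLINIC if clinic_provider.startswith("COMMUNITY") else Setting.GUM_CLINIC
        )

        d0 = _uniform_date(rng, config.study_start, config.study_end)
        dates = [d0]
        if rng.random() < config.repeat_tester_fraction:
            d1 = d0 + timedelta(days=rng.randint(7, 41))
            if d1 <= config.study_end:
                dates.append(d1)

        online = d0 >= config.online_start and rng.random() < _uptake_for(config, d0)
        positivity = config.online_positivity if online else config.clinic_positivity
        episode_positive = rng.random() < positivity
        diagnosis = rng.choice(_DIAGNOSIS_CHOICES) if episode_positive else None

        for k, d in enumerate(dates):
            visit_type = VisitType.FIRST if k == 0 else VisitType.FOLLOWUP
            if online:
                returned = rng.random() < config.return_rate
                if returned:
                    sti = ["T4"] + ([diagnosis] if diagnosis else [])
                else:
                    sti = []
                records.append(
                    AttendanceRecord(
                        person_id=pid,
                        visit_date=d,
                        setting=Setting.ONLINE,
                        provider_id="ONLINE",
                        age_years=age,
                        gender=gender,
                        msm=msm,
                        prisoner=False,
                        area_code=area,
                        visit_type=visit_type,
                        sti_codes=sti,
                        ordered_only=not returned,
                    )
                )
            else:
                sti = ["TT" if msm else "T4"]
                if diagnosis:
                    sti.append(diagnosis)
                if rng.random() >= config.simple_visit_fraction:
                    sti.append(rng.choice(_COMPLEX_ACTIVITY_CHOICES))
                records.append(
                    AttendanceRecord(
                        person_id=pid,
                        visit_date=d,
                        setting=clinic_setting,
                        provider_id=clinic_provider,
                        age_years=age,
                        gender=gender,
                        msm=msm,
                        prisoner=False,
                        area_code=area,
                        visit_type=visit_type,
                        sti_codes=sti,
                    )
                )

    records.sort(key=lambda r: (r.visit_date, r.person_id))
    return records


def _exclusion_record(
    rng: Random, config: SyntheticConfig, pid: str, area: str, kind: str
) -> AttendanceRecord:
    """One clinic record that trips exactly the requested exclusion filter."""
    age = rng.randint(16, 65)
    sti = ["T4"]
    prisoner = False
    if kind == "no_codes":
        sti = []
    elif kind == "under_16":
        age = rng.randint(13, 15)
    elif kind == "over_99":
        age = rng.randint(100, 105)
    elif kind == "prisoner":
        prisoner = True
    return AttendanceRecord(
        person_id=pid,
        visit_date=_uniform_date(rng, config.study_start, config.study_end),
        setting=Setting.GUM_CLINIC,
        provider_id="CLINIC_A",
        age_years=age,
        gender=Gender.MALE if rng.random() < 0.5 else Gender.FEMALE,
        msm=False,
        prisoner=prisoner,
        area_code=area,
        visit_type=VisitType.FIRST,
        sti_codes=sti,
    )
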