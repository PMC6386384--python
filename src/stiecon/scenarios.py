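"""Closed-form whole-system scenario models for online STI testing.

With clinic unit cost C, online/clinic cost ratio r, online share of tests f,
clinic positivity p and online/clinic positivity ratio rho (total testing
volume held constant):

* blended cost per test        ``C [(1 - f) + f r]``
* blended cost per diagnosis   ``C [(1 - f) + f r] / (p [(1 - f) + f rho])``
* break-even positivity ratio  ``rho* = r`` — cost per diagnosis is
  decreasing in f when rho > r, flat at rho = r, increasing when rho < r.

For the online service itself, a kit dispatched costs a fraction s of the
online unit cost c up front and the remainder only on return; with return
rate R the cost per *completed* test is ``c [s / R + (1 - s)]``.

The cross-area comparison prices each area's diagnoses at a common clinic
reference cost and online price divided by the locally observed positivity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields, replace
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import ConfigError, DEFAULT_TARIFFS, TariffSchedule, round_gbp

__all__ = [
    "ScenarioParams",
    "AreaProfile",
    "blended_cost_per_test",
    "blended_cost_per_diagnosis",
    "break_even_positivity_ratio",
    "cost_per_completed_test",
    "area_cost_per_diagnosis",
    "area_table",
    "load_area_profiles",
    "packaged_area_profiles",
    "sweep",
    "SCENARIO_MODELS",
]


@dataclass(frozen=True)
class ScenarioParams:
    """Symbols of the closed-form models.

    ``online_cost`` may be set directly (e.g. a £33 kit price); otherwise it
    is derived as ``cost_ratio * clinic_cost``. When set, it also defines the
    effective cost ratio used by the blended models, keeping the two
    parameterisations consistent.
    """

    clinic_cost: float = 66.0  # C, per clinic test
    cost_ratio: float = 0.45  # r = online / clinic unit cost
    online_fraction: float = 0.37  # f, share of tests done online
    clinic_positivity: float = 0.10  # p
    positivity_ratio: float = 0.70  # rho = online / clinic positivity
    dispatch_fraction: float = 0.15  # s, share of online cost incurred on dispatch
    return_rate: float = 0.75  # R, kits returned / kits dispatched
    online_cost: float | None = None  # c; defaults to r * C

    def __post_init__(self) -> None:
        if self.clinic_cost <= 0:
            raise ConfigError("clinic_cost must be > 0")
        if self.cost_ratio <= 0 or self.positivity_ratio <= 0:
            raise ConfigError("cost_ratio and positivity_ratio must be > 0")
        for name in ("online_fraction", "clinic_positivity", "dispatch_fraction", "return_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.online_cost is not None and self.online_cost <= 0:
            raise ConfigError("online_cost must be > 0 when set")

    @property
    def effective_cost_ratio(self) -> float:
        if self.online_cost is not None:
            return self.online_cost / self.clinic_cost
        return self.cost_ratio

    @property
    def effective_online_cost(self) -> float:
        if self.online_cost is not None:
            return self.online_cost
        return self.cost_ratio * self.clinic_cost


def blended_cost_per_test(params: ScenarioParams) -> float:
    """Average cost per test over clinic and online combined: C[(1-f) + f r]."""
    f, r = params.online_fraction, params.effective_cost_ratio
    return params.clinic_cost * ((1.0 - f) + f * r)


def blended_cost_per_diagnosis(params: ScenarioParams) -> float:
    """Average cost per diagnosis: C[(1-f) + f r] / (p[(1-f) + f rho]).

    The numerator is total spend per test, the denominator the diagnosis
    yield per test; positivity weights each setting's share.
    """
    f, rho, p = params.online_fraction, params.positivity_ratio, params.clinic_positivity
    if p <= 0:
        raise ConfigError("clinic_positivity must be > 0")
    yield_factor = (1.0 - f) + f * rho
    if yield_factor <= 0:
        raise ZeroDivisionError("diagnosis yield denominator is zero")
    return blended_cost_per_test(params) / (p * yield_factor)


def break_even_positivity_ratio(params: ScenarioParams) -> float:
    """Positivity ratio at which shifting tests online leaves cost per
    diagnosis unchanged: rho* = r.

    Above it cost per diagnosis falls as the online share grows; below it,
    it rises. At rho = r the blended cost per diagnosis equals C/p for every
    online fraction.
    """
    return params.effective_cost_ratio


def cost_per_completed_test(params: ScenarioParams) -> float:
    """Online cost per completed test: c [s/R + (1 - s)].

    1/R kits are dispatched per completed test; the dispatch share s of the
    unit cost is spent on every kit, the rest only on returned ones.
    """
    s, rate = params.dispatch_fraction, params.return_rate
    if rate <= 0:
        raise ZeroDivisionError("return_rate must be > 0")
    return params.effective_online_cost * (s / rate + (1.0 - s))


@dataclass(frozen=True)
class AreaProfile:
    """Observed chlamydia positivities for one commissioning area."""

    name: str
    urban_rural_class: str
    clinic_positivity: float
    online_positivity: float

    def __post_init__(self) -> None:
        for name in ("clinic_positivity", "online_positivity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name}={v} must lie in (0, 1]")


def area_cost_per_diagnosis(
    area: AreaProfile, tariffs: TariffSchedule | None = None
) -> tuple[Decimal, Decimal]:
    """(clinic, online) cost per diagnosis for one area, whole pounds.

    Clinic reference cost divided by clinic positivity, online price divided
    by online positivity; each rounded to the nearest pound for reporting.
    """
    t = tariffs or DEFAULT_TARIFFS
    clinic = round_gbp(t.clinic_reference_cost / Decimal(str(area.clinic_positivity)))
    online = round_gbp(t.online_price / Decimal(str(area.online_positivity)))
    return clinic, online


def area_table(
    areas: Iterable[AreaProfile], tariffs: TariffSchedule | None = None
) -> pd.DataFrame:
    """Cross-area comparison: one row per area with both cost-per-diagnosis columns."""
    rows = []
    for a in areas:
        clinic, online = area_cost_per_diagnosis(a, tariffs)
        rows.append(
            {
                "area_name": a.name,
                "urban_rural_class": a.urban_rural_class,
                "clinic_positivity": a.clinic_positivity,
                "online_positivity": a.online_positivity,
                "cost_per_diagnosis_clinic": int(clinic),
                "cost_per_diagnosis_online": int(online),
            }
        )
    return pd.DataFrame(rows)


def load_area_profiles(path: str | Path) -> list[AreaProfile]:
    """Read an area-profile CSV (area_name, urban_rural_class, clinic_positivity, online_positivity)."""
    out: list[AreaProfile] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                AreaProfile(
                    name=row["area_name"],
                    urban_rural_class=row["urban_rural_class"],
                    clinic_positivity=float(row["clinic_positivity"]),
                    online_positivity=float(row["online_positivity"]),
                )
            )
    return out


def packaged_area_profiles() -> list[AreaProfile]:
    """The four published area profiles shipped with the package."""
    ref = resources.files("stiecon.data").joinpath("area_profiles.csv")
    with resources.as_file(ref) as path:
        return load_area_profiles(path)


SCENARIO_MODELS = {
    "cost-per-test": blended_cost_per_test,
    "cost-per-diagnosis": blended_cost_per_diagnosis,
    "return-rate": cost_per_completed_test,
    # function-name aliases
    "blended_cost_per_test": blended_cost_per_test,
    "blended_cost_per_diagnosis": blended_cost_per_diagnosis,
    "cost_per_completed_test": cost_per_completed_test,
}

_PARAM_NAMES = {f.name for f in fields(ScenarioParams)}


def sweep(
    model: str,
    vary: str,
    grid: Sequence[float],
    base: ScenarioParams | None = None,
) -> pd.DataFrame:
    """Evaluate one scenario model along a parameter grid.

    Returns a two-column frame — the varied parameter and the model output —
    one row per grid point in grid order, all other parameters held at
    ``base``.
    """
    if model not in SCENARIO_MODELS:
        raise ConfigError(f"unknown scenario model {model!r}")
    if vary not in _PARAM_NAMES:
        raise ConfigError(f"unknown scenario parameter {vary!r}")
    fn = SCENARIO_MODELS[model]
    base = base or ScenarioParams()
    rows = [{vary: g, model: fn(replace(base, **{vary: g}))} for g in grid]
    return pd.DataFrame(rows, columns=[vary, model])
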