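"""Tariff assignment and period-level cost summaries.

Clinic visits are priced from the London integrated sexual-health tariff:
the primary tariff when simple STI testing is the main activity, the
additional tariff when testing rides along a costlier activity, and a flat
triple-site tariff for MSM testing (same price whether primary or
additional). Online tests are priced at a single indicative kit price.

All money is exact Decimal GBP; rounding to whole pounds happens only when a
figure is presented.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from .metrics import Complexity, SiteScope, VisitClassification, classify_visit
from .model import (
    AttendanceRecord,
    CodeSets,
    DEFAULT_CODE_SETS,
    DEFAULT_TARIFFS,
    Setting,
    StudyPeriod,
    TariffSchedule,
)

__all__ = [
    "CATEGORY_KEYS",
    "CostOutcomes",
    "PeriodCostSummary",
    "assign_tariff",
    "cost_outcomes",
    "period_cost_summary",
    "simple_test_share",
]

# clinic visit categories, keyed by (site scope, complexity)
CATEGORY_KEYS = ("genital_complex", "triple_complex", "genital_simple", "triple_simple")


def assign_tariff(
    classification: VisitClassification, tariffs: TariffSchedule | None = None
) -> Decimal:
    """Unit price (GBP) for one classified test-or-diagnosis visit."""
    t = tariffs or DEFAULT_TARIFFS
    if classification.setting is Setting.ONLINE:
        return t.online_price
    if classification.site_scope is SiteScope.TRIPLE_SITE:
        return t.msm_triple  # flat: primary and additional tariffs are equal
    if classification.complexity is Complexity.SIMPLE:
        return t.primary_simple
    return t.additional_complex


@dataclass(frozen=True)
class CostOutcomes:
    """The derived outcome block of a period cost comparison.

    ``annualised_cost`` rescales the period total to 12 months; monthly
    figures divide by the period length. Unrounded intermediates are kept
    so per-test and per-diagnosis costs are exact; rounding is presentational.
    """

    annualised_cost: Decimal
    monthly_cost: Decimal
    monthly_tests: Decimal
    monthly_diagnoses: Decimal
    cost_per_test: Decimal
    cost_per_diagnosis: Decimal | None


def cost_outcomes(
    combined_cost: Decimal | int,
    n_visits: int,
    n_diagnoses: int,
    n_months: int,
) -> CostOutcomes:
    """Annualised / monthly averages and unit costs from period totals.

    ``n_visits`` counts clinic test-or-diagnosis visits plus completed
    online tests. ``cost_per_diagnosis`` is ``None`` (undefined, not
    infinite) when the period saw no diagnoses.
    """
    total = Decimal(str(combined_cost))
    months = Decimal(n_months)
    annualised = total * 12 / months
    monthly_cost = annualised / 12
    monthly_tests = Decimal(n_visits) / months
    monthly_diagnoses = Decimal(n_diagnoses) / months
    cost_per_test = monthly_cost / monthly_tests if n_visits else None
    cost_per_diagnosis = monthly_cost / monthly_diagnoses if n_diagnoses else None
    if cost_per_test is None:
        raise ValueError("period has no test-or-diagnosis visits")
    return CostOutcomes(
        annualised_cost=annualised,
        monthly_cost=monthly_cost,
        monthly_tests=monthly_tests,
        monthly_diagnoses=monthly_diagnoses,
        cost_per_test=cost_per_test,
        cost_per_diagnosis=cost_per_diagnosis,
    )


@dataclass(frozen=True)
class PeriodCostSummary:
    period: StudyPeriod
    n_clinic_visits: int
    n_online_tests: int
    n_diagnoses: int
    category_counts: dict[str, int]
    category_costs: dict[str, Decimal]
    clinic_total_cost: Decimal
    online_total_cost: Decimal
    combined_cost: Decimal
    outcomes: CostOutcomes

    @property
    def annualised_cost(self) -> Decimal:
        return self.outcomes.annualised_cost

    @property
    def monthly_cost(self) -> Decimal:
        return self.outcomes.monthly_cost

    @property
    def cost_per_test(self) -> Decimal:
        return self.outcomes.cost_per_test

    @property
    def cost_per_diagnosis(self) -> Decimal | None:
        return self.outcomes.cost_per_diagnosis


def _category_key(c: VisitClassification) -> str:
    site = "triple" if c.site_scope is SiteScope.TRIPLE_SITE else "genital"
    cx = "complex" if c.complexity is Complexity.COMPLEX else "simple"
    return f"{site}_{cx}"


def period_cost_summary(
    records: list[AttendanceRecord],
    code_sets: CodeSets | None = None,
    tariffs: TariffSchedule | None = None,
    period: StudyPeriod | None = None,
) -> PeriodCostSummary:
    """Cost and outcome aggregates for one study period.

    Considers harmonised records dated within the period that bear a test or
    diagnosis code (order-only online events never cost or count here).
    Clinic diagnosis-only visits are tariffed by their complexity class like
    any other clinic visit, keeping the visit denominator consistent.
    """
    cs = code_sets or DEFAULT_CODE_SETS
    t = tariffs or DEFAULT_TARIFFS
    if period is None:
        raise ValueError("period is required")

    counts = {k: 0 for k in CATEGORY_KEYS}
    n_online = 0
    n_diag = 0
    online_cost = Decimal("0")
    for r in records:
        if r.ordered_only or not period.contains(r.visit_date):
            continue
        c = classify_visit(r, cs)
        if not (c.has_test or c.has_diagnosis):
            continue
        if c.has_diagnosis:
            n_diag += 1
        if r.setting is Setting.ONLINE:
            n_online += 1
            online_cost += t.online_price
        else:
            counts[_category_key(c)] += 1

    category_costs = {
        "genital_simple": counts["genital_simple"] * t.primary_simple,
        "genital_complex": counts["genital_complex"] * t.additional_complex,
        "triple_simple": counts["triple_simple"] * t.msm_triple,
        "triple_complex": counts["triple_complex"] * t.msm_triple,
    }
    clinic_cost = sum(category_costs.values(), Decimal("0"))
    combined = clinic_cost + online_cost
    n_clinic = sum(counts.values())
    outcomes = cost_outcomes(combined, n_clinic + n_online, n_diag, period.n_months)
    return PeriodCostSummary(
        period=period,
        n_clinic_visits=n_clinic,
        n_online_tests=n_online,
        n_diagnoses=n_diag,
        category_counts=counts,
        category_costs=category_costs,
        clinic_total_cost=clinic_cost,
        online_total_cost=online_cost,
        combined_cost=combined,
        outcomes=outcomes,
    )


def simple_test_share(
    records: list[AttendanceRecord],
    code_sets: CodeSets | None = None,
    period: StudyPeriod | None = None,
) -> float | None:
    """Fraction of test-bearing clinic visits where testing was the sole activity.

    ``None`` when the period has no test-bearing clinic visits.
    """
    cs = code_sets or DEFAULT_CODE_SETS
    n = 0
    n_simple = 0
    for r in records:
        if r.setting is Setting.ONLINE or r.ordered_only:
            continue
        if period is not None and not period.contains(r.visit_date):
            continue
        c = classify_visit(r, cs)
        if not c.has_test:
            continue
        n += 1
        if c.complexity is Complexity.SIMPLE:
            n_simple += 1
    return n_simple / n if n else None
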