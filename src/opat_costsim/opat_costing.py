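"""Outpatient (OPAT) phase costing from both perspectives.

Payer: ambulatory clinic contacts are reimbursed by a quarterly flat fee
(92 EUR per started calendar quarter in 2015) regardless of the number of
visits; prescribed antibiotics are paid per treatment day at the pharmacy
daily rate. Laboratory and radiology during OPAT are carried as cost-neutral
line items.

Provider: each clinic visit costs the outpatient department 75 EUR
(personnel 46, materials 3, overhead 26), against which only the quarterly
flat fee is earned — typically a deficit.

Visit schedules depend on the drug: vancomycin needs monitoring three times
a week, other agents once a week. The schedule formulas are configurable;
a stored per-case visit count always takes precedence for regimen class
``other``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal

from .money import money
from .cohort_model import CaseRecord

__all__ = [
    "OPATPlan",
    "ClinicCostSchedule",
    "DEFAULT_SCHEDULE",
    "plan_from_case",
    "payer_clinic_fee",
    "payer_drug_cost",
    "planned_visit_count",
    "provider_clinic_margin",
    "payer_opat_total",
    "OPATSummary",
    "summarize_opat",
]


@dataclass(frozen=True)
class ClinicCostSchedule:
    """Clinic fee and per-visit cost components (2015 euro values)."""

    quarterly_flat_fee: Decimal = Decimal("92")
    personnel_per_visit: Decimal = Decimal("46")
    materials_per_visit: Decimal = Decimal("3")
    overhead_per_visit: Decimal = Decimal("26")

    def __post_init__(self) -> None:
        for name in ("quarterly_flat_fee", "personnel_per_visit",
                     "materials_per_visit", "overhead_per_visit"):
            object.__setattr__(self, name, Decimal(str(getattr(self, name))))

    @property
    def per_visit_total(self) -> Decimal:
        return (
            self.personnel_per_visit + self.materials_per_visit + self.overhead_per_visit
        )


DEFAULT_SCHEDULE = ClinicCostSchedule()


@dataclass(frozen=True)
class OPATPlan:
    """Per-case outpatient plan: duration equals the saved bed days."""

    case_id: str
    duration_days: int
    quarter_count: int
    drug_daily_cost: Decimal
    visit_count: int
    regimen_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_daily_cost", money(self.drug_daily_cost))
        if self.duration_days < 1:
            raise ValueError(f"plan {self.case_id}: duration_days must be >= 1")
        if self.quarter_count not in (1, 2):
            raise ValueError(f"plan {self.case_id}: quarter_count must be 1 or 2")
        if self.visit_count < 1:
            raise ValueError(f"plan {self.case_id}: visit_count must be >= 1")


def plan_from_case(case: CaseRecord) -> OPATPlan:
    """Derive the outpatient plan carried on a cohort record."""
    return OPATPlan(
        case_id=case.case_id,
        duration_days=case.dischargeable_days,
        quarter_count=case.quarter_count,
        drug_daily_cost=case.drug_daily_cost,
        visit_count=case.visit_count,
        regimen_class=case.regimen_class,
    )


def payer_clinic_fee(plan: OPATPlan, sched: ClinicCostSchedule = DEFAULT_SCHEDULE) -> Decimal:
    """Quarterly flat fees billed to the payer for the clinic contacts."""
    return money(plan.quarter_count * sched.quarterly_flat_fee)


def payer_drug_cost(plan: OPATPlan) -> Decimal:
    """Antibiotic cost to the payer: treatment days x pharmacy daily rate."""
    return money(plan.duration_days * plan.drug_daily_cost)


def planned_visit_count(plan: OPATPlan) -> int:
    """Clinic visits implied by the monitoring schedule of the regimen.

    Thrice-weekly (vancomycin-type) monitoring yields three visits per full
    treatment week; weekly monitoring one visit per started week. For
    regimen class ``other`` no formula applies and the stored count is
    returned.
    """
    if plan.regimen_class == "thrice_weekly":
        return (plan.duration_days // 7) * 3
    if plan.regimen_class == "weekly":
        return math.ceil(plan.duration_days / 7)
    return plan.visit_count


def provider_clinic_margin(
    plan: OPATPlan, sched: ClinicCostSchedule = DEFAULT_SCHEDULE
) -> Decimal:
    """Clinic flat-fee revenue minus per-visit costs (usually negative)."""
    return money(payer_clinic_fee(plan, sched) - plan.visit_count * sched.per_visit_total)


def payer_opat_total(plans: list[OPATPlan]) -> Decimal:
    """Total payer cost of the outpatient phase: sum of per-case drug bills.

    Clinic flat fees are accounted separately (see :func:`summarize_opat`);
    the drug-only figure is recovered by subtracting them.
    """
    if not plans:
        raise ValueError("no outpatient plans")
    return sum((payer_drug_cost(p) for p in plans), Decimal(0))


@dataclass
class OPATSummary:
    """Cohort-level outpatient ledger for both perspectives."""

    opat_total: Decimal          # payer: sum of per-case totals
    clinic_fees: Decimal         # payer = provider revenue: quarterly flat fees
    drug_cost_ex_fees: Decimal   # opat_total net of clinic fees
    clinic_visit_cost: Decimal   # provider: visits x per-visit total
    clinic_margin: Decimal       # provider: fees - visit cost


def summarize_opat(
    plans: list[OPATPlan], sched: ClinicCostSchedule = DEFAULT_SCHEDULE
) -> OPATSummary:
    total = payer_opat_total(plans)
    fees = sum((payer_clinic_fee(p, sched) for p in plans), Decimal(0))
    visit_cost = sum(
        (money(p.visit_count * sched.per_visit_total) for p in plans), Decimal(0)
    )
    return OPATSummary(
        opat_total=total,
        clinic_fees=fees,
        drug_cost_ex_fees=total - fees,
        clinic_visit_cost=visit_cost,
        clinic_margin=fees - visit_cost,
    )
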