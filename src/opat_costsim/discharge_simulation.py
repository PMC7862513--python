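"""Counterfactual early-discharge simulation.

The earliest safe discharge day is the latest of three clinical criteria:
the fifth day after the last operation, the day after the last medical
intervention (radiology and laboratory excluded), and the day the wound is
documented dry. Days between that day and the actual discharge are the bed
days an outpatient regimen would save.

The financial consequences are asymmetric between the two perspectives:

* payer (statutory insurer): revenue falls only by forfeited long-stay
  surcharge days, i.e. only for stays above the upper trimming point (OGVD),
  at the case's surcharge per-diem;
* provider (hospital): cost falls by every saved bed day at the case's
  general ward per-diem, because operations, intensive care and other lump
  costs all precede the eligibility day.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from .money import money
from .cohort_model import CaseRecord
from .tariff_model import DRGTariff

__all__ = [
    "ClinicalTimeline",
    "SimulationResult",
    "CohortSimulation",
    "earliest_discharge_day",
    "saved_days",
    "payer_revenue_reduction",
    "provider_cost_reduction",
    "simulate_case",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ClinicalTimeline:
    """Event days of one admission; admission is day 0, discharge day = los.

    ``wound_dry_day`` defaults to the admission day: a wound is taken as dry
    unless documented otherwise, so the other two criteria are usually
    binding.
    """

    los: int
    last_operation_day: int = 0
    last_intervention_day: int = 0
    wound_dry_day: int = 0

    def __post_init__(self) -> None:
        if self.los < 1:
            raise ValueError(f"los must be >= 1, got {self.los}")
        for name in ("last_operation_day", "last_intervention_day", "wound_dry_day"):
            v = getattr(self, name)
            if not (0 <= v <= self.los):
                raise ValueError(f"{name}={v} outside [0, los={self.los}]")


def earliest_discharge_day(t: ClinicalTimeline) -> int:
    """Latest of the three eligibility criteria, capped at actual discharge."""
    day = max(
        t.last_operation_day + 5,
        t.last_intervention_day + 1,
        t.wound_dry_day,
    )
    return min(day, t.los)


def saved_days(los: int, discharge_day: int) -> int:
    """Bed days saved by discharging on ``discharge_day`` instead of ``los``."""
    if discharge_day > los:
        raise ValueError(f"discharge_day ({discharge_day}) exceeds los ({los})")
    return los - discharge_day


def payer_revenue_reduction(case: CaseRecord, tariff: DRGTariff) -> Decimal:
    """Forfeited long-stay surcharges when the case is discharged early.

    Only days above the OGVD carry revenue, so the reduction is the smaller
    of the saved days and the days beyond the OGVD, at the case's surcharge
    per-diem. Zero for stays at or below the OGVD.
    """
    if case.drg_code != tariff.drg_code:
        raise ValueError(
            f"case {case.case_id}: tariff {tariff.drg_code} does not match "
            f"drg_code {case.drg_code}"
        )
    days_above_ogvd = max(0, case.los - tariff.ogvd)
    forfeited = min(case.dischargeable_days, days_above_ogvd)
    return money(forfeited * case.surcharge_per_diem)


def provider_cost_reduction(case: CaseRecord) -> Decimal:
    """Hospital cost saved: every saved bed day at the ward per-diem."""
    return money(case.dischargeable_days * case.ward_per_diem)


@dataclass
class SimulationResult:
    """Counterfactual financials for one case (hospital perspective)."""

    case_id: str
    saved_days: int
    revenue_reduction: Decimal
    cost_reduction: Decimal
    actual_revenue: Decimal
    actual_cost: Decimal
    new_revenue: Decimal
    new_cost: Decimal

    @property
    def actual_margin(self) -> Decimal:
        return self.actual_revenue - self.actual_cost

    @property
    def new_margin(self) -> Decimal:
        return self.new_revenue - self.new_cost


@dataclass
class CohortSimulation:
    """Per-case results plus cent-exact cohort totals."""

    per_case: list[SimulationResult]

    def _total(self, attr: str) -> Decimal:
        return sum((getattr(r, attr) for r in self.per_case), Decimal(0))

    @property
    def total_saved_days(self) -> int:
        return sum(r.saved_days for r in self.per_case)

    @property
    def total_revenue_reduction(self) -> Decimal:
        return self._total("revenue_reduction")

    @property
    def total_cost_reduction(self) -> Decimal:
        return self._total("cost_reduction")

    @property
    def total_actual_revenue(self) -> Decimal:
        return self._total("actual_revenue")

    @property
    def total_actual_cost(self) -> Decimal:
        return self._total("actual_cost")

    @property
    def total_new_revenue(self) -> Decimal:
        return self._total("new_revenue")

    @property
    def total_new_cost(self) -> Decimal:
        return self._total("new_cost")

    @property
    def total_actual_margin(self) -> Decimal:
        return self.total_actual_revenue - self.total_actual_cost

    @property
    def total_new_margin(self) -> Decimal:
        return self.total_new_revenue - self.total_new_cost


def simulate_case(case: CaseRecord, tariff: DRGTariff) -> SimulationResult:
    rev_red = payer_revenue_reduction(case, tariff)
    cost_red = provider_cost_reduction(case)
    return SimulationResult(
        case_id=case.case_id,
        saved_days=case.dischargeable_days,
        revenue_reduction=rev_red,
        cost_reduction=cost_red,
        actual_revenue=case.actual_revenue,
        actual_cost=case.actual_cost,
        new_revenue=case.actual_revenue - rev_red,
        new_cost=case.actual_cost - cost_red,
    )


def simulate_cohort(
    cases: list[CaseRecord], tariffs: dict[str, DRGTariff]
) -> CohortSimulation:
    """Run the early-discharge counterfactual over a cohort."""
    results = []
    for case in cases:
        if case.drg_code not in tariffs:
            raise KeyError(
                f"case {case.case_id}: no tariff for DRG {case.drg_code!r}"
            )
        results.append(simulate_case(case, tariffs[case.drg_code]))
    return CohortSimulation(per_case=results)
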