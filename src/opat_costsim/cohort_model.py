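"""Case-level cohort model, screening filter and bundled fixtures.

The analysed cohort is 12 periprosthetic joint infection (PJI) episodes
treated with inpatient parenteral antibiotics in 2015. Each record carries
the actual DRG revenue and provider cost, the per-diem rates driving the
early-discharge simulation, and the inputs of the outpatient costing
(treatment duration, drug daily rate, clinic quarters and visits).

A separate screening pool reproduces the inclusion funnel: 133 candidate
episodes of which 121 are excluded by the screening criteria and 12 remain.
The bundled pool is synthetic — individual excluded patients' attributes are
invented placeholders; only the per-reason tallies are meaningful.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict, fields as dc_fields
from decimal import Decimal, InvalidOperation
from importlib import resources
from pathlib import Path

from .money import money, parse_money, fmt_eur

__all__ = [
    "CaseRecord",
    "ScreeningRecord",
    "DifferenceLedger",
    "EXCLUSION_ORDER",
    "SCREENING_FLAGS",
    "REGIMEN_CLASSES",
    "CohortValidationError",
    "apply_inclusion_filter",
    "load_cohort",
    "write_cohort",
    "load_screening_pool",
    "default_cohort",
    "default_screening_pool",
    "difference_ledger",
]

REGIMEN_CLASSES = ("thrice_weekly", "weekly", "other")

#: Flags a screening record may carry (beyond the age / length-of-stay fields).
SCREENING_FLAGS = (
    "complex_case",
    "non_hip_knee_implant",
    "no_antibiotics",
    "no_infection",
    "oral_antibiotics",
    "transferred",
)

#: Exclusion reasons in precedence order; a record is tallied under the first
#: reason that applies, so the tally partitions the excluded set.
EXCLUSION_ORDER = (
    "age_under_18",
    "los_under_7",
    "complex_case",
    "non_hip_knee_implant",
    "no_antibiotics",
    "no_infection",
    "oral_antibiotics",
    "transferred",
)


class CohortValidationError(ValueError):
    """Raised when a cohort or screening file violates the record schema."""


@dataclass
class CaseRecord:
    """One inpatient PJI episode with actual financials and simulation inputs.

    ``dischargeable_days`` is the number of bed days after the simulated
    earliest safe discharge — the stay that an outpatient regimen would
    replace. ``surcharge_per_diem`` is the case's long-stay supplement per
    day above the upper trimming point; ``ward_per_diem`` the provider's
    general ward day rate.
    """

    case_id: str
    age: int
    drg_code: str
    reason: str
    los: int
    actual_revenue: Decimal
    actual_cost: Decimal
    surcharge_per_diem: Decimal
    ward_per_diem: Decimal
    dischargeable_days: int
    quarter_count: int
    drug_daily_cost: Decimal
    visit_count: int
    regimen_class: str

    def __post_init__(self) -> None:
        for name in ("actual_revenue", "actual_cost", "surcharge_per_diem",
                     "ward_per_diem", "drug_daily_cost"):
            setattr(self, name, money(getattr(self, name)))
        self.validate()

    def validate(self, tariffs: dict | None = None) -> None:
        cid = self.case_id
        if self.age < 18:
            raise CohortValidationError(f"case {cid}: field age must be >= 18, got {self.age}")
        if self.los < 7:
            raise CohortValidationError(f"case {cid}: field los must be >= 7 for an included case, got {self.los}")
        if not (0 <= self.dischargeable_days <= self.los):
            raise CohortValidationError(
                f"case {cid}: field dischargeable_days must lie in [0, los={self.los}], "
                f"got {self.dischargeable_days}"
            )
        for name in ("actual_revenue", "actual_cost", "surcharge_per_diem",
                     "ward_per_diem", "drug_daily_cost"):
            if getattr(self, name) <= 0:
                raise CohortValidationError(f"case {cid}: field {name} must be > 0")
        if self.quarter_count < 1:
            raise CohortValidationError(f"case {cid}: field quarter_count must be >= 1")
        if self.visit_count < 1:
            raise CohortValidationError(f"case {cid}: field visit_count must be >= 1")
        if self.regimen_class not in REGIMEN_CLASSES:
            raise CohortValidationError(
                f"case {cid}: field regimen_class must be one of {REGIMEN_CLASSES}, "
                f"got {self.regimen_class!r}"
            )
        if tariffs is not None and self.drg_code not in tariffs:
            raise CohortValidationError(
                f"case {cid}: field drg_code {self.drg_code!r} not in tariff catalogue"
            )


@dataclass(frozen=True)
class ScreeningRecord:
    """A candidate episode entering the inclusion screen."""

    case_id: str
    age: int
    los: int
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))
        unknown = self.flags - set(SCREENING_FLAGS)
        if unknown:
            raise CohortValidationError(
                f"record {self.case_id}: unknown screening flags {sorted(unknown)}"
            )


def _exclusion_reason(rec: ScreeningRecord) -> str | None:
    """First-matching exclusion reason, or None if the record is included."""
    if rec.age < 18:
        return "age_under_18"
    if rec.los < 7:
        return "los_under_7"
    for flag in EXCLUSION_ORDER[2:]:
        if flag in rec.flags:
            return flag
    return None


def apply_inclusion_filter(
    records: list[ScreeningRecord],
) -> tuple[list[ScreeningRecord], dict[str, int]]:
    """Split a screening pool into included survivors and an exclusion tally.

    Criteria are applied in the fixed precedence order :data:`EXCLUSION_ORDER`;
    each excluded record is counted under exactly one (first-matching) reason,
    so the tally values sum to the number excluded.
    """
    if not records:
        raise ValueError("screening pool is empty")
    included: list[ScreeningRecord] = []
    tally: dict[str, int] = {reason: 0 for reason in EXCLUSION_ORDER}
    for rec in records:
        reason = _exclusion_reason(rec)
        if reason is None:
            included.append(rec)
        else:
            tally[reason] += 1
    return included, tally


_INT_FIELDS = {"age", "los", "dischargeable_days", "quarter_count", "visit_count"}
_MONEY_FIELDS = {"actual_revenue", "actual_cost", "surcharge_per_diem",
                 "ward_per_diem", "drug_daily_cost"}
_COHORT_COLUMNS = [f.name for f in dc_fields(CaseRecord)]


def load_cohort(path: str | Path) -> list[CaseRecord]:
    """Read a cohort CSV into validated :class:`CaseRecord` objects.

    German decimal commas are accepted in money columns. A schema violation
    raises :class:`CohortValidationError` naming the offending field and row.
    """
    records: list[CaseRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_COHORT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CohortValidationError(f"cohort file missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            kwargs = {}
            for name in _COHORT_COLUMNS:
                raw = row[name]
                try:
                    if name in _INT_FIELDS:
                        kwargs[name] = int(raw)
                    elif name in _MONEY_FIELDS:
                        kwargs[name] = parse_money(raw)
                    else:
                        kwargs[name] = raw.strip()
                except (ValueError, InvalidOperation) as exc:
                    raise CohortValidationError(
                        f"row {i}: field {name}: cannot parse {raw!r}"
                    ) from exc
            try:
                records.append(CaseRecord(**kwargs))
            except CohortValidationError as exc:
                raise CohortValidationError(f"row {i}: {exc}") from exc
    return records


def write_cohort(records: list[CaseRecord], path: str | Path) -> None:
    """Write records to CSV (dot decimals, two places on money columns)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COHORT_COLUMNS)
        for rec in records:
            d = asdict(rec)
            writer.writerow(
                [fmt_eur(d[c]) if c in _MONEY_FIELDS else d[c] for c in _COHORT_COLUMNS]
            )


def load_screening_pool(path: str | Path) -> list[ScreeningRecord]:
    """Read a screening-pool CSV (columns record_id, age, los, flags)."""
    records: list[ScreeningRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            flags = frozenset(f for f in row["flags"].split(";") if f)
            try:
                records.append(
                    ScreeningRecord(
                        case_id=row["record_id"].strip(),
                        age=int(row["age"]),
                        los=int(row["los"]),
                        flags=flags,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise CohortValidationError(f"screening row {i}: {exc}") from exc
    return records


def default_cohort() -> list[CaseRecord]:
    """The bundled 12-case 2015 PJI cohort."""
    with resources.as_file(
        resources.files("opat_costsim").joinpath("data/cohort_pji_2015.csv")
    ) as p:
        return load_cohort(p)


def default_screening_pool() -> list[ScreeningRecord]:
    """The bundled synthetic 133-record screening pool.

    Individual attributes of the excluded records are invented placeholders;
    only the exclusion-reason tallies carry information.
    """
    with resources.as_file(
        resources.files("opat_costsim").joinpath("data/screening_pool_synthetic.csv")
    ) as p:
        return load_screening_pool(p)


@dataclass
class DifferenceLedger:
    """Per-case and total revenue / cost / margin (margin = revenue - cost)."""

    per_case: list[dict]
    total_revenue: Decimal
    total_cost: Decimal
    total_margin: Decimal


def difference_ledger(records: list[CaseRecord]) -> DifferenceLedger:
    """Build the actuals ledger; the margin identity holds to the cent."""
    per_case = []
    for rec in records:
        margin = rec.actual_revenue - rec.actual_cost
        per_case.append(
            {
                "case_id": rec.case_id,
                "revenue": rec.actual_revenue,
                "cost": rec.actual_cost,
                "margin": margin,
            }
        )
    total_revenue = sum((r["revenue"] for r in per_case), Decimal(0))
    total_cost = sum((r["cost"] for r in per_case), Decimal(0))
    return DifferenceLedger(
        per_case=per_case,
        total_revenue=total_revenue,
        total_cost=total_cost,
        total_margin=total_revenue - total_cost,
    )
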