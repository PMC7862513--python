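"""Synthetic screening pools, cohorts and clinical timelines.

The generator emulates the statistical shape of the study data so that every
pipeline stage can be exercised at arbitrary scale: DRG-coded episodes with
lengths of stay straddling the upper trimming point, clinical timelines that
determine discharge eligibility, ward and drug daily rates in the observed
ranges, and a screening pool with configurable exclusion-reason proportions.

Distributions are uniform over the configured ranges (the study reports only
ranges and means); all draws come from one seeded generator, no global state.
Crucially, case-specific lump costs (operations, intensive care) are placed
before the eligibility day, so simulated savings depend only on the ward
per-diem — the central accounting assumption of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np

from .money import money
from .tariff_model import (
    BaseRate,
    DEFAULT_BASE_RATE,
    DRGTariff,
    case_revenue,
    default_tariffs,
    per_diem_surcharge,
)
from .cohort_model import CaseRecord, ScreeningRecord, EXCLUSION_ORDER
from .discharge_simulation import ClinicalTimeline, earliest_discharge_day
from .opat_costing import planned_visit_count, plan_from_case

__all__ = ["GeneratorConfig", "generate_screening_pool", "generate_case", "generate_cohort"]

#: Screening exclusion proportions mirroring the observed funnel
#: (counts out of 133 candidates).
_DEFAULT_EXCLUSION_MIX = {
    "age_under_18": 1 / 133,
    "los_under_7": 33 / 133,
    "complex_case": 29 / 133,
    "non_hip_knee_implant": 26 / 133,
    "no_antibiotics": 15 / 133,
    "no_infection": 5 / 133,
    "oral_antibiotics": 4 / 133,
    "transferred": 8 / 133,
}

# day-of-year on which calendar quarters start (non-leap year)
_QUARTER_STARTS = (0, 90, 181, 273)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic generator; defaults mirror the study cohort."""

    n_cases: int = 12
    seed: int = 0
    los_range: tuple[int, int] = (19, 84)
    age_range: tuple[int, int] = (63, 84)
    drg_pool: list[DRGTariff] = field(default_factory=lambda: list(default_tariffs().values()))
    drug_rate_range: tuple[float, float] = (265.0, 570.0)
    ward_per_diem_range: tuple[float, float] = (230.0, 306.0)
    lump_cost_range: tuple[float, float] = (3000.0, 30000.0)
    exclusion_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EXCLUSION_MIX)
    )
    ogvd_straddle_fraction: float = 0.5
    thrice_weekly_fraction: float = 0.25
    base_rate: BaseRate = DEFAULT_BASE_RATE

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not self.drg_pool:
            raise ValueError("drg_pool must be non-empty")
        for name in ("ogvd_straddle_fraction", "thrice_weekly_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        bad = set(self.exclusion_mix) - set(EXCLUSION_ORDER)
        if bad:
            raise ValueError(f"unknown exclusion reasons: {sorted(bad)}")
        if any(p < 0 for p in self.exclusion_mix.values()) or sum(self.exclusion_mix.values()) > 1:
            raise ValueError("exclusion_mix probabilities must be >= 0 and sum to <= 1")
        for name in ("los_range", "age_range", "drug_rate_range",
                     "ward_per_diem_range", "lump_cost_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name}: upper bound below lower bound")


def _uniform_money(rng: np.random.Generator, lo: float, hi: float) -> Decimal:
    return money(f"{rng.uniform(lo, hi):.2f}")


def generate_screening_pool(cfg: GeneratorConfig, n: int | None = None) -> list[ScreeningRecord]:
    """Draw a screening pool with the configured exclusion-reason mix.

    Each record's attributes are made consistent with its drawn category
    (minors, short stays, or one triggering flag); included records carry no
    flags. Deterministic under a fixed seed.
    """
    n = cfg.n_cases if n is None else n
    rng = np.random.default_rng(cfg.seed)
    reasons = list(cfg.exclusion_mix)
    probs = [cfg.exclusion_mix[r] for r in reasons]
    categories = reasons + ["included"]
    probs = probs + [1.0 - sum(probs)]
    records: list[ScreeningRecord] = []
    age_lo, age_hi = cfg.age_range
    los_lo, los_hi = cfg.los_range
    for i in range(n):
        cat = rng.choice(categories, p=probs)
        age = int(rng.integers(max(18, age_lo), age_hi + 1))
        los = int(rng.integers(max(7, los_lo), los_hi + 1))
        flags: frozenset = frozenset()
        if cat == "age_under_18":
            age = int(rng.integers(5, 18))
        elif cat == "los_under_7":
            los = int(rng.integers(1, 7))
        elif cat != "included":
            flags = frozenset({cat})
        records.append(ScreeningRecord(case_id=f"S{i + 1:04d}", age=age, los=los, flags=flags))
    return records


def _draw_los(rng: np.random.Generator, cfg: GeneratorConfig, tariff: DRGTariff) -> int:
    lo = max(tariff.ugvd, 7)
    if rng.uniform() < cfg.ogvd_straddle_fraction:
        extension = int(rng.integers(1, max(2, (cfg.los_range[1] - cfg.los_range[0]) // 2)))
        return tariff.ogvd + extension
    return int(rng.integers(lo, tariff.ogvd + 1))


def _quarters_spanned(rng: np.random.Generator, duration: int) -> int:
    start = int(rng.integers(0, 365))
    end = min(start + duration - 1, 364)
    q = lambda d: sum(d >= s for s in _QUARTER_STARTS)
    return q(end) - q(start) + 1


def generate_case(
    cfg: GeneratorConfig, tariff: DRGTariff, rng: np.random.Generator, case_id: str = "01"
) -> tuple[CaseRecord, ClinicalTimeline]:
    """Generate one episode and its timeline.

    ``dischargeable_days`` is recomputed from the timeline through
    :func:`earliest_discharge_day`, closing the loop that fixture data
    cannot test, and is at least one day by construction. ``actual_cost``
    is los x ward per-diem plus a lump (surgery, intensive care) incurred
    before the eligibility day.
    """
    los = _draw_los(rng, cfg, tariff)
    # keep eligibility strictly before actual discharge
    op_day = int(rng.integers(0, los - 5))
    intervention_day = int(rng.integers(0, los - 1))
    timeline = ClinicalTimeline(
        los=los,
        last_operation_day=op_day,
        last_intervention_day=intervention_day,
        wound_dry_day=0,
    )
    dischargeable = los - earliest_discharge_day(timeline)
    ward = _uniform_money(rng, *cfg.ward_per_diem_range)
    lump = _uniform_money(rng, *cfg.lump_cost_range) if cfg.lump_cost_range[1] > 0 else Decimal("0.00")
    regimen = "thrice_weekly" if rng.uniform() < cfg.thrice_weekly_fraction else "weekly"
    case = CaseRecord(
        case_id=case_id,
        age=int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1)),
        drg_code=tariff.drg_code,
        reason="synthetic periprosthetic joint infection episode",
        los=los,
        actual_revenue=case_revenue(los, tariff, cfg.base_rate),
        actual_cost=money(los * ward + lump),
        surcharge_per_diem=per_diem_surcharge(tariff, cfg.base_rate),
        ward_per_diem=ward,
        dischargeable_days=dischargeable,
        quarter_count=_quarters_spanned(rng, dischargeable),
        drug_daily_cost=_uniform_money(rng, *cfg.drug_rate_range),
        visit_count=1,  # placeholder, replaced by the schedule below
        regimen_class=regimen,
    )
    case.visit_count = max(1, planned_visit_count(plan_from_case(case)))
    return case, timeline


def generate_cohort(cfg: GeneratorConfig) -> tuple[list[CaseRecord], list[ClinicalTimeline]]:
    """Generate ``cfg.n_cases`` episodes from a single seeded stream."""
    rng = np.random.default_rng(cfg.seed)
    cases: list[CaseRecord] = []
    timelines: list[ClinicalTimeline] = []
    for i in range(cfg.n_cases):
        tariff = cfg.drg_pool[int(rng.integers(0, len(cfg.drg_pool)))]
        case, tl = generate_case(cfg, tariff, rng, case_id=f"{i + 1:02d}")
        cases.append(case)
        timelines.append(tl)
    return cases, timelines
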