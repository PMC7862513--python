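"""Synthetic generator: determinism, construction invariants, end-to-end
ledger identities, and parameter recovery."""

import math
from decimal import Decimal

import numpy as np
import pytest

from opat_costsim.cohort_model import apply_inclusion_filter
from opat_costsim.discharge_simulation import earliest_discharge_day, simulate_cohort
from opat_costsim.opat_costing import (
    payer_clinic_fee,
    payer_drug_cost,
    plan_from_case,
    provider_clinic_margin,
    summarize_opat,
)
from opat_costsim.perspectives_report import build_report
from opat_costsim.synthetic_cohort import (
    GeneratorConfig,
    generate_cohort,
    generate_screening_pool,
)
from opat_costsim.tariff_model import default_tariffs


class TestScreeningPool:
    def test_same_seed_same_pool(self):
        cfg = GeneratorConfig(seed=7)
        assert generate_screening_pool(cfg, n=200) == generate_screening_pool(cfg, n=200)

    def test_zero_exclusion_mix_includes_everyone(self):
        cfg = GeneratorConfig(seed=1, exclusion_mix={})
        pool = generate_screening_pool(cfg, n=50)
        included, tally = apply_inclusion_filter(pool)
        assert len(included) == 50
        assert sum(tally.values()) == 0

    def test_inclusion_fraction_near_configured(self):
        # default mix leaves 12/133 of candidates includable; at n=1330 the
        # binomial s.d. of the observed fraction is ~0.0079
        cfg = GeneratorConfig(seed=20150101)
        pool = generate_screening_pool(cfg, n=1330)
        included, _ = apply_inclusion_filter(pool)
        p = 12 / 133
        sd = math.sqrt(p * (1 - p) / 1330)
        assert abs(len(included) / 1330 - p) < 4 * sd

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError, match="exclusion"):
            GeneratorConfig(exclusion_mix={"los_under_7": 0.9, "complex_case": 0.3})


class TestGeneratedCases:
    def test_same_seed_same_cohort(self):
        cfg = GeneratorConfig(n_cases=20, seed=11)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        assert a == b

    def test_dischargeable_days_close_timeline_loop(self, tariffs):
        cases, timelines = generate_cohort(GeneratorConfig(n_cases=40, seed=3))
        for case, tl in zip(cases, timelines):
            assert case.los == tl.los
            assert case.dischargeable_days == case.los - earliest_discharge_day(tl)
            case.validate(tariffs)  # generated cohorts never violate invariants

    def test_no_straddle_means_no_revenue_reduction(self, tariffs):
        cfg = GeneratorConfig(n_cases=30, seed=5, ogvd_straddle_fraction=0.0)
        cases, _ = generate_cohort(cfg)
        sim = simulate_cohort(cases, tariffs)
        assert sim.total_revenue_reduction == 0
        assert all(c.los <= tariffs[c.drg_code].ogvd for c in cases)

    def test_parameter_recovery_of_ward_per_diem(self):
        # with the lump switched off and the ward rate degenerate, cost is
        # exactly linear in the stay: the regression recovers the per-diem
        cfg = GeneratorConfig(
            n_cases=60, seed=9,
            ward_per_diem_range=(250.0, 250.0), lump_cost_range=(0.0, 0.0),
        )
        cases, _ = generate_cohort(cfg)
        los = np.array([c.los for c in cases], dtype=float)
        cost = np.array([float(c.actual_cost) for c in cases])
        slope, intercept = np.polyfit(los, cost, 1)
        assert slope == pytest.approx(250.0, abs=1e-9)
        assert intercept == pytest.approx(0.0, abs=1e-6)


class TestEndToEnd:
    @pytest.mark.parametrize("seed", range(100))
    def test_ledger_identities_hold_on_random_cohorts(self, tariffs, seed):
        cases, _ = generate_cohort(GeneratorConfig(n_cases=6, seed=seed))
        rep = build_report(cases, tariffs)
        assert (
            rep.payer["net_extra_cost"]
            == rep.payer["opat_total"] - rep.payer["ipat_savings"]
        )
        p = rep.provider
        assert p["net_benefit"] == p["deficit_reduction"] + p["clinic_margin"]
        assert p["deficit_actual"] - p["deficit_simulated"] == -p["deficit_reduction"]
        assert p["deficit_actual"] == p["ipat_revenue_total"] - p["ipat_cost_total"]

    def test_pipeline_totals_equal_per_case_bruteforce(self, tariffs):
        cases, _ = generate_cohort(GeneratorConfig(n_cases=300, seed=123))
        rep = build_report(cases, tariffs)
        # independent brute force: sum every case separately
        rev_red = cost_red = opat = fees = margin = Decimal(0)
        for case in cases:
            t = tariffs[case.drg_code]
            days = min(case.dischargeable_days, max(0, case.los - t.ogvd))
            rev_red += days * case.surcharge_per_diem
            cost_red += case.dischargeable_days * case.ward_per_diem
            plan = plan_from_case(case)
            opat += payer_drug_cost(plan)
            fees += payer_clinic_fee(plan)
            margin += provider_clinic_margin(plan)
        assert rep.payer["ipat_savings"] == rev_red
        assert rep.payer["opat_total"] == opat
        assert rep.payer["opat_clinic_fees"] == fees
        assert rep.provider["clinic_margin"] == margin
        assert rep.provider["deficit_reduction"] == cost_red - rev_red
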