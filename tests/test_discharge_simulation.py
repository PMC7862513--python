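"""Early-discharge eligibility and the counterfactual payer/provider effects."""

from dataclasses import replace
from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from opat_costsim.discharge_simulation import (
    ClinicalTimeline,
    earliest_discharge_day,
    payer_revenue_reduction,
    provider_cost_reduction,
    saved_days,
    simulate_cohort,
)


class TestEarliestDischarge:
    def test_intervention_criterion_binds(self):
        t = ClinicalTimeline(los=40, last_operation_day=10,
                             last_intervention_day=20, wound_dry_day=12)
        assert earliest_discharge_day(t) == 21

    def test_operation_plus_five_dominates_on_day_zero_events(self):
        assert earliest_discharge_day(ClinicalTimeline(los=30)) == 5

    def test_capped_at_actual_discharge(self):
        t = ClinicalTimeline(los=30, last_operation_day=28)
        assert earliest_discharge_day(t) == 30

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(data=st.data(), los=st.integers(1, 120))
    def test_matches_bruteforce_max_rule(self, data, los):
        op = data.draw(st.integers(0, los))
        iv = data.draw(st.integers(0, los))
        wd = data.draw(st.integers(0, los))
        t = ClinicalTimeline(los=los, last_operation_day=op,
                             last_intervention_day=iv, wound_dry_day=wd)
        # independently: smallest day satisfying all three criteria, capped
        day = next(
            (d for d in range(los + 1) if d >= op + 5 and d >= iv + 1 and d >= wd),
            los,
        )
        assert earliest_discharge_day(t) == day

    def test_event_outside_stay_rejected(self):
        with pytest.raises(ValueError, match="last_operation_day"):
            ClinicalTimeline(los=10, last_operation_day=11)


class TestSavedDays:
    def test_case_12(self, by_id):
        assert saved_days(by_id["12"].los, by_id["12"].los - 25) == 25

    def test_fixture_total(self, cohort):
        assert sum(c.dischargeable_days for c in cohort) == 159

    def test_zero_when_discharged_on_time(self):
        assert saved_days(30, 30) == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            saved_days(10, 11)


class TestPayerRevenueReduction:
    def test_days_above_trim_point_bind(self, by_id, tariffs):
        # 15 dischargeable days but only 7 above the OGVD are revenue-bearing
        case = by_id["05"]
        assert payer_revenue_reduction(case, tariffs[case.drg_code]) == Decimal("1786.82")

    def test_saved_days_bind(self, by_id, tariffs):
        case = by_id["01"]
        assert payer_revenue_reduction(case, tariffs[case.drg_code]) == Decimal("4523.70")

    def test_zero_below_trim_point(self, by_id, tariffs):
        case = by_id["03"]  # 35-day stay, trim point 39
        assert payer_revenue_reduction(case, tariffs[case.drg_code]) == Decimal("0.00")

    def test_tariff_mismatch_rejected(self, by_id, tariffs):
        with pytest.raises(ValueError, match="does not match"):
            payer_revenue_reduction(by_id["01"], tariffs["I12A"])

    def test_bounded_by_both_day_counts(self, cohort, tariffs):
        for case in cohort:
            t = tariffs[case.drg_code]
            red = payer_revenue_reduction(case, t)
            assert red <= case.dischargeable_days * case.surcharge_per_diem
            assert red <= max(0, case.los - t.ogvd) * case.surcharge_per_diem


class TestProviderCostReduction:
    @pytest.mark.parametrize("cid,expected", [("01", "1358.00"), ("02", "3548.40"),
                                              ("12", "5899.50")])
    def test_ward_per_diem_times_saved_days(self, by_id, cid, expected):
        assert provider_cost_reduction(by_id[cid]) == Decimal(expected)

    def test_zero_saved_days(self, by_id):
        case = replace_dischargeable(by_id["05"], 0)
        assert provider_cost_reduction(case) == Decimal("0.00")


def replace_dischargeable(case, days):
    import copy

    c = copy.copy(case)
    c.dischargeable_days = days
    return c


class TestCohortSimulation:
    def test_case_01_counterfactual(self, cohort, tariffs):
        sim = simulate_cohort(cohort, tariffs)
        r = sim.per_case[0]
        assert r.new_revenue == Decimal("43016.06")
        assert r.new_cost == Decimal("39082.18")
        assert r.new_margin == Decimal("3933.88")

    def test_totals_and_conservation(self, cohort, tariffs):
        sim = simulate_cohort(cohort, tariffs)
        assert sim.total_revenue_reduction == Decimal("18117.35")
        assert sim.total_cost_reduction == Decimal("40713.60")
        assert sim.total_new_revenue == Decimal("178143.22")
        assert sim.total_new_cost == Decimal("211569.79")
        assert sim.total_new_margin == Decimal("-33426.57")
        assert sim.total_new_revenue == sim.total_actual_revenue - sim.total_revenue_reduction
        assert sim.total_new_cost == sim.total_actual_cost - sim.total_cost_reduction

    def test_identity_when_nothing_saved(self, cohort, tariffs):
        frozen = [replace_dischargeable(c, 0) for c in cohort]
        sim = simulate_cohort(frozen, tariffs)
        assert sim.total_new_revenue == sim.total_actual_revenue
        assert sim.total_new_cost == sim.total_actual_cost
        assert sim.total_saved_days == 0

    def test_no_case_falls_below_lower_trim_point(self, cohort, tariffs):
        for case in cohort:
            assert case.los - case.dischargeable_days >= tariffs[case.drg_code].ugvd

    def test_more_saved_days_never_increase_counterfactuals(self, cohort, tariffs):
        sim = simulate_cohort(cohort, tariffs)
        for case, base in zip(cohort, sim.per_case):
            if case.dischargeable_days + 1 > case.los:
                continue
            bumped = simulate_cohort(
                [replace_dischargeable(case, case.dischargeable_days + 1)], tariffs
            ).per_case[0]
            assert bumped.new_cost <= base.new_cost
            assert bumped.new_revenue <= base.new_revenue

    def test_unknown_drg_rejected(self, cohort, tariffs):
        slim = {k: v for k, v in tariffs.items() if k != "I01Z"}
        with pytest.raises(KeyError, match="I01Z"):
            simulate_cohort(cohort, slim)
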