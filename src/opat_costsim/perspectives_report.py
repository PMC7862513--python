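"""Headline payer / provider ledgers, summary statistics and report output.

Brings together the inpatient actuals, the early-discharge counterfactual
and the outpatient costing into the two bottom lines:

* payer: net extra cost of switching to OPAT
  = outpatient total - inpatient savings;
* provider: net benefit
  = (cost reduction - revenue reduction) + outpatient clinic margin.

The provider benefit has a second, gross framing in which the inpatient
revenue reduction is not netted (residual-deficit improvement minus the
clinic deficit); both are computed and labelled explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from .money import money, fmt_eur
from .cohort_model import CaseRecord
from .tariff_model import DRGTariff
from .discharge_simulation import CohortSimulation, simulate_cohort
from .opat_costing import (
    ClinicCostSchedule,
    DEFAULT_SCHEDULE,
    OPATSummary,
    payer_clinic_fee,
    plan_from_case,
    summarize_opat,
)

__all__ = [
    "per_diem_statistics",
    "payer_ledger",
    "provider_ledger",
    "PerspectiveReport",
    "build_report",
    "write_report",
]


def per_diem_statistics(values: list[Decimal]) -> dict[str, Decimal]:
    """Mean, median and range of a list of daily rates, cents-rounded.

    The even-n median is the midpoint of the two central order statistics.
    """
    if not values:
        raise ValueError("no rates supplied")
    ordered = sorted(Decimal(v) for v in values)
    n = len(ordered)
    if n % 2:
        median = ordered[n // 2]
    else:
        median = (ordered[n // 2 - 1] + ordered[n // 2]) / 2
    return {
        "mean": money(sum(ordered) / n),
        "median": money(median),
        "min": money(ordered[0]),
        "max": money(ordered[-1]),
    }


def payer_ledger(sim: CohortSimulation, opat: OPATSummary) -> dict[str, Decimal]:
    """Statutory-insurer bottom line of the inpatient-to-outpatient switch."""
    return {
        "ipat_total": sim.total_actual_revenue,
        "ipat_savings": sim.total_revenue_reduction,
        "opat_total": opat.opat_total,
        "opat_clinic_fees": opat.clinic_fees,
        "opat_drug_cost": opat.drug_cost_ex_fees,
        "net_extra_cost": opat.opat_total - sim.total_revenue_reduction,
    }


def provider_ledger(sim: CohortSimulation, opat: OPATSummary) -> dict[str, Decimal | int]:
    """Hospital bottom line: deficits before/after, clinic margin, benefit."""
    deficit_reduction = sim.total_cost_reduction - sim.total_revenue_reduction
    ledger: dict[str, Decimal | int] = {
        "ipat_revenue_total": sim.total_actual_revenue,
        "ipat_cost_total": sim.total_actual_cost,
        "deficit_actual": sim.total_actual_margin,
        "deficit_simulated": sim.total_new_margin,
        "deficit_reduction": deficit_reduction,
        "clinic_margin": opat.clinic_margin,
        "net_benefit": deficit_reduction + opat.clinic_margin,
        # gross framing: residual-deficit improvement less the clinic deficit,
        # without netting the inpatient revenue reduction
        "net_benefit_gross": abs(sim.total_new_margin) - abs(opat.clinic_margin),
        "bed_days_freed": sim.total_saved_days,
    }
    return ledger


@dataclass
class PerspectiveReport:
    """Full dual-perspective report: six case tables, ledgers, statistics."""

    tables: dict[str, list[dict]]
    payer: dict[str, Decimal]
    provider: dict[str, Decimal | int]
    per_diem_stats: dict[str, dict[str, Decimal]]
    deficit_share_pct: int


def _totals_row(rows: list[dict], sum_cols: list[str], label_col: str) -> dict:
    total = {k: "" for k in rows[0]}
    total[label_col] = "total"
    for col in sum_cols:
        total[col] = sum((Decimal(str(r[col])) for r in rows), Decimal(0))
    return total


def build_report(
    cases: list[CaseRecord],
    tariffs: dict[str, DRGTariff],
    sched: ClinicCostSchedule = DEFAULT_SCHEDULE,
) -> PerspectiveReport:
    """Run the whole pipeline on a cohort and assemble the report."""
    sim = simulate_cohort(cases, tariffs)
    plans = [plan_from_case(c) for c in cases]
    opat = summarize_opat(plans, sched)
    by_id = {r.case_id: r for r in sim.per_case}

    t_actuals, t_payer_red, t_sim, t_provider_red, t_opat_payer, t_opat_provider = (
        [], [], [], [], [], [],
    )
    for case, plan in zip(cases, plans):
        res = by_id[case.case_id]
        tariff = tariffs[case.drg_code]
        diff = case.los - tariff.ogvd
        t_actuals.append({
            "case_id": case.case_id, "drg": case.drg_code,
            "cost": case.actual_cost, "revenue": case.actual_revenue,
            "margin": res.actual_margin, "los": case.los,
            "ogvd": tariff.ogvd, "los_minus_ogvd": diff,
        })
        t_payer_red.append({
            "case_id": case.case_id, "revenue": case.actual_revenue,
            "los_minus_ogvd": diff, "surcharge_per_diem": case.surcharge_per_diem,
            "dischargeable_days": case.dischargeable_days,
            "revenue_reduction": res.revenue_reduction,
        })
        t_sim.append({
            "case_id": case.case_id,
            "revenue": res.actual_revenue, "revenue_new": res.new_revenue,
            "cost": res.actual_cost, "cost_new": res.new_cost,
            "margin": res.actual_margin, "margin_new": res.new_margin,
        })
        t_provider_red.append({
            "case_id": case.case_id, "cost": case.actual_cost,
            "los_minus_ogvd": diff, "ward_per_diem": case.ward_per_diem,
            "dischargeable_days": case.dischargeable_days,
            "cost_reduction": res.cost_reduction,
        })
        clinic_fee = payer_clinic_fee(plan, sched)
        t_opat_payer.append({
            "case_id": case.case_id, "clinic_fee": clinic_fee,
            "drug_daily_cost": plan.drug_daily_cost,
            "opat_total": money(plan.duration_days * plan.drug_daily_cost),
        })
        visit_cost = money(plan.visit_count * sched.per_visit_total)
        t_opat_provider.append({
            "case_id": case.case_id, "clinic_revenue": clinic_fee,
            "clinic_cost": visit_cost, "clinic_margin": clinic_fee - visit_cost,
        })

    tables = {
        "table4": t_actuals + [_totals_row(t_actuals, ["cost", "revenue", "margin"], "case_id")],
        "table5": t_payer_red + [_totals_row(t_payer_red, ["revenue", "dischargeable_days", "revenue_reduction"], "case_id")],
        "table6": t_sim + [_totals_row(t_sim, ["revenue", "revenue_new", "cost", "cost_new", "margin", "margin_new"], "case_id")],
        "table7": t_provider_red + [_totals_row(t_provider_red, ["cost", "dischargeable_days", "cost_reduction"], "case_id")],
        "table8": t_opat_payer + [_totals_row(t_opat_payer, ["clinic_fee", "opat_total"], "case_id")],
        "table9": t_opat_provider + [_totals_row(t_opat_provider, ["clinic_revenue", "clinic_cost", "clinic_margin"], "case_id")],
    }

    payer = payer_ledger(sim, opat)
    provider = provider_ledger(sim, opat)
    stats = {
        "inpatient_surcharge_per_diem": per_diem_statistics(
            [c.surcharge_per_diem for c in cases]
        ),
        "drug_daily_cost": per_diem_statistics([c.drug_daily_cost for c in cases]),
        "drug_cost_per_patient": per_diem_statistics(
            [money(p.duration_days * p.drug_daily_cost) for p in plans]
        ),
    }
    share = (abs(sim.total_actual_margin) / sim.total_actual_cost * 100).quantize(
        Decimal("1"), rounding=ROUND_HALF_UP
    )
    return PerspectiveReport(
        tables=tables,
        payer=payer,
        provider=provider,
        per_diem_stats=stats,
        deficit_share_pct=int(share),
    )


def _cell(v) -> str:
    return fmt_eur(v) if isinstance(v, Decimal) else str(v)


def write_report(report: PerspectiveReport, outdir: str | Path, fmt: str = "csv") -> list[Path]:
    """Write table4..table9, summary.json and summary.txt; deterministic.

    Identical inputs yield byte-identical files. Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown format {fmt!r}")
    for name, rows in report.tables.items():
        if fmt == "csv":
            path = outdir / f"{name}.csv"
            lines = [",".join(rows[0].keys())]
            lines += [",".join(_cell(v) for v in row.values()) for row in rows]
            path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        else:
            path = outdir / f"{name}.json"
            path.write_text(
                json.dumps(
                    [{k: _cell(v) for k, v in row.items()} for row in rows], indent=2
                )
                + "\n",
                encoding="utf-8",
            )
        written.append(path)

    summary = {
        "payer": {k: _cell(v) for k, v in report.payer.items()},
        "provider": {k: _cell(v) for k, v in report.provider.items()},
        "per_diem_stats": {
            name: {k: _cell(v) for k, v in stats.items()}
            for name, stats in report.per_diem_stats.items()
        },
        "provider_deficit_share_pct": report.deficit_share_pct,
    }
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(spath)

    txt = [
        "Dual-perspective cost comparison: inpatient vs outpatient parenteral antibiotics",
        "",
        "Payer (statutory insurance) perspective, EUR:",
        f"  inpatient case payments (actual)      {fmt_eur(report.payer['ipat_total'])}",
        f"  inpatient savings from early discharge {fmt_eur(report.payer['ipat_savings'])}",
        f"  outpatient total (drugs incl. fees)    {fmt_eur(report.payer['opat_total'])}",
        f"    of which clinic flat fees            {fmt_eur(report.payer['opat_clinic_fees'])}",
        f"    of which drugs (net of fees)         {fmt_eur(report.payer['opat_drug_cost'])}",
        f"  net extra cost of OPAT                 {fmt_eur(report.payer['net_extra_cost'])}",
        "",
        "Provider (hospital) perspective, EUR:",
        f"  inpatient revenue (actual)             {fmt_eur(report.provider['ipat_revenue_total'])}",
        f"  inpatient cost (actual)                {fmt_eur(report.provider['ipat_cost_total'])}",
        f"  contribution margin, actual            {fmt_eur(report.provider['deficit_actual'])}",
        f"  contribution margin, simulated         {fmt_eur(report.provider['deficit_simulated'])}",
        f"  outpatient clinic margin               {fmt_eur(report.provider['clinic_margin'])}",
        f"  net benefit of OPAT (revenue netted)   {fmt_eur(report.provider['net_benefit'])}",
        f"  net benefit of OPAT (gross framing)    {fmt_eur(report.provider['net_benefit_gross'])}",
        f"  bed days freed                         {report.provider['bed_days_freed']}",
        "",
        f"Actual deficit as share of provider cost: {report.deficit_share_pct}%",
    ]
    tpath = outdir / "summary.txt"
    tpath.write_text("\n".join(txt) + "\n", encoding="utf-8")
    written.append(tpath)
    return written
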