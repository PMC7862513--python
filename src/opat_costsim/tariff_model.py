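"""G-DRG case-payment arithmetic.

A German DRG (Diagnosis Related Group) pays a fixed relative weight for any
length of stay between the lower and upper trimming points (UGVD and OGVD).
Days beyond the OGVD each earn an additional per-day relative weight (the
long-stay supplement); the first surcharge day is OGVD + 1. Stays below the
UGVD are discounted per day, the first discount day being UGVD - 1. Euros are
obtained by multiplying the summed relative weight by the federal base case
value (Bundesbasisfallwert, BBFW; 3231.20 EUR in 2015).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from pathlib import Path

from .money import money

__all__ = [
    "DRGTariff",
    "BaseRate",
    "DEFAULT_BASE_RATE",
    "per_diem_surcharge",
    "surcharge_days",
    "discount_days",
    "case_revenue",
    "case_revenue_brute_force",
    "load_tariffs",
    "default_tariffs",
]


@dataclass(frozen=True)
class DRGTariff:
    """One catalogue row: trimming points and relative weights for a DRG.

    Attributes
    ----------
    drg_code : catalogue label, e.g. ``"I12A"``.
    ugvd : lower trimming point in days.
    ugvd_br_per_day : relative weight discounted per day below the UGVD.
    mvd : catalogue mean length of stay (informational).
    inlier_br : relative weight for stays within the trimming points.
    ogvd : upper trimming point in days.
    ogvd_br_per_day : relative weight added per day above the OGVD.
    """

    drg_code: str
    ugvd: int
    ugvd_br_per_day: Decimal
    mvd: Decimal
    inlier_br: Decimal
    ogvd: int
    ogvd_br_per_day: Decimal

    def __post_init__(self) -> None:
        for name in ("ugvd_br_per_day", "mvd", "inlier_br", "ogvd_br_per_day"):
            object.__setattr__(self, name, Decimal(str(getattr(self, name))))
        if not self.drg_code:
            raise ValueError("drg_code must be non-empty")
        if self.ugvd < 1:
            raise ValueError(f"{self.drg_code}: ugvd must be >= 1, got {self.ugvd}")
        if self.ogvd <= self.ugvd:
            raise ValueError(f"{self.drg_code}: ogvd ({self.ogvd}) must exceed ugvd ({self.ugvd})")
        for name in ("ugvd_br_per_day", "inlier_br", "ogvd_br_per_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.drg_code}: {name} must be > 0")
        if not (self.ugvd < self.mvd < self.ogvd):
            raise ValueError(
                f"{self.drg_code}: mvd ({self.mvd}) must lie strictly between "
                f"ugvd ({self.ugvd}) and ogvd ({self.ogvd})"
            )


@dataclass(frozen=True)
class BaseRate:
    """Federal base case value: euros paid per relative-weight unit."""

    bbfw: Decimal
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bbfw", Decimal(str(self.bbfw)))
        if self.bbfw <= 0:
            raise ValueError(f"bbfw must be > 0, got {self.bbfw}")


#: 2015 federal base case value.
DEFAULT_BASE_RATE = BaseRate(Decimal("3231.20"), label="G-DRG 2015")


def per_diem_surcharge(tariff: DRGTariff, rate: BaseRate) -> Decimal:
    """Euro value of one surcharge day above the OGVD (cents, half-up)."""
    return money(tariff.ogvd_br_per_day * rate.bbfw)


def per_diem_discount(tariff: DRGTariff, rate: BaseRate) -> Decimal:
    """Euro value of one discount day below the UGVD (cents, half-up)."""
    return money(tariff.ugvd_br_per_day * rate.bbfw)


def surcharge_days(los: int, tariff: DRGTariff) -> int:
    """Number of surcharge days for a stay of ``los`` days.

    The first surcharge day is OGVD + 1, so a stay ending exactly on the
    OGVD earns none.
    """
    if los < 1:
        raise ValueError(f"los must be >= 1, got {los}")
    return max(0, los - tariff.ogvd)


def discount_days(los: int, tariff: DRGTariff) -> int:
    """Number of discount days for a stay of ``los`` days.

    The first discount day is UGVD - 1, i.e. a stay one day short of the
    UGVD is discounted by exactly one day.
    """
    if los < 1:
        raise ValueError(f"los must be >= 1, got {los}")
    return max(0, tariff.ugvd - los)


def case_revenue(los: int, tariff: DRGTariff, rate: BaseRate) -> Decimal:
    """Case payment in euros for a stay of ``los`` days.

    The effective relative weight is the inlier weight, plus one per-day
    weight for each day above the OGVD, minus one per-day weight for each
    day below the UGVD; the euro amount is weight x base rate, rounded to
    cents half-up.
    """
    weight = (
        tariff.inlier_br
        + surcharge_days(los, tariff) * tariff.ogvd_br_per_day
        - discount_days(los, tariff) * tariff.ugvd_br_per_day
    )
    return money(weight * rate.bbfw)


def case_revenue_brute_force(los: int, tariff: DRGTariff, rate: BaseRate) -> Decimal:
    """Day-by-day accumulation oracle for :func:`case_revenue`.

    Walks the stay one day at a time: the inlier lump is booked when the
    stay reaches the UGVD, every day past the OGVD adds a per-day weight,
    and every missing day up to the UGVD subtracts one. Kept deliberately
    independent of the closed-form path.
    """
    if los < 1:
        raise ValueError(f"los must be >= 1, got {los}")
    weight = Decimal(0)
    booked_inlier = False
    for day in range(1, los + 1):
        if day == tariff.ugvd:
            weight += tariff.inlier_br
            booked_inlier = True
        if day > tariff.ogvd:
            weight += tariff.ogvd_br_per_day
    if not booked_inlier:  # short stay: lump minus one discount per missing day
        weight += tariff.inlier_br
        for day in range(los + 1, tariff.ugvd + 1):
            weight -= tariff.ugvd_br_per_day
    return money(weight * rate.bbfw)


def load_tariffs(path: str | Path) -> dict[str, DRGTariff]:
    """Read a tariff catalogue CSV into a dict keyed by DRG code.

    Expected columns: drg_code, ugvd, ugvd_br, mvd, inlier_br, ogvd, ogvd_br
    (comma-separated, dot decimals, header row required).
    """
    tariffs: dict[str, DRGTariff] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"drg_code", "ugvd", "ugvd_br", "mvd", "inlier_br", "ogvd", "ogvd_br"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"tariff catalogue missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                t = DRGTariff(
                    drg_code=row["drg_code"].strip(),
                    ugvd=int(row["ugvd"]),
                    ugvd_br_per_day=Decimal(row["ugvd_br"]),
                    mvd=Decimal(row["mvd"]),
                    inlier_br=Decimal(row["inlier_br"]),
                    ogvd=int(row["ogvd"]),
                    ogvd_br_per_day=Decimal(row["ogvd_br"]),
                )
            except (ValueError, ArithmeticError) as exc:
                raise ValueError(f"tariff catalogue row {i}: {exc}") from exc
            tariffs[t.drg_code] = t
    return tariffs


def default_tariffs() -> dict[str, DRGTariff]:
    """The bundled 2015 catalogue for the six hip/knee infection DRGs."""
    with resources.as_file(
        resources.files("opat_costsim").joinpath("data/tariffs_2015.csv")
    ) as p:
        return load_tariffs(p)
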