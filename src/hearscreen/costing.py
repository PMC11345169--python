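"""Micro-costing engine for screening modalities.

Converts raw cost line items (apportioned salaries, straight-line annualized
equipment, consumables, overheads) into annual program costs, throughput and
unit cost per screen for each modality (portable automated ABR, OAE, BERA).

All arithmetic is carried out on unrounded values; half-up rounded views are
produced only for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .util import InvalidParameterError, UndefinedMetricError, round_half_up

#: Six cost categories of an annual cost inventory, in report order.
INVENTORY_CATEGORIES = (
    "human_resource",
    "medical_consumables",
    "non_medical_consumables",
    "medical_equipment",
    "non_medical_equipment",
    "overheads",
)


@dataclass(frozen=True)
class StaffCostLine:
    """One staff member's salary line, apportioned to the screening program.

    The apportioning statistic is the fraction of the salary attributed to
    screening.  If not given explicitly it is derived from the daily hours
    spent on screening: ``hours_per_day * working_days_per_month /
    overall_monthly_hours`` (22 working days/month, 176 h full time).
    """

    role: str
    monthly_salary: float
    hours_per_day_on_screening: float = 8.0
    overall_monthly_hours: float = 176.0
    apportioning_statistic: float | None = None
    months_per_year: int = 12
    working_days_per_month: float = 22.0

    def __post_init__(self) -> None:
        if self.monthly_salary < 0:
            raise InvalidParameterError(f"{self.role}: monthly_salary must be >= 0")
        if self.overall_monthly_hours <= 0:
            raise InvalidParameterError(f"{self.role}: overall_monthly_hours must be > 0")
        a = self.effective_apportioning
        if not 0.0 <= a <= 1.0:
            raise InvalidParameterError(
                f"{self.role}: apportioning statistic {a} outside [0, 1]"
            )

    @property
    def monthly_hours_on_screening(self) -> float:
        return self.hours_per_day_on_screening * self.working_days_per_month

    @property
    def effective_apportioning(self) -> float:
        if self.apportioning_statistic is not None:
            return self.apportioning_statistic
        return self.monthly_hours_on_screening / self.overall_monthly_hours


@dataclass(frozen=True)
class EquipmentCostLine:
    """A capital purchase annualized straight-line over its lifespan (no discounting)."""

    description: str
    purchase_price: float
    lifespan_years: float = 6.0

    def __post_init__(self) -> None:
        if self.purchase_price < 0:
            raise InvalidParameterError(f"{self.description}: purchase_price must be >= 0")
        if self.lifespan_years <= 0:
            raise InvalidParameterError(f"{self.description}: lifespan_years must be > 0")


@dataclass(frozen=True)
class CostInventory:
    """Annual cost inventory (INR/year) across the six standard categories."""

    human_resource: float = 0.0
    medical_consumables: float = 0.0
    non_medical_consumables: float = 0.0
    medical_equipment: float = 0.0
    non_medical_equipment: float = 0.0
    overheads: float = 0.0

    def __post_init__(self) -> None:
        for cat in INVENTORY_CATEGORIES:
            if getattr(self, cat) < 0:
                raise InvalidParameterError(f"inventory component {cat} must be >= 0")

    @property
    def total(self) -> float:
        return sum(getattr(self, cat) for cat in INVENTORY_CATEGORIES)

    def as_dict(self) -> dict[str, float]:
        return {cat: getattr(self, cat) for cat in INVENTORY_CATEGORIES}


@dataclass(frozen=True)
class ScreeningModality:
    """A first-line or confirmatory hearing test with its throughput and cost economics."""

    name: str
    test_duration_minutes: float
    inventory: CostInventory
    working_days_per_year: int = 260
    effective_screening_hours_per_day: float = 6.0
    staff_lines: tuple[StaffCostLine, ...] = field(default_factory=tuple)
    equipment_lines: tuple[EquipmentCostLine, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.test_duration_minutes <= 0:
            raise InvalidParameterError(
                f"{self.name}: test_duration_minutes must be > 0"
            )
        if self.effective_screening_hours_per_day <= 0:
            raise InvalidParameterError(
                f"{self.name}: effective_screening_hours_per_day must be > 0"
            )


@dataclass(frozen=True)
class UnitCost:
    """Unit cost per screen: exact value for accumulation, half-up integer for reporting."""

    unrounded: float
    reported: int


def daily_throughput(modality: ScreeningModality) -> int:
    """Whole screens completable in one working day."""
    return int(
        math.floor(
            modality.effective_screening_hours_per_day * 60.0
            / modality.test_duration_minutes
        )
    )


def annual_throughput(modality: ScreeningModality) -> int:
    """Screens per year = daily throughput x working days."""
    return daily_throughput(modality) * modality.working_days_per_year


def annualize_equipment(line: EquipmentCostLine) -> float:
    """Straight-line annual cost of a capital item: price / lifespan, no salvage value."""
    return line.purchase_price / line.lifespan_years


def staff_monthly_cost(line: StaffCostLine) -> float:
    """Monthly cost to the system: salary x apportioning statistic."""
    return line.monthly_salary * line.effective_apportioning


def staff_annual_cost(line: StaffCostLine) -> float:
    return staff_monthly_cost(line) * line.months_per_year


def total_annual_cost(inventory: CostInventory) -> float:
    """Exact sum of the six inventory components (INR/year)."""
    return inventory.total


def unit_cost(modality: ScreeningModality) -> UnitCost:
    """Cost per screen = total annual cost / annual throughput.

    Raises
    ------
    UndefinedMetricError
        If the modality has zero annual throughput.
    """
    volume = annual_throughput(modality)
    if volume <= 0:
        raise UndefinedMetricError(
            f"{modality.name}: annual throughput is {volume}; unit cost undefined "
            f"(duration {modality.test_duration_minutes} min, "
            f"{modality.working_days_per_year} working days)"
        )
    exact = total_annual_cost(modality.inventory) / volume
    return UnitCost(unrounded=exact, reported=int(round_half_up(exact)))


def inventory_from_lines(
    staff_lines: tuple[StaffCostLine, ...] | list[StaffCostLine] = (),
    equipment_lines: tuple[EquipmentCostLine, ...] | list[EquipmentCostLine] = (),
    medical_consumables: float = 0.0,
    non_medical_consumables: float = 0.0,
    non_medical_equipment: float = 0.0,
    overheads: float = 0.0,
    extra_human_resource: float = 0.0,
) -> CostInventory:
    """Assemble an annual inventory from staff and equipment lines plus direct amounts.

    ``extra_human_resource`` covers lump-sum HR items amortized in the analysis
    year, such as post-service training.
    """
    return CostInventory(
        human_resource=sum(staff_annual_cost(s) for s in staff_lines) + extra_human_resource,
        medical_consumables=medical_consumables,
        non_medical_consumables=non_medical_consumables,
        medical_equipment=sum(annualize_equipment(e) for e in equipment_lines),
        non_medical_equipment=non_medical_equipment,
        overheads=overheads,
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "modality",
    "category",
    "description",
    "amount",
    "lifespan_years",
    "monthly_salary",
    "apportioning_statistic",
]


def read_cost_inventory_csv(path) -> dict[str, CostInventory]:
    """Read a line-item cost inventory CSV into per-modality annual inventories.

    Each row contributes to one of the six categories of one modality.  A row
    with ``monthly_salary`` set is an apportioned staff line (annual =
    salary x apportioning x 12); a row with ``lifespan_years`` set is a capital
    purchase annualized straight-line; otherwise ``amount`` is taken as an
    annual INR figure directly.
    """
    df = pd.read_csv(path)
    missing = {"modality", "category", "amount"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"cost inventory CSV missing columns: {sorted(missing)}")
    totals: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        cat = str(row["category"])
        if cat not in INVENTORY_CATEGORIES:
            raise InvalidParameterError(
                f"unknown cost category {cat!r}; expected one of {INVENTORY_CATEGORIES}"
            )
        salary = row.get("monthly_salary")
        lifespan = row.get("lifespan_years")
        if salary is not None and not pd.isna(salary):
            app = row.get("apportioning_statistic")
            line = StaffCostLine(
                role=str(row.get("description", "")),
                monthly_salary=float(salary),
                apportioning_statistic=None if pd.isna(app) else float(app),
            )
            annual = staff_annual_cost(line)
        elif lifespan is not None and not pd.isna(lifespan):
            annual = annualize_equipment(
                EquipmentCostLine(
                    description=str(row.get("description", "")),
                    purchase_price=float(row["amount"]),
                    lifespan_years=float(lifespan),
                )
            )
        else:
            annual = float(row["amount"])
        totals.setdefault(str(row["modality"]), {c: 0.0 for c in INVENTORY_CATEGORIES})
        totals[str(row["modality"])][cat] += annual
    return {name: CostInventory(**cats) for name, cats in totals.items()}


def costing_report(modalities: list[ScreeningModality]) -> pd.DataFrame:
    """Per-modality costing table mirroring the screening-cost summary layout.

    One column per modality; rows are duration, throughput, the six annual cost
    categories, total annual cost and unit cost (reported and unrounded).
    """
    cols = {}
    for m in modalities:
        uc = unit_cost(m)
        col = {
            "test_duration_minutes": m.test_duration_minutes,
            "working_days_per_year": m.working_days_per_year,
            "daily_throughput": daily_throughput(m),
            "annual_throughput": annual_throughput(m),
            **{f"cost_{cat}": getattr(m.inventory, cat) for cat in INVENTORY_CATEGORIES},
            "total_annual_cost": total_annual_cost(m.inventory),
            "unit_cost_reported": uc.reported,
            "unit_cost_unrounded": uc.unrounded,
        }
        cols[m.name] = col
    out = pd.DataFrame(cols)
    out.index.name = "item"
    return out


def with_total_override(modality: ScreeningModality, total: float) -> ScreeningModality:
    """Scale nothing — replace the inventory by a single-line one matching ``total``.

    Used for what-if runs where only a printed total is known; keeps the
    modality's throughput economics intact.
    """
    if total < 0:
        raise InvalidParameterError("total cost override must be >= 0")
    return replace(modality, inventory=CostInventory(human_resource=total))
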