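"""Activity-based unit costing, annual scenario costs and break-even analysis.

Unit full costs per examination decompose into contrast agent, medical
personnel, radiographers, nursing and allocated asset depreciation.  Capacity
(fixed) costs — personnel and equipment — are related to examinations through
mean occupation times against the unit's practical capacity hours, not by
dividing annual cost by examination volume, so a change in volume does not
change the unit cost.  All arithmetic is exact in cents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Mapping

from ._money import CENT, money
from .io import AssetSpec
from .pathway import Utilisation

COMPONENTS = ("contrast", "medical", "radiographer", "nursing", "depreciation")


@dataclass(frozen=True)
class UnitCost:
    """Per-examination full cost, exact in cents."""

    contrast: Decimal = Decimal("0.00")
    medical: Decimal = Decimal("0.00")
    radiographer: Decimal = Decimal("0.00")
    nursing: Decimal = Decimal("0.00")
    depreciation: Decimal = Decimal("0.00")

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"unit-cost component {name} must be nonnegative")

    @property
    def total(self) -> Decimal:
        return (
            self.contrast
            + self.medical
            + self.radiographer
            + self.nursing
            + self.depreciation
        )

    @classmethod
    def from_mapping(cls, components: Mapping[str, object]) -> "UnitCost":
        return cls(**{k: money(v) for k, v in components.items() if k in COMPONENTS})


def unit_total(components: UnitCost) -> Decimal:
    """Cent-exact sum of the five unit-cost components."""
    return components.total


class CtVariant(str, Enum):
    UNENHANCED = "unenhanced"
    CONTRAST_ENHANCED = "contrast_enhanced"


@dataclass(frozen=True)
class Scenario:
    """Annual utilisation priced against a unit-cost table."""

    label: str
    utilisation: Utilisation
    unit_costs: Mapping[str, UnitCost]
    ct_variant: CtVariant = CtVariant.UNENHANCED


def annual_depreciation(asset: AssetSpec) -> Decimal:
    """Straight-line annual depreciation: price / useful life.

    An explicit override on the asset (a depreciation figure taken directly
    from the accounting system) takes precedence over the straight line.
    """
    if asset.useful_life_years <= 0:
        raise ValueError("useful_life_years must be positive")
    if asset.annual_depreciation_override is not None:
        return asset.annual_depreciation_override
    return (asset.price / asset.useful_life_years).quantize(CENT, rounding=ROUND_HALF_UP)


def allocate_capacity_cost(
    annual_cost: Decimal, capacity_hours: float, occupation_min: float
) -> Decimal:
    """Slice an annual capacity cost onto one examination by occupation time.

    annual_cost / (capacity_hours * 60) * occupation_min, rounded half-up to
    cents at the per-examination boundary.
    """
    if capacity_hours <= 0:
        raise ValueError("capacity_hours must be positive")
    if occupation_min < 0:
        raise ValueError("occupation_min must be nonnegative")
    per_min = money(annual_cost) / (Decimal(str(capacity_hours)) * 60)
    return (per_min * Decimal(str(occupation_min))).quantize(CENT, rounding=ROUND_HALF_UP)


def scenario_cost(s: Scenario) -> Decimal:
    """Total annual cost: sum over modalities of count x unit total.

    Subdiagnostic tomosynthesis examinations are charged at the DTS unit cost
    (they consume the examination without diagnostic yield).
    """
    total = Decimal("0.00")
    for modality, count in s.utilisation.counts.items():
        if count == 0:
            continue
        if modality not in s.unit_costs:
            raise ValueError(f"no unit cost for utilised modality {modality!r}")
        total += count * s.unit_costs[modality].total
    if s.utilisation.subdiagnostic_dts:
        if "DTS" not in s.unit_costs:
            raise ValueError("subdiagnostic DTS utilised but no DTS unit cost given")
        total += s.utilisation.subdiagnostic_dts * s.unit_costs["DTS"].total
    return total


def differential_saving(before: Scenario, after: Scenario) -> Decimal:
    """Annual saving of the *after* scenario: cost(before) - cost(after)."""
    if before.ct_variant is not after.ct_variant:
        raise ValueError(
            "scenarios price CT differently "
            f"({before.ct_variant.value} vs {after.ct_variant.value})"
        )
    return scenario_cost(before) - scenario_cost(after)


@dataclass(frozen=True)
class BreakEvenInput:
    fixed_cost: Decimal
    reimbursement_rate: Decimal
    variable_unit_cost: Decimal = Decimal("0.00")

    def __post_init__(self) -> None:
        if self.fixed_cost < 0:
            raise ValueError("fixed_cost must be nonnegative")

    @property
    def contribution_margin(self) -> Decimal:
        return self.reimbursement_rate - self.variable_unit_cost


def break_even(b: BreakEvenInput) -> int:
    """Examinations needed to recover the fixed cost.

    Smallest integer n with n x (reimbursement - variable unit cost) >=
    fixed cost, i.e. the ceiling of fixed cost / contribution margin.
    """
    margin = b.contribution_margin
    if margin <= 0:
        raise ValueError("contribution margin must be positive: never breaks even")
    if b.fixed_cost == 0:
        return 0
    return math.ceil(b.fixed_cost / margin)
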