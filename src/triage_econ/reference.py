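"""Aggregate tables of the reference single-centre chest-imaging cohort.

These in-memory tables — lesion-category counts, per-reader confusion
aggregates, equipment and unit-cost tables, annual utilisation and
reimbursement — are the package's worked example: a cohort of 465 patients
with suspected thoracic lesions on chest radiography triaged by digital
tomosynthesis, costed against the hospital's accounting figures for 2012.
"""

from __future__ import annotations

from decimal import Decimal

from ._money import money
from .accuracy import ConfusionCounts
from .costing import BreakEvenInput, CtVariant, Scenario, UnitCost
from .io import AssetSpec
from .pathway import Utilisation
from .records import LesionCategory

#: lesion-category counts (465 patients; 144 CT-deserving positives)
CATEGORY_COUNTS: dict[LesionCategory, int] = {
    LesionCategory.PULMONARY_OPACITY: 60,
    LesionCategory.PRIMARY_LUNG_NEOPLASM: 5,
    LesionCategory.GROUND_GLASS: 47,
    LesionCategory.NONCALCIFIED_SOLID_NODULE: 32,
    LesionCategory.PULMONARY_SCAR: 26,
    LesionCategory.CALCIFIED_SOLID_NODULE: 23,
    LesionCategory.PLEURAL_PLAQUE: 36,
    LesionCategory.PSEUDOLESION: 236,
}

#: mean size (cm) and SD per category; pseudolesions carry no size
CATEGORY_SIZES: dict[LesionCategory, tuple[float, float]] = {
    LesionCategory.PULMONARY_OPACITY: (2.5, 0.3),
    LesionCategory.PRIMARY_LUNG_NEOPLASM: (2.5, 0.7),
    LesionCategory.GROUND_GLASS: (2.5, 0.4),
    LesionCategory.NONCALCIFIED_SOLID_NODULE: (1.1, 0.3),
    LesionCategory.PULMONARY_SCAR: (1.1, 0.3),
    LesionCategory.CALCIFIED_SOLID_NODULE: (1.1, 0.3),
    LesionCategory.PLEURAL_PLAQUE: (2.4, 0.6),
}

#: per-reader, per-modality confusion aggregates (marker-lesion analysis)
CONFUSION: dict[tuple[str, str], ConfusionCounts] = {
    ("reader1", "CXR"): ConfusionCounts(tp=34, tn=33, fp=288, fn=110),
    ("reader1", "DTS"): ConfusionCounts(tp=116, tn=308, fp=13, fn=28),
    ("reader2", "CXR"): ConfusionCounts(tp=25, tn=43, fp=278, fn=119),
    ("reader2", "DTS"): ConfusionCounts(tp=122, tn=308, fp=13, fn=22),
}

#: interpretation time (s): mean, SD per modality
INTERPRETATION_TIME_S: dict[str, tuple[float, float]] = {
    "CXR": (66.0, 23.0),
    "DTS": (103.0, 66.0),
}

#: consensus triage outcome: 127/465 to CT, 338/465 to CXR follow-up
N_PATIENTS = 465
N_CT_ROUTED = 127
N_SUBDIAGNOSTIC = 7

#: equipment table: price, 10-year straight line, maintenance, practical capacity.
#: The DTS depreciation figure is the accounting system's, carried as an
#: override (it does not equal price / 10).
ASSETS: dict[str, AssetSpec] = {
    "DTS": AssetSpec(
        price=money(30_000),
        useful_life_years=10,
        annual_maintenance=money(10_000),
        capacity_hours_per_year=2_600.0,
        annual_depreciation_override=money(3_750),
    ),
    "CT": AssetSpec(
        price=money(1_242_000),
        useful_life_years=10,
        annual_maintenance=money(105_996),
        capacity_hours_per_year=3_030.0,
        annual_depreciation_override=money(155_250),
    ),
}

#: mean unit occupation time (minutes) per modality
OCCUPATION_MIN: dict[str, float] = {
    "CXR": 6.0,
    "DTS": 13.0,
    "CT_unenhanced": 15.0,
    "CT_contrast": 19.0,
}

#: unit full costs (EUR): contrast, medical, radiographer, nursing, depreciation
UNIT_COSTS: dict[str, UnitCost] = {
    "CXR": UnitCost(
        medical=money("11,65"), radiographer=money("3,05"), depreciation=money("0,45")
    ),
    "DTS": UnitCost(
        medical=money("23,04"), radiographer=money("7,92"), depreciation=money("10,59")
    ),
    "CT_unenhanced": UnitCost(
        medical=money("31,95"),
        radiographer=money("7,07"),
        nursing=money("6,98"),
        depreciation=money("19,35"),
    ),
    "CT_contrast": UnitCost(
        contrast=money("25,83"),
        medical=money("46,24"),
        radiographer=money("11,19"),
        nursing=money("11,05"),
        depreciation=money("19,35"),
    ),
}

#: annual utilisation, year before implementation: 811 suspected-lesion
#: patients produced 271 chest CTs
UTILISATION_BEFORE = Utilisation(counts={"CT": 271})

#: annual utilisation, first year after implementation
UTILISATION_AFTER = Utilisation(counts={"CXR": 91, "DTS": 130, "CT": 39}, subdiagnostic_dts=7)

#: regional reimbursement for a DTS examination; DTS variable cost is nil
BREAKEVEN = BreakEvenInput(
    fixed_cost=money(30_000),
    reimbursement_rate=money("62,7"),
    variable_unit_cost=money(0),
)


def unit_costs_for_variant(variant: CtVariant) -> dict[str, UnitCost]:
    """Unit-cost table keyed by scenario modality names for one CT variant."""
    key = "CT_unenhanced" if variant is CtVariant.UNENHANCED else "CT_contrast"
    return {"CXR": UNIT_COSTS["CXR"], "DTS": UNIT_COSTS["DTS"], "CT": UNIT_COSTS[key]}


def scenario_before(variant: CtVariant = CtVariant.UNENHANCED) -> Scenario:
    return Scenario(
        label="pre-DTS (CXR + CT only)",
        utilisation=UTILISATION_BEFORE,
        unit_costs=unit_costs_for_variant(variant),
        ct_variant=variant,
    )


def scenario_after(variant: CtVariant = CtVariant.UNENHANCED) -> Scenario:
    return Scenario(
        label="post-DTS (CXR + DTS, CT on triage)",
        utilisation=UTILISATION_AFTER,
        unit_costs=unit_costs_for_variant(variant),
        ct_variant=variant,
    )


def reference_tables() -> dict:
    """All reference aggregates in one mapping (worked-example fixture)."""
    return {
        "category_counts": dict(CATEGORY_COUNTS),
        "confusion": dict(CONFUSION),
        "interpretation_time_s": dict(INTERPRETATION_TIME_S),
        "n_patients": N_PATIENTS,
        "n_ct_routed": N_CT_ROUTED,
        "n_subdiagnostic": N_SUBDIAGNOSTIC,
        "assets": dict(ASSETS),
        "occupation_min": dict(OCCUPATION_MIN),
        "unit_costs": dict(UNIT_COSTS),
        "utilisation_before": UTILISATION_BEFORE,
        "utilisation_after": UTILISATION_AFTER,
        "breakeven": BREAKEVEN,
    }
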