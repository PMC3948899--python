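"""Readers and writers for reading-record tables, truth tables and cost config.

CSV files are comma-separated UTF-8 with a header row.  Monetary values in
cost configs may use either a decimal point or the decimal-comma print
convention; both are normalised to exact cents on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from ._money import money
from .records import (
    LesionCategory,
    Modality,
    ReadingRecord,
    TruthLabel,
    validate_readings,
)

READINGS_COLUMNS = ["patient_id", "modality", "reader_id", "score", "interpretation_time_s"]
TRUTH_COLUMNS = ["patient_id", "category", "size_cm"]


def read_readings(path: Union[str, Path], delimiter: str = ",") -> list[ReadingRecord]:
    """Load and validate a readings table.

    Raises ``ValueError`` naming the offending row for scores outside 1-5 and
    for duplicate (patient, modality, reader) triples.  Row order is
    preserved.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str, "reader_id": str})
    missing = {"patient_id", "modality", "reader_id", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            score = int(row.score)
            time = getattr(row, "interpretation_time_s", None)
            if time is not None and pd.isna(time):
                time = None
            records.append(
                ReadingRecord(
                    patient_id=str(row.patient_id),
                    modality=Modality(str(row.modality).upper()),
                    reader_id=str(row.reader_id),
                    score=score,
                    interpretation_time_s=float(time) if time is not None else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return validate_readings(records)


def write_readings(records: list[ReadingRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "modality": r.modality.value,
                "reader_id": r.reader_id,
                "score": r.score,
                "interpretation_time_s": r.interpretation_time_s,
            }
            for r in records
        ],
        columns=READINGS_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_truth(path: Union[str, Path], delimiter: str = ",") -> list[TruthLabel]:
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    missing = {"patient_id", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    labels = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            size = getattr(row, "size_cm", None)
            if size is not None and pd.isna(size):
                size = None
            labels.append(
                TruthLabel(
                    patient_id=str(row.patient_id),
                    category=LesionCategory(str(row.category)),
                    size_cm=float(size) if size is not None else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    seen: set[str] = set()
    for label in labels:
        if label.patient_id in seen:
            raise ValueError(f"{path}: duplicate truth label for patient {label.patient_id}")
        seen.add(label.patient_id)
    return labels


def write_truth(labels: list[TruthLabel], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {"patient_id": t.patient_id, "category": t.category.value, "size_cm": t.size_cm}
            for t in labels
        ],
        columns=TRUTH_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_consensus(path: Union[str, Path]) -> dict[str, int]:
    """Load a consensus-score table (columns patient_id, score)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if not {"patient_id", "score"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns patient_id, score")
    out: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        score = int(row.score)
        if score not in range(1, 6):
            raise ValueError(f"{path}: row {i + 2}: score must be in 1..5, got {score}")
        if row.patient_id in out:
            raise ValueError(f"{path}: duplicate consensus score for patient {row.patient_id}")
        out[str(row.patient_id)] = score
    return out


@dataclass(frozen=True)
class AssetSpec:
    """Capital-equipment description for straight-line depreciation."""

    price: Decimal
    useful_life_years: int
    annual_maintenance: Decimal = Decimal("0.00")
    capacity_hours_per_year: float = 0.0
    annual_depreciation_override: Optional[Decimal] = None

    def __post_init__(self) -> None:
        if self.useful_life_years <= 0:
            raise ValueError("useful_life_years must be positive")
        if self.price < 0 or self.annual_maintenance < 0:
            raise ValueError("currency amounts must be nonnegative")


@dataclass
class CostConfig:
    """Structured cost inputs.

    ``unit_cost_components`` carries per-modality component costs directly
    (authoritative mode); ``personnel_rates`` / ``occupation_time_min`` /
    ``asset_specs`` support building them from rates and lead times (model
    mode).  ``reimbursement`` and ``variable_costs`` feed the break-even
    analysis.
    """

    unit_cost_components: dict[str, dict[str, Decimal]] = field(default_factory=dict)
    personnel_rates: dict[str, Decimal] = field(default_factory=dict)
    occupation_time_min: dict[str, float] = field(default_factory=dict)
    asset_specs: dict[str, AssetSpec] = field(default_factory=dict)
    reimbursement: dict[str, Decimal] = field(default_factory=dict)
    variable_costs: dict[str, Decimal] = field(default_factory=dict)
    utilisation: dict[str, dict[str, int]] = field(default_factory=dict)
    breakeven: dict[str, Decimal] = field(default_factory=dict)


def _money_map(d: dict) -> dict[str, Decimal]:
    return {str(k): money(v) for k, v in d.items()}


def load_cost_config(path: Union[str, Path]) -> CostConfig:
    """Load a YAML or JSON cost configuration."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: cost config must be a mapping")

    assets = {}
    for name, spec in (raw.get("asset_specs") or {}).items():
        assets[name] = AssetSpec(
            price=money(spec["price"]),
            useful_life_years=int(spec["useful_life_years"]),
            annual_maintenance=money(spec.get("annual_maintenance", 0)),
            capacity_hours_per_year=float(spec.get("capacity_hours_per_year", 0.0)),
            annual_depreciation_override=(
                money(spec["annual_depreciation_override"])
                if "annual_depreciation_override" in spec
                else None
            ),
        )

    return CostConfig(
        unit_cost_components={
            str(mod): _money_map(components)
            for mod, components in (raw.get("unit_costs") or {}).items()
        },
        personnel_rates=_money_map(raw.get("personnel_rates") or {}),
        occupation_time_min={
            str(k): float(v) for k, v in (raw.get("occupation_time_min") or {}).items()
        },
        asset_specs=assets,
        reimbursement=_money_map(raw.get("reimbursement") or {}),
        variable_costs=_money_map(raw.get("variable_costs") or {}),
        utilisation={
            str(k): {str(m): int(n) for m, n in v.items()}
            for k, v in (raw.get("utilisation") or {}).items()
        },
        breakeven=_money_map(raw.get("breakeven") or {}),
    )
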