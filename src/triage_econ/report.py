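"""Full-pipeline orchestration: accuracy -> pathway -> costing, with manifests.

``run_full`` assembles the whole report in memory first and only then writes
files, so a failing stage leaves no partial outputs.  Reports are plain JSON
(Decimals rendered at cent precision) plus a CSV of triage decisions; every
report embeds a manifest (command line, config hash, seeds, input digests,
package version, timestamp) so a run can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from decimal import Decimal
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__, accuracy, costing, pathway, reference
from .cohort import Cohort, CohortSpec, generate
from .costing import CtVariant
from .io import CostConfig
from .records import Modality, ReadingRecord, TruthLabel, truth_map

logger = logging.getLogger("triage_econ")


@dataclass
class RunManifest:
    command_line: str
    config_hash: Optional[str]
    seeds: list[int]
    input_digests: dict[str, str]
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def to_dict(self) -> dict:
        return asdict(self)


def file_digest(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, Decimal):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "value") and not isinstance(obj, type):  # Enum
        return obj.value
    return obj


def accuracy_report(
    records: Sequence[ReadingRecord],
    truth_labels: Sequence[TruthLabel],
    reader_id: str,
    modality: str,
    score3_policy: accuracy.Score3Policy = accuracy.Score3Policy.PENALISE,
    ci_method: str = "normal",
) -> dict:
    """Confusion counts, exact metrics and nonparametric AUC for one reading set."""
    truth = truth_map(truth_labels)
    mod = Modality(modality)
    subset = [r for r in records if r.reader_id == reader_id and r.modality is mod]
    if not subset:
        raise ValueError(f"no readings for reader {reader_id!r}, modality {modality!r}")
    counts = accuracy.classify(subset, truth, policy=score3_policy)
    m = accuracy.metrics(counts)
    dist = accuracy.score_distribution(subset, truth)
    auc, se = accuracy.auc_nonparametric(dist)
    lo, hi = accuracy.auc_confidence_interval(auc, se, method=ci_method)
    return {
        "reader": reader_id,
        "modality": mod.value,
        "score3_policy": score3_policy.value,
        "confusion": {"tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn},
        "metrics_percent": m.as_percent(),
        "metrics_exact": {
            name: (None if v is None else [v.numerator, v.denominator])
            for name, v in (
                ("sensitivity", m.sensitivity),
                ("specificity", m.specificity),
                ("accuracy", m.accuracy),
                ("ppv", m.ppv),
                ("npv", m.npv),
            )
        },
        "auc": round(auc, 3),
        "auc_ci": [round(lo, 3), round(hi, 3)],
    }


def _agreement_section(cohort: Cohort) -> dict:
    out = {}
    for modality in ("CXR", "DTS"):
        s1 = cohort.scores("r1", modality)
        s2 = cohort.scores("r2", modality)
        pids = sorted(s1)
        try:
            k = accuracy.weighted_kappa([s1[p] for p in pids], [s2[p] for p in pids])
            out[modality] = {"kappa": round(k.kappa, 3), "band": k.band, "weights": k.weights}
        except ValueError as exc:
            out[modality] = {"kappa": None, "band": None, "error": str(exc)}
    t1 = cohort.times("r1", "CXR")
    t2 = cohort.times("r1", "DTS")
    pids = sorted(set(t1) & set(t2))
    wil = accuracy.compare_times([t1[p] for p in pids], [t2[p] for p in pids])
    out["interpretation_time_cxr_vs_dts"] = {
        "statistic": wil.statistic,
        "pvalue": wil.pvalue,
        "method": wil.method,
    }
    return out


def cost_section(
    config: Optional[CostConfig] = None, ct_variant: CtVariant = CtVariant.UNENHANCED
) -> dict:
    """Scenario costs, differential saving and break-even.

    Falls back to the reference cost tables for anything the config omits.
    """
    if config is not None and config.unit_cost_components:
        key = "ct_unenhanced" if ct_variant is CtVariant.UNENHANCED else "ct_contrast"
        name_map = {"cxr": "CXR", "dts": "DTS", key: "CT"}
        unit_costs = {
            name_map[k]: costing.UnitCost.from_mapping(v)
            for k, v in config.unit_cost_components.items()
            if k in name_map
        }
    else:
        unit_costs = reference.unit_costs_for_variant(ct_variant)

    if config is not None and config.utilisation:
        def _util(block: dict[str, int]) -> pathway.Utilisation:
            counts = {k.upper(): v for k, v in block.items() if k != "dts_subdiagnostic"}
            return pathway.Utilisation(
                counts=counts, subdiagnostic_dts=block.get("dts_subdiagnostic", 0)
            )

        util_before = _util(config.utilisation["before"])
        util_after = _util(config.utilisation["after"])
    else:
        util_before = reference.UTILISATION_BEFORE
        util_after = reference.UTILISATION_AFTER

    before = costing.Scenario("before", util_before, unit_costs, ct_variant)
    after = costing.Scenario("after", util_after, unit_costs, ct_variant)

    if config is not None and config.breakeven:
        be_input = costing.BreakEvenInput(
            fixed_cost=config.breakeven["fixed_cost"],
            reimbursement_rate=config.breakeven["reimbursement"],
            variable_unit_cost=config.breakeven.get("variable_unit_cost", Decimal(0)),
        )
    else:
        be_input = reference.BREAKEVEN

    cost_before = costing.scenario_cost(before)
    cost_after = costing.scenario_cost(after)
    return {
        "ct_variant": ct_variant.value,
        "unit_cost_totals": {k: v.total for k, v in unit_costs.items()},
        "annual_cost_before": cost_before,
        "annual_cost_after": cost_after,
        "annual_saving": cost_before - cost_after,
        "break_even_examinations": costing.break_even(be_input),
    }


def run_full(
    out_dir: Union[str, Path],
    cohort: Optional[Cohort] = None,
    spec: Optional[CohortSpec] = None,
    config: Optional[CostConfig] = None,
    ct_variant: CtVariant = CtVariant.UNENHANCED,
    manifest: Optional[RunManifest] = None,
    quiet: bool = False,
) -> dict:
    """Run accuracy -> pathway -> costing and write report.json + decisions.csv.

    Provide either a *cohort* (real or pre-generated) or a *spec* to simulate
    one.  Returns the report dict.
    """
    if not quiet:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    if cohort is None:
        if spec is None:
            raise ValueError("run_full needs a cohort or a CohortSpec to simulate one")
        logger.info("simulating cohort: n=%d seed=%d", spec.n, spec.seed)
        cohort = generate(spec)

    stage = "accuracy"
    try:
        acc = {
            f"{reader}_{modality}": accuracy_report(
                cohort.readings, cohort.truth, reader, modality
            )
            for reader in ("r1", "r2")
            for modality in ("CXR", "DTS")
        }
        agreement = _agreement_section(cohort)

        stage = "pathway"
        decisions = pathway.triage(cohort.consensus, subdiagnostic=cohort.subdiagnostic_ids)
        frac = pathway.ct_fraction(decisions)
        util = pathway.tally_utilisation(decisions)

        stage = "costing"
        costs = cost_section(config, ct_variant)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report = {
        "manifest": (manifest or RunManifest("run_full", None, [], {})).to_dict(),
        "accuracy": acc,
        "agreement": agreement,
        "pathway": {
            "n_patients": len([d for d in decisions if not d.subdiagnostic]),
            "ct_fraction": [frac.numerator, frac.denominator],
            "ct_fraction_percent": round(100 * frac.numerator / frac.denominator),
            "utilisation": {"counts": util.counts, "subdiagnostic_dts": util.subdiagnostic_dts},
        },
        "costs": costs,
    }

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "route": d.route.value,
                "deciding_score": d.deciding_score,
                "subdiagnostic": d.subdiagnostic,
            }
            for d in decisions
        ]
    ).to_csv(out_dir / "decisions.csv", index=False)
    logger.info("report written to %s", out_dir / "report.json")
    return report
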