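"""Score-driven triage pathway and modality-utilisation accounting.

After tomosynthesis, each patient's consensus confidence score routes them:
scores 1-2 (benign / pseudolesion) to chest-radiography follow-up at about
six months, scores 3-5 (indeterminate or suspected pulmonary lesion) to CT
within one week.  Subdiagnostic tomosynthesis examinations (the patient could
not hold the upright position or suspend respiration) produce no score; they
still consume an examination and are carried as a separate utilisation line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Mapping, Optional, Sequence


class Route(str, Enum):
    CXR_FOLLOWUP = "cxr_followup"
    CT_WITHIN_1_WEEK = "ct_within_1_week"


@dataclass(frozen=True)
class TriageDecision:
    patient_id: str
    route: Route
    deciding_score: Optional[int]  # None only for subdiagnostic examinations
    subdiagnostic: bool = False


@dataclass
class Utilisation:
    """Examination counts per modality for a costing period."""

    counts: dict[str, int] = field(default_factory=dict)
    subdiagnostic_dts: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()) or self.subdiagnostic_dts < 0:
            raise ValueError("utilisation counts must be nonnegative")


def route_for_score(score: int) -> Route:
    if score not in range(1, 6):
        raise ValueError(f"score must be in 1..5, got {score}")
    return Route.CXR_FOLLOWUP if score <= 2 else Route.CT_WITHIN_1_WEEK


def triage(
    consensus_scores: Mapping[str, Optional[int]],
    subdiagnostic: Sequence[str] = (),
    subdiagnostic_route: Route = Route.CT_WITHIN_1_WEEK,
) -> list[TriageDecision]:
    """Route every patient by consensus score.

    *subdiagnostic* patients carry no score; unresolved suspicion cannot be
    dismissed, so they default to the CT route (configurable).  A patient
    with neither a score nor a subdiagnostic flag is an error.
    """
    sub = set(subdiagnostic)
    decisions = []
    for pid, score in consensus_scores.items():
        if pid in sub:
            decisions.append(
                TriageDecision(pid, subdiagnostic_route, None, subdiagnostic=True)
            )
        elif score is None:
            raise ValueError(f"patient {pid} has no consensus score and is not subdiagnostic")
        else:
            decisions.append(TriageDecision(pid, route_for_score(score), score))
    for pid in sub - set(consensus_scores):
        decisions.append(TriageDecision(pid, subdiagnostic_route, None, subdiagnostic=True))
    return decisions


def ct_fraction(decisions: Sequence[TriageDecision]) -> Fraction:
    """Exact proportion of patients routed to CT."""
    if not decisions:
        raise ValueError("ct_fraction of an empty decision list is undefined")
    n_ct = sum(d.route is Route.CT_WITHIN_1_WEEK for d in decisions)
    return Fraction(n_ct, len(decisions))


def tally_utilisation(
    decisions: Sequence[TriageDecision],
    count_followup_cxr: bool = True,
    count_subdiagnostic_ct: bool = False,
) -> Utilisation:
    """Examination counts implied by a set of triage decisions.

    Every patient consumed one tomosynthesis examination.  CT counts the
    scored patients routed to CT; follow-up chest radiographs (one per
    patient routed to follow-up) are counted when *count_followup_cxr* is
    true.  Subdiagnostic examinations are booked on their own line; their
    onward CT is excluded by default, matching the accounting in which a
    subdiagnostic examination contributes its cost but no diagnostic yield.
    """
    scored = [d for d in decisions if not d.subdiagnostic]
    n_sub = sum(d.subdiagnostic for d in decisions)
    n_ct = sum(d.route is Route.CT_WITHIN_1_WEEK for d in scored)
    if count_subdiagnostic_ct:
        n_ct += sum(
            d.route is Route.CT_WITHIN_1_WEEK for d in decisions if d.subdiagnostic
        )
    n_followup = sum(d.route is Route.CXR_FOLLOWUP for d in scored)
    counts = {"DTS": len(scored), "CT": n_ct}
    if count_followup_cxr:
        counts["CXR"] = n_followup
    return Utilisation(counts=counts, subdiagnostic_dts=n_sub)
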