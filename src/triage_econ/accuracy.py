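"""Reader-performance statistics for ordinal confidence-score reading studies.

Scores run 1-5: 1-2 call the finding benign/extra-pulmonary/pseudolesion,
3 is indeterminate, 4-5 call a pulmonary lesion.  Under the study's
classification rule an indeterminate reading is always an error: it counts as
a false positive on a truth-negative patient (the patient is sent on to CT
without need) and as a false negative on a truth-positive patient.

The module wraps the field-standard implementations of the paired tests
(McNemar, Yates chi-square, Wilcoxon signed-rank, weighted kappa) and authors
the nonparametric AUC with its Hanley-McNeil standard error and the
correlated-AUC comparison, which no installed package provides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .records import Modality, ReadingRecord

__all__ = [
    "Score3Policy",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "classify",
    "score_distribution",
    "metrics",
    "auc_nonparametric",
    "auc_confidence_interval",
    "rating_correlation",
    "compare_auc_correlated",
    "mcnemar",
    "chi2_yates",
    "weighted_kappa",
    "kappa_band",
    "compare_times",
    "merge_consensus",
]


class Score3Policy(str, Enum):
    """How an indeterminate (score 3) reading enters the confusion counts."""

    PENALISE = "penalise"  # FP on negatives, FN on positives (study rule)
    EXCLUDE = "exclude"  # indeterminate readings dropped
    FAVOUR = "favour"  # TP on positives, TN on negatives


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def classify(
    records: Iterable[ReadingRecord],
    truth: Mapping[str, bool],
    policy: Score3Policy = Score3Policy.PENALISE,
) -> ConfusionCounts:
    """Tally confusion counts for one reader and one modality.

    Scores 4-5 call the lesion positive, 1-2 call it negative; score 3 is
    handled per *policy* (default: counted as an error against the truth).
    Every record must have a truth label.
    """
    tp = tn = fp = fn = 0
    for rec in records:
        if rec.patient_id not in truth:
            raise ValueError(f"no truth label for patient {rec.patient_id}")
        positive = truth[rec.patient_id]
        if rec.score >= 4:
            called = True
        elif rec.score <= 2:
            called = False
        else:  # indeterminate
            if policy is Score3Policy.EXCLUDE:
                continue
            called = positive if policy is Score3Policy.FAVOUR else not positive
        if positive:
            tp, fn = (tp + 1, fn) if called else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if not called else (tn, fp + 1)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def score_distribution(
    records: Iterable[ReadingRecord], truth: Mapping[str, bool]
) -> np.ndarray:
    """2x5 count table (rows: truth negative, truth positive; cols: score 1..5)."""
    counts = np.zeros((2, 5), dtype=np.int64)
    for rec in records:
        if rec.patient_id not in truth:
            raise ValueError(f"no truth label for patient {rec.patient_id}")
        counts[int(truth[rec.patient_id]), rec.score - 1] += 1
    return counts


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Exact-fraction sensitivity/specificity/accuracy/PPV/NPV.

    A metric whose denominator is empty is ``None`` (undefined), never zero.
    """

    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    accuracy: Optional[Fraction]
    ppv: Optional[Fraction]
    npv: Optional[Fraction]

    def as_percent(self) -> dict[str, Optional[int]]:
        """Round-half-up integer percentages (report convention)."""
        out = {}
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            value = getattr(self, name)
            out[name] = None if value is None else int((200 * value + 1) // 2)
        return out


def _ratio(num: int, den: int) -> Optional[Fraction]:
    return None if den == 0 else Fraction(num, den)


def metrics(c: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, PPV, NPV."""
    return DiagnosticMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def auc_nonparametric(dist: np.ndarray) -> tuple[float, float]:
    """Nonparametric (Mann-Whitney) AUC over an ordinal 2x5 score table.

    A concordant (positive scored above negative) pair counts 1, a tie counts
    1/2.  The standard error is the Hanley-McNeil formula with
    Q1 = A/(2-A) and Q2 = 2A^2/(1+A).

    Parameters
    ----------
    dist
        Counts with rows (truth negative, truth positive) and columns for
        scores 1..5 (any number of ordered categories is accepted).

    Returns
    -------
    (auc, se)
    """
    dist = np.asarray(dist, dtype=np.float64)
    neg, pos = dist[0], dist[1]
    n_neg, n_pos = neg.sum(), pos.sum()
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both truth classes must be non-empty to compute an AUC")
    # cumulative negatives strictly below each score, plus half the ties
    cum_below = np.concatenate(([0.0], np.cumsum(neg)[:-1]))
    wins = float(np.sum(pos * (cum_below + 0.5 * neg)))
    auc = wins / (n_neg * n_pos)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1.0) * (q1 - auc * auc)
        + (n_neg - 1.0) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return auc, math.sqrt(max(var, 0.0))


def auc_confidence_interval(
    auc: float, se: float, level: float = 0.95, method: str = "normal"
) -> tuple[float, float]:
    """Normal (default) or logit-transformed interval, clipped to [0, 1]."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "normal":
        return max(0.0, auc - z * se), min(1.0, auc + z * se)
    if method == "logit":
        if not 0.0 < auc < 1.0:
            return (auc, auc)
        logit = math.log(auc / (1.0 - auc))
        se_logit = se / (auc * (1.0 - auc))
        lo, hi = logit - z * se_logit, logit + z * se_logit
        return 1.0 / (1.0 + math.exp(-lo)), 1.0 / (1.0 + math.exp(-hi))
    raise ValueError(f"unknown CI method {method!r}")


def rating_correlation(
    scores_a: Sequence[int],
    scores_b: Sequence[int],
    positive: Sequence[bool],
) -> float:
    """Average within-truth-class correlation of paired ratings.

    Used as the between-area correlation r in the correlated-AUC z test: the
    Pearson correlation of the two modalities' scores is computed separately
    among positives and among negatives and the two are averaged.  A class
    with no score variation on either modality contributes zero correlation.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    rs = []
    for mask in (positive, ~positive):
        a, b = scores_a[mask], scores_b[mask]
        if len(a) < 2 or a.std() == 0.0 or b.std() == 0.0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(rs))


@dataclass(frozen=True)
class AucComparison:
    z: float
    pvalue: float
    r: float


def compare_auc_correlated(
    auc1: float, auc2: float, se1: float, se2: float, r: float = 0.0
) -> AucComparison:
    """Paired z test for two correlated AUCs.

    z = (A1 - A2) / sqrt(se1^2 + se2^2 - 2 r se1 se2); two-sided normal p.
    *r* is the between-area correlation induced by reading the same cases
    (see :func:`rating_correlation`); r = 0 recovers the independent-samples
    formula.
    """
    var = se1 * se1 + se2 * se2 - 2.0 * r * se1 * se2
    if var <= 0.0:
        raise ValueError(
            "degenerate pairing: variance of the AUC difference is not positive"
        )
    if auc1 == auc2:
        return AucComparison(z=0.0, pvalue=1.0, r=r)
    z = (auc1 - auc2) / math.sqrt(var)
    return AucComparison(z=z, pvalue=2.0 * stats.norm.sf(abs(z)), r=r)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    pvalue: float
    method: str
    flagged: bool = False


def mcnemar(
    correct_a: Sequence[bool],
    correct_b: Sequence[bool],
    exact: Optional[bool] = None,
) -> PairedTestResult:
    """McNemar's test on paired per-patient correctness of two modalities.

    The continuity-corrected chi-square is used by default; when the
    discordant total b + c is below 25 (or ``exact=True``) the exact binomial
    version is used instead.  Zero discordant pairs give p = 1, flagged.
    """
    correct_a = np.asarray(correct_a, dtype=bool)
    correct_b = np.asarray(correct_b, dtype=bool)
    if correct_a.shape != correct_b.shape:
        raise ValueError("paired correctness vectors must have equal length")
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    return mcnemar_from_counts(b, c, exact=exact)


def mcnemar_from_counts(b: int, c: int, exact: Optional[bool] = None) -> PairedTestResult:
    if b + c == 0:
        return PairedTestResult(0.0, 1.0, "mcnemar-degenerate", flagged=True)
    if exact is None:
        exact = (b + c) < 25
    table = [[0, b], [c, 0]]  # concordant cells do not enter the test
    res = _sm_mcnemar(table, exact=exact, correction=True)
    method = "mcnemar-exact" if exact else "mcnemar-chi2-corrected"
    return PairedTestResult(float(res.statistic), float(res.pvalue), method)


def chi2_yates(table: Sequence[Sequence[int]]) -> PairedTestResult:
    """Yates-corrected chi-square (1 df) on a 2x2 correct/incorrect table.

    Rows are modalities, columns (correct, incorrect).
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("chi2_yates expects a 2x2 table")
    if arr.sum() == 0 or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("a margin of the 2x2 table is empty: expected counts are zero")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return PairedTestResult(float(stat), float(p), "chi2-yates")


_KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (float("inf"), "very good"),
)


def kappa_band(kappa: float) -> str:
    """Agreement grade: poor < 0.20 <= fair < 0.40 <= moderate < 0.60 <= good
    < 0.80 <= very good (left-closed intervals)."""
    for upper, band in _KAPPA_BANDS:
        if kappa < upper:
            return band
    return "very good"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    band: str
    weights: str


def weighted_kappa(
    scores_a: Sequence[int],
    scores_b: Sequence[int],
    weights: str = "linear",
) -> KappaResult:
    """Weighted kappa between two readers' 1-5 scores on the same patients.

    ``weights`` is "linear" (default for a 5-point ordinal scale) or
    "quadratic".  Undefined (both readers constant) raises ``ValueError``.
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    a = np.asarray(scores_a, dtype=np.int64)
    b = np.asarray(scores_b, dtype=np.int64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired scores of equal length")
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        raise ValueError("kappa undefined: neither reader shows any score variation")
    table = np.zeros((5, 5), dtype=np.int64)
    np.add.at(table, (a - 1, b - 1), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = _sm_cohens_kappa(table, wt="linear" if weights == "linear" else "quadratic")
    kappa = float(res.kappa)
    return KappaResult(kappa=kappa, band=kappa_band(kappa), weights=weights)


def compare_times(
    times_a: Sequence[Optional[float]], times_b: Sequence[Optional[float]]
) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired interpretation times.

    Pairs with a missing time on either side are excluded; zero differences
    are dropped (Wilcoxon convention).  All-zero differences give p = 1,
    flagged.
    """
    a = np.asarray([np.nan if t is None else t for t in times_a], dtype=float)
    b = np.asarray([np.nan if t is None else t for t in times_b], dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired time vectors must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    diffs = a[mask] - b[mask]
    if diffs.size == 0:
        raise ValueError("no complete pairs of interpretation times")
    if np.all(diffs == 0.0):
        return PairedTestResult(0.0, 1.0, "wilcoxon-degenerate", flagged=True)
    stat, p = stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")
    return PairedTestResult(float(stat), float(p), "wilcoxon-signed-rank")


def _route_to_ct(score: int) -> bool:
    return score >= 3


def merge_consensus(
    scores_reader1: Mapping[str, int],
    scores_reader2: Mapping[str, int],
    supplied: Optional[Mapping[str, int]] = None,
) -> dict[str, int]:
    """Resolve the two readers' scores into one consensus score per patient.

    Where the readers' triage decisions (scores 1-2 vs 3-5) agree, reader 1's
    score is kept.  Where they differ, a supplied consensus score wins; absent
    one, the higher (more suspicious) score wins — a conservative rule that
    never dismisses a suspicion one reader raised.
    """
    if set(scores_reader1) != set(scores_reader2):
        raise ValueError("readers must score the same patients")
    supplied = supplied or {}
    out: dict[str, int] = {}
    for pid, s1 in scores_reader1.items():
        s2 = scores_reader2[pid]
        if _route_to_ct(s1) == _route_to_ct(s2):
            out[pid] = s1
        elif pid in supplied:
            out[pid] = supplied[pid]
        else:
            out[pid] = max(s1, s2)
    return out
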