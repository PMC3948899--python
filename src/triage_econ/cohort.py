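"""Synthetic cohort generator emulating a two-reader, two-modality study.

Generates reference-standard labels, paired ordinal confidence scores for two
readers on chest radiography (CXR) and digital tomosynthesis (DTS), lognormal
interpretation times, consensus scores and a subdiagnostic-examination count,
with the statistical structure of the reference cohort: prevalence 144/465 of
CT-deserving pulmonary lesions, modality- and truth-conditional score
distributions calibrated to the aggregate sensitivity/specificity (CXR 24%/10%,
DTS 80%/95%), and a copy-probability reader-agreement model.

Everything is driven by a single integer seed and is reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .accuracy import merge_consensus
from .records import (
    POSITIVE_CATEGORIES,
    LesionCategory,
    Modality,
    ReadingRecord,
    TruthLabel,
)
from . import reference

#: default truth-conditional score distributions, P(score | modality, truth).
#: Calibrated so that P(score>=4 | positive) and P(score<=2 | negative) equal
#: the reference aggregate sensitivity and specificity; the remaining mass is
#: spread with heavy indeterminate (score 3) use on CXR, light on DTS.
DEFAULT_SCORE_MODEL: dict[tuple[str, bool], tuple[float, ...]] = {
    ("CXR", True): (0.01, 0.22, 0.53, 0.20, 0.04),   # sensitivity 0.24
    ("CXR", False): (0.005, 0.095, 0.80, 0.09, 0.01),  # specificity 0.10
    ("DTS", True): (0.03, 0.07, 0.10, 0.30, 0.50),   # sensitivity 0.80
    ("DTS", False): (0.70, 0.25, 0.03, 0.015, 0.005),  # specificity 0.95
}

#: probability that reader 2 copies reader 1's score (else independent redraw).
#: Under this mixture the expected linear weighted kappa has the closed form
#: kappa = 1 - (1 - a) * E|X-Y|_within / E|X-Y|_marginal; these values solve it
#: for the reference inter-reader agreement (kappa 0.40 on CXR, 0.89 on DTS)
#: given the default score model and prevalence
DEFAULT_READER_AGREEMENT: dict[str, float] = {"CXR": 0.3816, "DTS": 0.7572}

#: 7 subdiagnostic DTS examinations among 472 attempted in the reference cohort
DEFAULT_SUBDIAGNOSTIC_RATE = 7.0 / 472.0


def _default_category_mix() -> dict[LesionCategory, float]:
    total = sum(reference.CATEGORY_COUNTS.values())
    return {cat: n / total for cat, n in reference.CATEGORY_COUNTS.items()}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``category_mix`` defaults to the reference lesion-category proportions
    (prevalence 144/465 under the truth mapping).  ``reader_agreement`` is a
    copy probability, scalar or per modality.  ``time_model`` holds per-
    modality (mean, SD) of interpretation time in seconds, realised as a
    moment-matched lognormal truncated at 1 s.
    """

    n: int = 465
    category_mix: Mapping[LesionCategory, float] = field(
        default_factory=_default_category_mix
    )
    score_model: Mapping[tuple[str, bool], Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MODEL)
    )
    reader_agreement: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_READER_AGREEMENT)
    )
    time_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(reference.INTERPRETATION_TIME_S)
    )
    subdiagnostic_rate: float = DEFAULT_SUBDIAGNOSTIC_RATE
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not np.isclose(sum(self.category_mix.values()), 1.0, atol=1e-9):
            raise ValueError("category_mix must sum to 1")
        for key, probs in self.score_model.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (5,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"score_model[{key}] must be 5 nonnegative probs summing to 1")
        if not 0.0 <= self.subdiagnostic_rate < 1.0:
            raise ValueError("subdiagnostic_rate must be in [0, 1)")

    def agreement_for(self, modality: str) -> float:
        a = self.reader_agreement
        p = a if isinstance(a, (int, float)) else a[modality]
        if not 0.0 <= p <= 1.0:
            raise ValueError("reader_agreement must be in [0, 1]")
        return float(p)


@dataclass
class Cohort:
    """A generated cohort: labels, four reading sets, consensus, subdiagnostics."""

    truth: list[TruthLabel]
    readings: list[ReadingRecord]
    consensus: dict[str, int]
    subdiagnostic_ids: list[str]

    def scores(self, reader_id: str, modality: str) -> dict[str, int]:
        mod = Modality(modality)
        return {
            r.patient_id: r.score
            for r in self.readings
            if r.reader_id == reader_id and r.modality is mod
        }

    def times(self, reader_id: str, modality: str) -> dict[str, Optional[float]]:
        mod = Modality(modality)
        return {
            r.patient_id: r.interpretation_time_s
            for r in self.readings
            if r.reader_id == reader_id and r.modality is mod
        }


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with given mean and SD."""
    if mean <= 0:
        raise ValueError("time mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_times(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    mu, sigma = _lognormal_params(mean, sd)
    return np.maximum(rng.lognormal(mu, sigma, size=n), 1.0)


def generate(spec: CohortSpec) -> Cohort:
    """Generate a synthetic cohort from *spec*, reproducibly given its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    width = max(4, len(str(n)))
    ids = [f"p{i:0{width}d}" for i in range(1, n + 1)]

    categories = list(spec.category_mix.keys())
    probs = np.asarray(list(spec.category_mix.values()), dtype=float)
    cat_idx = rng.choice(len(categories), size=n, p=probs / probs.sum())
    positive = np.array(
        [categories[i] in POSITIVE_CATEGORIES for i in cat_idx], dtype=bool
    )

    truth = []
    for pid, i in zip(ids, cat_idx):
        cat = categories[i]
        size_spec = reference.CATEGORY_SIZES.get(cat)
        size = None
        if size_spec is not None:
            size = float(max(rng.normal(size_spec[0], size_spec[1]), 0.1))
        truth.append(TruthLabel(patient_id=pid, category=cat, size_cm=size))

    readings: list[ReadingRecord] = []
    scores_by_reader_mod: dict[tuple[str, str], np.ndarray] = {}
    for modality in ("CXR", "DTS"):
        p_pos = np.asarray(spec.score_model[(modality, True)], dtype=float)
        p_neg = np.asarray(spec.score_model[(modality, False)], dtype=float)
        cdf_pos, cdf_neg = np.cumsum(p_pos), np.cumsum(p_neg)

        def draw_scores(u: np.ndarray) -> np.ndarray:
            s = np.empty(n, dtype=np.int64)
            s[positive] = np.searchsorted(cdf_pos, u[positive], side="right") + 1
            s[~positive] = np.searchsorted(cdf_neg, u[~positive], side="right") + 1
            return np.clip(s, 1, 5)

        s1 = draw_scores(rng.random(n))
        s2_indep = draw_scores(rng.random(n))
        copy = rng.random(n) < spec.agreement_for(modality)
        s2 = np.where(copy, s1, s2_indep)
        scores_by_reader_mod[("r1", modality)] = s1
        scores_by_reader_mod[("r2", modality)] = s2

        mean, sd = spec.time_model[modality]
        for reader, s in (("r1", s1), ("r2", s2)):
            times = _draw_times(rng, n, mean, sd)
            readings.extend(
                ReadingRecord(
                    patient_id=pid,
                    modality=Modality(modality),
                    reader_id=reader,
                    score=int(score),
                    interpretation_time_s=float(t),
                )
                for pid, score, t in zip(ids, s, times)
            )

    consensus = merge_consensus(
        dict(zip(ids, (int(s) for s in scores_by_reader_mod[("r1", "DTS")]))),
        dict(zip(ids, (int(s) for s in scores_by_reader_mod[("r2", "DTS")]))),
    )

    n_sub = int(rng.binomial(n, spec.subdiagnostic_rate))
    subdiagnostic_ids = [f"s{i:0{width}d}" for i in range(1, n_sub + 1)]

    return Cohort(
        truth=truth,
        readings=readings,
        consensus=consensus,
        subdiagnostic_ids=subdiagnostic_ids,
    )
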