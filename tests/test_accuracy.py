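"""Reader-performance statistics against independent oracles.

Each nontrivial operation is checked against a brute-force or closed-form
computation written here, independent of the implementation path.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from triage_econ import accuracy as A
from triage_econ.records import Modality, ReadingRecord

# ---------------------------------------------------------------- oracles


def oracle_classify(score: int, positive: bool) -> str:
    """Per-record confusion cell under the study rule (score 3 is an error)."""
    called_positive = score >= 4
    if positive:
        return "tp" if called_positive and score != 3 else "fn"
    return "tn" if score <= 2 else "fp"


def oracle_auc(table: np.ndarray) -> float:
    """Exhaustive pairwise comparison of all (positive, negative) score pairs."""
    neg, pos = table[0], table[1]
    wins = ties = 0.0
    for i, np_count in enumerate(pos):
        for j, nn_count in enumerate(neg):
            if i > j:
                wins += np_count * nn_count
            elif i == j:
                ties += np_count * nn_count
    return (wins + 0.5 * ties) / (pos.sum() * neg.sum())


def oracle_weighted_kappa(a, b, weights="linear"):
    """Direct observed/expected weighted-disagreement computation."""
    a, b = np.asarray(a), np.asarray(b)
    k = 5
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[x - 1, y - 1] += 1
    obs /= obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    idx = np.arange(k)
    w = np.abs(idx[:, None] - idx[None, :]).astype(float)
    if weights == "quadratic":
        w = w**2
    return 1.0 - (w * obs).sum() / (w * exp).sum()


def oracle_mcnemar_exact(b: int, c: int) -> float:
    """Exact binomial two-sided p on the discordant pairs."""
    n = b + c
    res = stats.binomtest(min(b, c), n, 0.5, alternative="two-sided")
    return res.pvalue


def oracle_chi2_yates(table) -> float:
    """Textbook Yates formula N(|ad - bc| - N/2)^2 / (r1 r2 c1 c2)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    num = n * (max(abs(a * d - b * c) - n / 2.0, 0.0)) ** 2
    return num / ((a + b) * (c + d) * (a + c) * (b + d))


def oracle_wilcoxon_exact(diffs) -> float:
    """Enumerate all sign assignments of the ranked |differences|."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    ws = []
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        ws.append(w)
    ws = np.asarray(ws)
    mean = ranks.sum() / 2.0
    p = np.mean(np.abs(ws - mean) >= abs(w_obs - mean) - 1e-12)
    return float(p)


# ---------------------------------------------------------------- classify


def _records(scores, modality="DTS", reader="r1"):
    return [
        ReadingRecord(f"p{i}", Modality(modality), reader, int(s))
        for i, s in enumerate(scores)
    ]


def test_classify_reproduces_reference_aggregates():
    """116 TP of 144 positives and 308 TN of 321 negatives under the rule."""
    scores, truth = [], {}
    pid = 0
    for score, positive, count in [
        (5, True, 116),      # confident positives on true lesions
        (2, True, 28),       # missed or indeterminate lesions
        (1, False, 308),     # correctly dismissed
        (4, False, 13),      # false alarms
    ]:
        for _ in range(count):
            truth[f"p{pid}"] = positive
            pid += 1
    recs = _records([5] * 116 + [2] * 28 + [1] * 308 + [4] * 13)
    counts = A.classify(recs, truth)
    assert (counts.tp, counts.tn, counts.fp, counts.fn) == (116, 308, 13, 28)
    assert counts.total == 465


def test_all_score_three_is_always_an_error():
    truth = {f"p{i}": i < 10 for i in range(30)}
    counts = A.classify(_records([3] * 30), truth)
    assert (counts.tp, counts.tn, counts.fp, counts.fn) == (0, 0, 20, 10)


def test_classify_matches_per_record_oracle():
    rng = np.random.default_rng(42)
    scores = rng.integers(1, 6, size=50)
    positives = rng.random(50) < 0.3
    truth = {f"p{i}": bool(p) for i, p in enumerate(positives)}
    counts = A.classify(_records(scores), truth)
    expected = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for i, s in enumerate(scores):
        expected[oracle_classify(int(s), bool(positives[i]))] += 1
    assert counts == A.ConfusionCounts(**expected)
    assert counts.total == 50  # conservation


@pytest.mark.parametrize(
    "policy,exp",
    [
        (A.Score3Policy.PENALISE, (0, 0, 1, 1)),
        (A.Score3Policy.FAVOUR, (1, 1, 0, 0)),
        (A.Score3Policy.EXCLUDE, (0, 0, 0, 0)),
    ],
)
def test_score3_policy_variants(policy, exp):
    truth = {"p0": True, "p1": False}
    counts = A.classify(_records([3, 3]), truth, policy=policy)
    assert (counts.tp, counts.tn, counts.fp, counts.fn) == exp


def test_classify_requires_truth():
    with pytest.raises(ValueError, match="no truth"):
        A.classify(_records([4]), {})


# ---------------------------------------------------------------- metrics


def test_metrics_exact_fractions():
    m = A.metrics(A.ConfusionCounts(tp=116, tn=308, fp=13, fn=28))
    assert m.sensitivity == Fraction(116, 144)
    assert m.specificity == Fraction(308, 321)
    assert m.accuracy == Fraction(424, 465)
    pct = m.as_percent()
    assert pct["accuracy"] == 91
    m2 = A.metrics(A.ConfusionCounts(tp=34, tn=33, fp=288, fn=110))
    assert m2.sensitivity == Fraction(34, 144)
    assert m2.as_percent()["sensitivity"] == 24


def test_metrics_undefined_on_empty_class():
    m = A.metrics(A.ConfusionCounts(tp=0, tn=5, fp=2, fn=0))
    assert m.sensitivity is None
    assert m.npv == Fraction(5, 5)
    assert m.as_percent()["sensitivity"] is None


def test_metrics_invariant_to_record_order(small_cohort, small_truth):
    recs = [r for r in small_cohort.readings if r.reader_id == "r1" and r.modality is Modality.DTS]
    a = A.metrics(A.classify(recs, small_truth))
    b = A.metrics(A.classify(list(reversed(recs)), small_truth))
    assert a == b


# ---------------------------------------------------------------- AUC


def test_auc_perfect_separation():
    table = np.array([[10, 0, 0, 0, 0], [0, 0, 0, 0, 7]])
    auc, se = A.auc_nonparametric(table)
    assert auc == 1.0


def test_auc_identical_distributions():
    table = np.array([[2, 4, 6, 4, 2], [1, 2, 3, 2, 1]])
    auc, _ = A.auc_nonparametric(table)
    assert auc == pytest.approx(0.5, abs=1e-12)


def test_auc_empty_class_raises():
    with pytest.raises(ValueError):
        A.auc_nonparametric(np.array([[0, 0, 0, 0, 0], [1, 2, 3, 2, 1]]))


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.integers(0, 40), min_size=5, max_size=5),
    st.lists(st.integers(0, 40), min_size=5, max_size=5),
)
def test_auc_equals_pairwise_oracle(neg, pos):
    """Mann-Whitney AUC equals exhaustive pairwise comparison on any 2x5 table."""
    table = np.array([neg, pos], dtype=float)
    if table[0].sum() == 0 or table[1].sum() == 0:
        return
    auc, _ = A.auc_nonparametric(table)
    assert auc == pytest.approx(oracle_auc(table), abs=1e-12)


def test_auc_se_hanley_mcneil_closed_form():
    table = np.array([[8, 5, 3, 2, 1], [1, 2, 3, 5, 9]])
    auc, se = A.auc_nonparametric(table)
    n_neg, n_pos = 19.0, 20.0
    q1, q2 = auc / (2 - auc), 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (
        n_pos * n_neg
    )
    assert se == pytest.approx(math.sqrt(var), abs=1e-14)


def test_auc_ci_methods_bracket_the_estimate():
    lo, hi = A.auc_confidence_interval(0.9, 0.02)
    assert lo < 0.9 < hi <= 1.0
    lo2, hi2 = A.auc_confidence_interval(0.9, 0.02, method="logit")
    assert 0.0 < lo2 < 0.9 < hi2 < 1.0


# ---------------------------------------------------------- correlated AUC


def test_equal_aucs_give_z_zero():
    res = A.compare_auc_correlated(0.8, 0.8, 0.03, 0.04, r=0.5)
    assert res.z == 0.0 and res.pvalue == 1.0


def test_r_zero_reduces_to_independent_formula():
    res = A.compare_auc_correlated(0.9, 0.8, 0.02, 0.03, r=0.0)
    z = (0.9 - 0.8) / math.sqrt(0.02**2 + 0.03**2)
    assert res.z == pytest.approx(z, abs=1e-12)


def test_degenerate_pairing_raises():
    with pytest.raises(ValueError, match="degenerate"):
        A.compare_auc_correlated(0.9, 0.8, 0.03, 0.03, r=1.0)


def test_correlated_auc_p_shrinks_with_n_at_fixed_effect():
    """At a fixed AUC difference, larger samples must be more significant."""
    from triage_econ.cohort import CohortSpec, generate
    from triage_econ.records import truth_map

    pvals = []
    for n in (100, 400, 1600):
        cohort = generate(CohortSpec(n=n, seed=5))
        truth = truth_map(cohort.truth)
        aucs, ses = {}, {}
        for mod in ("CXR", "DTS"):
            recs = [
                r for r in cohort.readings if r.reader_id == "r1" and r.modality is Modality(mod)
            ]
            aucs[mod], ses[mod] = A.auc_nonparametric(A.score_distribution(recs, truth))
        pids = sorted(truth)
        s_cxr, s_dts = cohort.scores("r1", "CXR"), cohort.scores("r1", "DTS")
        r = A.rating_correlation(
            [s_cxr[p] for p in pids], [s_dts[p] for p in pids], [truth[p] for p in pids]
        )
        res = A.compare_auc_correlated(aucs["DTS"], aucs["CXR"], ses["DTS"], ses["CXR"], r=r)
        assert res.z > 0  # sign agrees with the AUC ordering
        pvals.append(res.pvalue)
    assert pvals[0] >= pvals[1] >= pvals[2] or pvals[0] < 1e-12


# ---------------------------------------------------------------- McNemar


def test_mcnemar_no_discordance_flagged():
    res = A.mcnemar_from_counts(0, 0)
    assert res.pvalue == 1.0 and res.flagged


def test_mcnemar_continuity_corrected_closed_form():
    res = A.mcnemar_from_counts(10, 0, exact=False)
    assert res.statistic == pytest.approx((abs(10 - 0) - 1) ** 2 / 10, abs=1e-12)


def test_mcnemar_exact_matches_binomial_oracle():
    for b, c in [(25, 10), (3, 1), (7, 7), (12, 2)]:
        res = A.mcnemar_from_counts(b, c, exact=True)
        assert res.pvalue == pytest.approx(oracle_mcnemar_exact(b, c), abs=1e-9)


def test_mcnemar_corrected_and_exact_agree_in_decision():
    """On b=25, c=10 both versions reach the same alpha=0.05 decision."""
    approx = A.mcnemar_from_counts(25, 10, exact=False)
    exact = A.mcnemar_from_counts(25, 10, exact=True)
    assert (approx.pvalue < 0.05) == (exact.pvalue < 0.05)


def test_mcnemar_from_paired_vectors():
    correct_a = [True] * 30 + [False] * 20
    correct_b = [True] * 20 + [False] * 30
    res = A.mcnemar(correct_a, correct_b)
    assert res.pvalue == pytest.approx(oracle_mcnemar_exact(10, 0), abs=1e-9)


# ---------------------------------------------------------------- chi-square


def test_chi2_yates_identical_columns():
    res = A.chi2_yates([[50, 50], [50, 50]])
    assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)


def test_chi2_yates_matches_textbook_formula():
    table = [[424, 41], [69, 396]]
    res = A.chi2_yates(table)
    assert res.statistic == pytest.approx(oracle_chi2_yates(table), abs=1e-9)
    assert res.pvalue < 1e-10


def test_chi2_yates_grows_with_sample_size():
    small = A.chi2_yates([[30, 20], [20, 30]]).statistic
    double = A.chi2_yates([[60, 40], [40, 60]]).statistic
    assert double > small


def test_chi2_yates_empty_margin_raises():
    with pytest.raises(ValueError):
        A.chi2_yates([[0, 0], [10, 5]])


# ---------------------------------------------------------------- kappa


def test_kappa_perfect_agreement():
    scores = [1, 2, 3, 4, 5, 3, 2, 4]
    res = A.weighted_kappa(scores, scores)
    assert res.kappa == pytest.approx(1.0)
    assert res.band == "very good"


@pytest.mark.parametrize(
    "kappa,band",
    [(0.19, "poor"), (0.20, "fair"), (0.39, "fair"), (0.40, "moderate"),
     (0.60, "good"), (0.80, "very good"), (1.0, "very good"), (-0.1, "poor")],
)
def test_kappa_bands_left_closed(kappa, band):
    assert A.kappa_band(kappa) == band


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5)), min_size=5, max_size=60),
       st.sampled_from(["linear", "quadratic"]))
def test_weighted_kappa_matches_direct_formula(pairs, weights):
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    if len(set(a)) == 1 and len(set(b)) == 1:
        return
    res = A.weighted_kappa(a, b, weights=weights)
    assert res.kappa == pytest.approx(oracle_weighted_kappa(a, b, weights), abs=1e-12)


def test_kappa_undefined_without_variation():
    with pytest.raises(ValueError, match="undefined"):
        A.weighted_kappa([3, 3, 3], [3, 3, 3])


def test_kappa_of_independent_readers_near_zero():
    """Statistically independent readers give kappa ~ 0 in expectation."""
    rng = np.random.default_rng(123)
    kappas = [
        A.weighted_kappa(rng.integers(1, 6, 200), rng.integers(1, 6, 200)).kappa
        for _ in range(40)
    ]
    mc_se = np.std(kappas, ddof=1) / math.sqrt(len(kappas))
    assert abs(np.mean(kappas)) < 3 * mc_se + 1e-3


# ---------------------------------------------------------------- times


def test_identical_times_flagged_p_one():
    res = A.compare_times([60.0, 70.0, 80.0], [60.0, 70.0, 80.0])
    assert res.pvalue == 1.0 and res.flagged


def test_longer_dts_times_detected(full_cohort):
    """DTS reading (103 +/- 66 s) takes significantly longer than CXR (66 +/- 23 s)."""
    t_cxr = full_cohort.times("r1", "CXR")
    t_dts = full_cohort.times("r1", "DTS")
    pids = sorted(t_cxr)
    res = A.compare_times([t_cxr[p] for p in pids], [t_dts[p] for p in pids])
    assert res.pvalue < 0.05


def test_wilcoxon_small_n_matches_exact_enumeration():
    diffs = [3.0, -1.0, 4.0, 2.0, -5.0, 6.0]
    base = [10.0, 12.0, 9.0, 11.0, 14.0, 8.0]
    other = [b - d for b, d in zip(base, diffs)]
    res = A.compare_times(base, other)
    assert res.pvalue == pytest.approx(oracle_wilcoxon_exact(diffs), abs=1e-9)


def test_missing_times_excluded_pairwise():
    res = A.compare_times([60.0, None, 80.0, 90.0], [50.0, 70.0, None, 85.0])
    assert res.method == "wilcoxon-signed-rank"


# ---------------------------------------------------------------- consensus


def test_consensus_prefers_supplied_then_higher_score():
    r1 = {"a": 2, "b": 2, "c": 4}
    r2 = {"a": 4, "b": 1, "c": 5}
    merged = A.merge_consensus(r1, r2, supplied={"a": 3})
    assert merged["a"] == 3  # triage differs, supplied wins
    assert merged["b"] == 2  # triage agrees, reader 1 kept
    assert merged["c"] == 4  # triage agrees (both CT)
    merged2 = A.merge_consensus(r1, r2)
    assert merged2["a"] == 4  # no supplied column: higher score wins
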