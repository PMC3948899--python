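# Methods

## Setting and model

The pipeline models a triage programme for patients whose chest radiograph
(CXR) shows a doubtful thoracic opacity. Each patient undergoes digital
tomosynthesis (DTS); two radiologists independently score the marker lesion
(the largest, most conspicuous finding when several are present) on both
modalities on a 5-point ordinal confidence scale: 1–2 definite/probable
benign, extra-pulmonary or pseudolesion; 3 indeterminate; 4–5
probable/definite pulmonary lesion. The reference standard assigns one of
eight lesion categories per patient; the binary ground truth calls
pulmonary opacities, primary neoplasms, ground-glass lesions and
non-calcified solid nodules *positive* (CT-deserving) and scars, calcified
nodules, pleural plaques and pseudolesions *negative*.

### Confusion classification

Scores 4–5 call a lesion, 1–2 dismiss it, and the indeterminate score 3 is
an error in both directions: FP on a negative patient (sent to CT without
need) and FN on a positive one. This is the `Score3Policy.PENALISE` default;
`EXCLUDE` and `FAVOUR` are provided for sensitivity analyses only. All
proportions are computed as exact `Fraction`s and rounded half-up to integer
percent only at the report boundary.

### Rank statistics

- **AUC** is the Mann–Whitney probability that a random positive outscores a
  random negative, ties credited ½, computed in closed form from the 2×5
  score table. The standard error is Hanley–McNeil with Q₁ = A/(2−A),
  Q₂ = 2A²/(1+A). The 95% CI defaults to the normal interval on A (clipped
  to [0,1]); a logit interval is selectable. The choice of interval is a
  genuinely open design point — neither is asserted against published
  values.
- **Correlated-AUC comparison** uses
  z = (A₁−A₂)/√(SE₁²+SE₂²−2r·SE₁SE₂). For r, the original lookup-table
  procedure maps average within-class rating correlations and average area
  to a tabulated correlation; the package uses the widely adopted
  approximation r ≈ (r₊+r₋)/2, the mean of the between-modality Pearson
  correlations among positives and among negatives
  (`rating_correlation`), and accepts an explicit r for users who prefer
  the table. A class without score variation contributes zero.
- **McNemar** runs the continuity-corrected χ² on the discordant pairs,
  falling back to the exact binomial when b+c < 25; zero discordance
  returns p = 1, flagged.
- **Weighted κ** defaults to linear weights — the common default for a
  5-point ordinal scale — with quadratic selectable; grading bands are
  left-closed (κ = 0.40 is "moderate"). Computation is delegated to
  statsmodels and cross-checked in the tests against a direct
  observed/expected weighted-disagreement formula.
- **Interpretation times** are compared with the Wilcoxon signed-rank test,
  zero differences dropped, pairs with a missing time excluded pairwise.

### Consensus and triage

Where the readers' triage decisions (1–2 vs 3–5) agree, reader 1's score
stands. Where they differ, a supplied consensus column (the "third reader")
wins; absent one, the higher score wins — conservative, since a suspicion
raised by either reader is never dismissed silently. Triage then routes
1–2 to a ~6-month follow-up CXR and 3–5 to CT within a week.

Subdiagnostic DTS examinations (patient unable to keep the upright position
or suspend respiration) carry no score. Their routing defaults to CT —
unresolved suspicion cannot be dismissed — but utilisation books them on a
separate `dts_subdiagnostic` line and does **not** add an onward CT by
default (`count_subdiagnostic_ct=False`): the reference accounting charges
their DTS examination cost only. Follow-up CXRs are counted
(`count_followup_cxr=True`): in the reference post-implementation year the
91 CXR line equals exactly the 130−39 patients routed to follow-up.

## Costing

All money is `decimal.Decimal` at cent precision; sums and count×unit-cost
products are exact, divisions round half-up to cents only when a
per-examination figure is materialised. Unit full costs have five
components (contrast, medical, radiographer, nursing, depreciation).
Capacity costs attach to examinations through mean occupation time:
annual cost / (capacity hours × 60) × occupation minutes, with 2,600
practical-capacity hours/year for the CXR/DTS stand and 3,030 for CT, and
occupation means of 6/13/15/19 minutes (CXR/DTS/CT/CT-contrast).

Two modes exist. *Authoritative mode* (the default reference tables and the
acceptance path) takes the per-component unit costs directly from the
accounting system. *Model mode* reconstructs them from personnel rates,
occupation times and asset specs; it is provided and tested arithmetically,
but the reference per-exam depreciation cells (e.g. 10.59 for DTS) are not
exactly recoverable from the equipment table plus stated capacity hours —
the allocation basis of the source accounts is under-specified — so nothing
is asserted about that reconstruction. Similarly, the reference DTS asset
prints an annual depreciation of 3,750 against a 30,000 price and a stated
10-year straight line; `annual_depreciation` computes price/life (3,000)
and the reference table carries the accounting figure as an explicit
override.

Scenario cost is Σ counts × unit total (subdiagnostic DTS at the DTS unit
cost); the differential saving is cost(before) − cost(after) and may be
negative. Break-even is the smallest integer n with
n·(reimbursement − variable unit cost) ≥ fixed cost, i.e. a ceiling, never
a rounding: 478.47 examinations means the 479th is needed.

## Synthetic cohorts

The generator draws, per patient: a lesion category from the reference mix
(prevalence 144/465 under the truth mapping), a size from the per-category
normal (truncated at 0.1 cm) where the category carries one, and ordinal
scores from truth- and modality-conditional categorical distributions. The
defaults put P(score ≥ 4 | positive) and P(score ≤ 2 | negative) exactly at
the reference operating points (CXR 0.24/0.10, DTS 0.80/0.95) and
concentrate the remaining CXR mass on the indeterminate score, which is the
behavioural signature being modelled: radiography leaves most patients
unresolved.

Reader 2 copies reader 1's score with probability a, else redraws
independently from the same conditional distribution. Under this mixture
the expected linear weighted κ is 1 − (1−a)·E|X−Y|within / E|X−Y|marginal,
which is solved in closed form for the default copy probabilities
(a = 0.3816 on CXR, 0.7572 on DTS, targeting κ = 0.40 and 0.89). This is
one tunable knob mapping monotonically to κ, sufficient for agreement
testing; it is not a full latent-correlation model and produces no
reader-specific bias.

Interpretation times are lognormal with moment-matched (μ, σ) for means/SDs
of 66 ± 23 s (CXR) and 103 ± 66 s (DTS), truncated at 1 s — positive,
right-skewed, matching the reported ranges. The subdiagnostic rate defaults
to 7/472 of attempted examinations.

What the generator does **not** emulate: per-score count tables of the
reference study (its printed per-score rows are internally inconsistent,
so only aggregate operating points are calibrated), lesion-size-dependent
scoring, reader-specific skill differences, and temporal or case-mix drift.
Passing tests therefore demonstrate correct statistical machinery and
faithful aggregate calibration, not validity on any real cohort.

## Numerical and degenerate-input choices

- Exact rational metrics; undefined denominators yield `None`, never 0.
- AUC requires both classes non-empty; the variance term of the correlated
  z must be positive, else the pairing is reported degenerate.
- κ is undefined (raises) when neither reader varies; independence drives
  it to ~0 in expectation (property-tested at Monte-Carlo precision).
- Currency strings accept both decimal points and decimal commas with
  thousands separators ("41,55", "1.242.000").
- Determinism: a cohort is a pure function of its spec and seed; re-running
  the full pipeline with the same inputs yields byte-identical reports up
  to the manifest timestamp.

## Problem sizes

Default test and acceptance runs use cohorts of n = 465 (the reference
size), a 10,000-patient cohort for moment-convergence checks, 200 seeds for
parameter recovery (estimates within exact Clopper–Pearson 95% CIs in
≥ 93% of replicates), and 1,000 random 2×5 tables for the AUC/oracle
equivalence sweep. The whole suite runs in a few seconds on one CPU.

## Known limitations

- The correlated-AUC r is an approximation to the original tabulated
  procedure (see above); supply r explicitly when the table value matters.
- Model-mode unit costing documents, rather than resolves, the reference
  depreciation-allocation gap.
- Costing carries no discounting, inflation, VAT or multi-year NPV; the
  break-even is a single-period contribution-margin calculation.
- The printed aggregate accuracies of the reference reading study are not
  always consistent with their own TP/TN counts; the package always
  computes metrics from counts.
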