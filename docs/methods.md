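# Methods note

This note documents the model implemented by `crcside`, the conventions
adopted where a published validation study of ICD-based tumor-sidedness
leaves room for interpretation, the design of the synthetic data
generator, the numerical choices, and known limitations. It makes no
empirical claim that the code does not compute.

## 1. Code lexicon

Codes are normalized by stripping dots and whitespace and upper-casing;
the code system (ICD-9-CM vs ICD-10-CM) is inferred from the leading
character (digit vs letter) and checked against any caller-supplied hint
(`MalformedCodeError` on conflict). The colorectal inclusion families are
ICD-9 `153`, `154` and ICD-10 `C18`, `C19`, `C20`, `C21`. Only exact
codes in the lexicon map to an anatomic site; an unlisted child of an
inclusion family (e.g. `C18.44`) raises `NotInLexiconError` rather than
guessing a site.

Sites group into sidedness categories:

| Category | Sites |
| --- | --- |
| RIGHT | cecum, ascending colon, hepatic flexure |
| TRANSVERSE | transverse colon |
| LEFT | splenic flexure, descending colon, sigmoid colon, rectosigmoid junction |
| RECTUM | rectum, anus |
| UNSPECIFIED | appendix (153.5/C18.1), overlapping sites (153.8/C18.8), unspecified colon (153.9/C18.9) |

The rectosigmoid junction (154.0/C19) groups with LEFT, consistent with
treating left-sided disease as splenic flexure and distal. Appendiceal
codes map to UNSPECIFIED rather than RIGHT: appendiceal primaries are
biologically distinct and a validation of colon sidedness should not
count them as right-sided evidence.

## 2. Index-date assignment algorithm

For each patient, among *dated* colorectal inclusion events
(undated events are ignored):

1. **Index date.** The event date minimizing the absolute day offset to
   the initial diagnosis date; equidistant ties break toward the
   *earlier* date. If the patient has no initial diagnosis date, the
   earliest event date is the index date. A patient with no dated
   inclusion events is unclassifiable (`UnclassifiableError`).
2. **Same-date collapse.** Codes on the index date are grouped by
   category. Unspecified codes are dropped whenever any side-specific
   category (LEFT/RIGHT/TRANSVERSE/RECTUM) is present on that date.
3. **Category.** One remaining specific category → that category; two or
   more distinct specific categories → `MULTIPLE[...]` listing the
   components in a fixed order; only unspecified codes → UNSPECIFIED.

Only index-date codes contribute: a side-specific code weeks later never
overrides an unspecified index-date assignment. This is deliberate — the
algorithm models how a registry would lock a sidedness value at
diagnosis, and the validation quantifies the cost of that rule (it is the
source of the large UNSPECIFIED row in the reference table).

RECTUM is treated as a side-specific (non-missing) category throughout:
it survives the same-date collapse and participates in MULTIPLE.

## 3. Validation metrics

* **Cross-tabulation.** Assigned category (6 rows: LEFT, RIGHT,
  TRANSVERSE, UNSPECIFIED, RECTUM, MULTIPLE[RIGHT+TRANSVERSE]) ×
  abstracted side (4 columns: LEFT, RIGHT, TRANSVERSE, UNSPECIFIED).
  Chart abstraction in the modeled study recorded colon sidedness only,
  so RECTUM is not an abstraction label.
* **Per-side 2×2.** For analysis side *S* (LEFT, RIGHT, TRANSVERSE, or
  the composite RIGHT-or-TRANSVERSE), a patient is *test-positive* when
  the assigned category is *S* or a MULTIPLE containing a component of
  *S*, and *gold-positive* when the abstracted side is in *S*.
  Abstracted-UNSPECIFIED patients are gold-negative, not excluded.
* **Proportion CIs.** 95% intervals via
  `statsmodels.stats.proportion.proportion_confint`; Clopper–Pearson
  (exact) by default, Wilson and Wald selectable. Undefined metrics
  (zero denominator) are reported as `None`, never as 0.
* **Cohen's kappa** over the union label space of rows and columns,
  computed with `fractions.Fraction` so that the displayed value is the
  true rational rounded half-up, not a binary-float artifact. A
  cross-check against `sklearn.metrics.cohen_kappa_score` is part of the
  test suite.
* **Restricted concordance.** Observed agreement and kappa recomputed
  after dropping assigned UNSPECIFIED, RECTUM, and MULTIPLE rows,
  i.e. over patients with a usable side-specific assignment.

## 4. Reference fixture and joint-table reconstruction

The package ships a deterministic 200-patient reference sample. Its
joint table is *not* hand-typed: `joint_table_oracle()` finds it by
brute-force integer search over all 6×4 tables constrained by

* the published row margins (70, 35, 10, 76, 8, 1) and abstraction
  margins (99, 67, 12, 22);
* half-up rounding windows of all 16 published accuracy percents
  (sensitivity/specificity/PPV/NPV for LEFT, RIGHT, TRANSVERSE, and
  RIGHT-or-TRANSVERSE);
* the window of "83% of the 76 unspecified-assigned patients had a side
  recovered by abstraction";
* the window of the published observed agreement 0.58.

Exactly one diagonal pattern survives; among completions the
lexicographically smallest row-major table is taken (off-diagonal freedom
only exists where it does not affect any published statistic). The
search is cross-checked in the tests against an independently derived
pencil-and-paper solution.

## 5. Synthetic EHR generator

Generation is *constructive*: each patient is planted with an
(abstracted side, assigned category) pair and an event stream is built
that provably classifies to the planted category under the algorithm of
§2 — the round-trip is asserted at n=200 and n=100,000 in the tests.
Realism features, all exercising a specific algorithm branch:

* ICD revision follows the event date (ICD-9 before 2015-10-01, ICD-10
  after), matching the US ICD-10-CM transition;
* decoy events at strictly farther dates, including different-sided
  specific codes for UNSPECIFIED-assigned patients (so the index-only
  rule is load-bearing, not vacuous);
* equidistant-tie cases and same-date unspecified+specific collapse
  cases are forced into the fixture;
* a configurable fraction of patients lacks an initial diagnosis date;
* demographics (sex, age band, stage group, year of diagnosis) are drawn
  per patient; the fixture reproduces the published demographic blocks
  exactly, including the stage strata of sizes 78 / 107 / 15.

`sample_cohort(CohortConfig(...))` draws i.i.d. cells from a configurable
joint distribution (default: the fixture's empirical joint). The
defaults are the study conditions; they were fixed from the reconstruction
before any downstream statistic was inspected and are not tuned. All
randomness flows from `numpy.random.default_rng(seed)`; no global state.

Scope limits of the generator: no longitudinal care-pattern structure
(visit cadence, comorbidity codes, coding-intensity drift), no
correlation between demographics and sidedness, and abstraction is
treated as error-free gold, as in the modeled chart review.

## 6. Numerical choices

* Display rounding is **half-up on exact ratios**: `percent(115, 200)`
  routes through `decimal.Decimal` integer division, so 0.575 → 0.58.
  Naive `round()` on the binary float would give 0.57 and fail to
  reproduce the published agreement.
* Kappa and agreement are carried as `Fraction`s until display.
* Clopper–Pearson coverage is empirically verified (≥93% observed at
  nominal 95% across p ∈ {0.1, 0.5, 0.9}, n ∈ {12, 99}, 2000
  replicates) against a direct `scipy.stats.beta.ppf` oracle.
* Problem sizes used in validation: the 200-patient fixture throughout;
  generator convergence at n=100,000 over 5 seeds (mean total-variation
  distance to the configured joint < 0.02); exhaustive classifier
  equivalence against a brute-force reference over ~18,500 enumerated
  small timelines.

## 7. Limitations

* **Restricted concordance.** From the reconstructed table, the 116
  side-specific assignments agree with abstraction for 102 patients:
  observed agreement 0.88, kappa 0.79. No integer diagonal consistent
  with the published margins, accuracy windows, and kappa 0.79 yields a
  restricted agreement near 0.84; the package therefore reports 0.88 and
  does not pin this statistic to a published value.
* The joint-table reconstruction pins the diagonal and all constrained
  cells uniquely, but a few off-diagonal cells are fixed only by the
  lexicographic-minimum convention; statistics reported by the package
  are invariant to that freedom by construction.
* The parent-cohort specific-code share (5940/9403 = 63%) is computed
  from published counts as inputs; no per-patient parent-cohort data are
  simulated.
* The algorithm's accuracy estimates are conditional on the modeled
  study's abstraction being correct; inter-abstractor variability is out
  of scope.
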