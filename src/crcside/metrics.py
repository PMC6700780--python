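"""Concordance and diagnostic-accuracy metrics for the validation study.

Given per-patient assigned categories (from the ICD classifier) and
gold-standard abstracted sides, this module builds the assigned x
abstracted contingency table and computes

* observed agreement and Cohen's kappa over the full category space
  (each MULTIPLE combination is its own label; labels seen by only one
  rater enter with zero margin on the other side), and
* per-side 2x2 diagnostic accuracy — sensitivity, specificity, PPV,
  NPV with 95% binomial confidence intervals — treating abstraction as
  the gold standard.  An abstracted "unspecified" is gold-negative for
  every side; a MULTIPLE assignment is test-positive for each of its
  component sides.

Agreement fractions are carried as exact rationals internally so that
display rounding is exact (115/200 prints as 0.58, not 0.57).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .assignment import AssignedCategory, Category, parse_label
from .lexicon import SideCategory
from .rounding import percent, round_half_up

#: Abstracted (gold) vocabulary: the chart review classifies colon
#: tumors only, so there is no rectum column.
GOLD_LABELS: tuple[str, ...] = ("LEFT", "RIGHT", "TRANSVERSE", "UNSPECIFIED")

#: Assigned categories that always appear as rows, in display order.
ASSIGNED_BASE_LABELS: tuple[str, ...] = (
    "LEFT",
    "RIGHT",
    "TRANSVERSE",
    "UNSPECIFIED",
    "RECTUM",
)

#: Per-side analyses reported by the validation, keyed by analysis name.
SIDE_ANALYSES: dict[str, frozenset[SideCategory]] = {
    "LEFT": frozenset({SideCategory.LEFT}),
    "RIGHT": frozenset({SideCategory.RIGHT}),
    "TRANSVERSE": frozenset({SideCategory.TRANSVERSE}),
    "RIGHT_OR_TRANSVERSE": frozenset({SideCategory.RIGHT, SideCategory.TRANSVERSE}),
}


class AlignmentError(ValueError):
    """Assigned and gold inputs do not describe the same patients."""


@dataclass(frozen=True)
class CrossTab:
    """Assigned-category x abstracted-side contingency table."""

    counts: pd.DataFrame  # index: assigned labels; columns: GOLD_LABELS

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 confusion counts of one per-side analysis."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """One proportion with its 95% CI.  ``point`` is None when the
    denominator is zero (undefined, not 0)."""

    numerator: int
    denominator: int
    point: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.point is not None

    def display_percent(self) -> int | None:
        """Integer percent under half-up rounding, or None if undefined."""
        if not self.defined:
            return None
        return percent(self.numerator, self.denominator)


@dataclass(frozen=True)
class AccuracyMetrics:
    """Per-side diagnostic accuracy against the abstraction gold standard."""

    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    ci_method: str


@dataclass(frozen=True)
class ConcordanceResult:
    """Observed and chance-expected agreement between the two raters."""

    observed_agreement: float
    expected_agreement: float
    kappa: float | None
    n: int
    category_convention: str
    observed_fraction: Fraction = field(repr=False, default=Fraction(0))
    kappa_fraction: Fraction | None = field(repr=False, default=None)

    def display(self, ndigits: int = 2) -> tuple[float, float | None]:
        """(observed agreement, kappa) rounded half-up from exact values."""
        po = round_half_up(self.observed_fraction, ndigits)
        k = (
            round_half_up(self.kappa_fraction, ndigits)
            if self.kappa_fraction is not None
            else None
        )
        return po, k


def _as_label(value: AssignedCategory | str) -> str:
    if isinstance(value, AssignedCategory):
        return value.label
    parse_label(value)  # validates
    return value


def _as_mapping(
    data: Mapping[str, object] | Iterable[tuple[str, object]], what: str
) -> dict[str, object]:
    if isinstance(data, Mapping):
        return dict(data)
    out: dict[str, object] = {}
    for pid, value in data:
        if pid in out:
            raise AlignmentError(f"duplicate patient id {pid!r} in {what}")
        out[pid] = value
    return out


def cross_tabulate(
    assigned: Mapping[str, AssignedCategory | str]
    | Iterable[tuple[str, AssignedCategory | str]],
    gold: Mapping[str, str] | Iterable[tuple[str, str]],
) -> CrossTab:
    """Tabulate assigned x abstracted counts over aligned patients.

    Raises :class:`AlignmentError` on empty input, duplicate ids, or a
    patient present on one side only.
    """
    assigned_map = _as_mapping(assigned, "assigned")
    gold_map = _as_mapping(gold, "gold")
    if not assigned_map:
        raise AlignmentError("no patients to tabulate")
    if set(assigned_map) != set(gold_map):
        missing = set(assigned_map) ^ set(gold_map)
        raise AlignmentError(
            f"assigned/gold patient ids differ; {len(missing)} unmatched "
            f"(e.g. {sorted(missing)[:3]})"
        )
    from collections import Counter

    pair_counts: Counter[tuple[str, str]] = Counter()
    for pid, value in assigned_map.items():
        col = str(gold_map[pid]).upper()
        if col not in GOLD_LABELS:
            raise AlignmentError(
                f"abstracted label {gold_map[pid]!r} for patient {pid!r} "
                f"is outside the gold vocabulary {GOLD_LABELS}"
            )
        pair_counts[(_as_label(value), col)] += 1
    extra = sorted(
        {r for r, _ in pair_counts if r not in ASSIGNED_BASE_LABELS}
    )
    index = list(ASSIGNED_BASE_LABELS) + extra
    counts = pd.DataFrame(0, index=index, columns=list(GOLD_LABELS), dtype=int)
    for (row, col), v in pair_counts.items():
        counts.loc[row, col] = v
    return CrossTab(counts=counts)


def _row_positive(label: str, sides: frozenset[SideCategory]) -> bool:
    category, components = parse_label(label)
    if category is Category.MULTIPLE:
        return bool(components & sides)
    return any(category.value == s.value for s in sides)


def per_side_2x2(
    crosstab: CrossTab,
    side: str | SideCategory | Iterable[SideCategory],
) -> TwoByTwo:
    """Collapse the contingency table to one side's 2x2.

    ``side`` is a specific side, the name of a composite analysis
    (``RIGHT_OR_TRANSVERSE``), or an explicit set of specific sides.
    Gold-positive means the abstracted side lies in the target set; the
    abstracted UNSPECIFIED column is gold-negative throughout.
    """
    if isinstance(side, str):
        if side not in SIDE_ANALYSES:
            raise KeyError(
                f"unknown side {side!r}; expected one of {sorted(SIDE_ANALYSES)}"
            )
        sides = SIDE_ANALYSES[side]
    elif isinstance(side, SideCategory):
        sides = frozenset({side})
    else:
        sides = frozenset(side)
    if not sides or SideCategory.UNSPECIFIED in sides:
        raise KeyError(f"invalid side set {sides!r}")

    tp = fp = fn = tn = 0
    gold_pos_cols = [s.value for s in sides]
    for label, row in crosstab.counts.iterrows():
        test_pos = _row_positive(str(label), sides)
        for col, count in row.items():
            gold_pos = col in gold_pos_cols
            if test_pos and gold_pos:
                tp += int(count)
            elif test_pos:
                fp += int(count)
            elif gold_pos:
                fn += int(count)
            else:
                tn += int(count)
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


_CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson", "wald": "normal"}


def binomial_ci(
    successes: int, trials: int, method: str = "clopper_pearson", alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided binomial confidence interval, clamped to [0, 1]."""
    if method not in _CI_METHODS:
        raise KeyError(f"unknown CI method {method!r}; expected {sorted(_CI_METHODS)}")
    if trials < 1 or successes < 0 or successes > trials:
        raise ValueError(f"invalid counts: successes={successes}, trials={trials}")
    low, high = proportion_confint(successes, trials, alpha=alpha, method=_CI_METHODS[method])
    low = 0.0 if not (low == low) else max(0.0, float(low))  # NaN at the boundary
    high = 1.0 if not (high == high) else min(1.0, float(high))
    if successes == 0:
        low = 0.0
    if successes == trials:
        high = 1.0
    return low, high


def _estimate(numerator: int, denominator: int, ci_method: str) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(numerator, denominator, None, None, None)
    low, high = binomial_ci(numerator, denominator, method=ci_method)
    return MetricEstimate(numerator, denominator, numerator / denominator, low, high)


def accuracy(two_by_two: TwoByTwo, ci_method: str = "clopper_pearson") -> AccuracyMetrics:
    """Sensitivity, specificity, PPV, NPV with 95% CIs from a 2x2."""
    t = two_by_two
    return AccuracyMetrics(
        sensitivity=_estimate(t.tp, t.tp + t.fn, ci_method),
        specificity=_estimate(t.tn, t.tn + t.fp, ci_method),
        ppv=_estimate(t.tp, t.tp + t.fp, ci_method),
        npv=_estimate(t.tn, t.tn + t.fn, ci_method),
        ci_method=ci_method,
    )


def _diagonal(crosstab: CrossTab) -> int:
    # Only the four shared labels can match; RECTUM and MULTIPLE rows
    # have no abstracted counterpart and never contribute.
    return sum(
        int(crosstab.counts.loc[lab, lab])
        for lab in GOLD_LABELS
        if lab in crosstab.counts.index
    )


def observed_agreement(crosstab: CrossTab) -> float:
    """Fraction of patients on the (shared-label) diagonal."""
    n = crosstab.n
    if n < 1:
        raise ValueError("observed agreement needs at least one patient")
    return _diagonal(crosstab) / n


def cohens_kappa(crosstab: CrossTab) -> ConcordanceResult:
    """Chance-corrected agreement over the union category space.

    Expected agreement is the usual marginal product summed over the
    union of assigned and abstracted labels; labels absent from one
    rater contribute zero.  Kappa is undefined (None) when expected
    agreement is 1.
    """
    n = crosstab.n
    if n < 1:
        raise ValueError("kappa needs at least one patient")
    rows = crosstab.row_margins()
    cols = crosstab.col_margins()
    labels = list(dict.fromkeys(list(crosstab.counts.index) + list(GOLD_LABELS)))
    pe = Fraction(0)
    for lab in labels:
        r = int(rows.get(lab, 0))
        c = int(cols.get(lab, 0))
        pe += Fraction(r * c, n * n)
    po = Fraction(_diagonal(crosstab), n)
    if pe == 1:
        kappa_frac = None
    else:
        kappa_frac = (po - pe) / (1 - pe)
    return ConcordanceResult(
        observed_agreement=float(po),
        expected_agreement=float(pe),
        kappa=float(kappa_frac) if kappa_frac is not None else None,
        n=n,
        category_convention="union of assigned and abstracted labels",
        observed_fraction=po,
        kappa_fraction=kappa_frac,
    )


def restricted_concordance(
    crosstab: CrossTab, exclude: Iterable[str | Category]
) -> ConcordanceResult:
    """Concordance after dropping whole assigned-category rows.

    ``exclude`` names top-level assigned categories (``MULTIPLE``
    drops every MULTIPLE[...] row).  Raises if nothing remains.
    """
    excluded = {e.value if isinstance(e, Category) else str(e) for e in exclude}
    unknown = excluded - {c.value for c in Category}
    if unknown:
        raise KeyError(f"unknown assigned categories {sorted(unknown)}")
    keep = [
        lab
        for lab in crosstab.counts.index
        if parse_label(str(lab))[0].value not in excluded
    ]
    sub = crosstab.counts.loc[keep]
    if int(sub.to_numpy().sum()) < 1:
        raise ValueError("exclusion leaves no patients")
    return cohens_kappa(CrossTab(counts=sub))


@dataclass(frozen=True)
class ValidationReport:
    """Everything the validation computes for one patient set."""

    crosstab: CrossTab
    per_side: dict[str, tuple[TwoByTwo, AccuracyMetrics]]
    concordance: ConcordanceResult
    restricted: ConcordanceResult | None
    ci_method: str


def validate(
    assigned: Mapping[str, AssignedCategory | str],
    gold: Mapping[str, str],
    ci_method: str = "clopper_pearson",
) -> ValidationReport:
    """Full validation: contingency table, per-side accuracy, concordance,
    and the side-specific-only (UNSPECIFIED/RECTUM excluded) concordance."""
    crosstab = cross_tabulate(assigned, gold)
    per_side = {
        name: (tbl := per_side_2x2(crosstab, name), accuracy(tbl, ci_method))
        for name in SIDE_ANALYSES
    }
    concordance = cohens_kappa(crosstab)
    restricted: ConcordanceResult | None
    try:
        restricted = restricted_concordance(
            crosstab, {Category.UNSPECIFIED, Category.RECTUM}
        )
    except ValueError:
        restricted = None
    return ValidationReport(
        crosstab=crosstab,
        per_side=per_side,
        concordance=concordance,
        restricted=restricted,
        ci_method=ci_method,
    )


def stratified_validate(
    assigned: Mapping[str, AssignedCategory | str],
    gold: Mapping[str, str],
    strata: Mapping[str, str],
    ci_method: str = "clopper_pearson",
) -> dict[str, ValidationReport]:
    """Per-stratum validation plus the pooled result (key ``pooled``).

    ``strata`` maps every patient id to a stratum label; a patient
    missing from it is an error.
    """
    missing = set(assigned) - set(strata)
    if missing:
        raise AlignmentError(
            f"{len(missing)} patients lack the stratum variable "
            f"(e.g. {sorted(missing)[:3]})"
        )
    reports = {"pooled": validate(assigned, gold, ci_method)}
    labels = sorted({strata[pid] for pid in assigned})
    for lab in labels:
        ids = [pid for pid in assigned if strata[pid] == lab]
        reports[lab] = validate(
            {pid: assigned[pid] for pid in ids},
            {pid: gold[pid] for pid in ids},
            ci_method,
        )
    return reports
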