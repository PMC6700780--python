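"""Synthetic EHR generation for the sidedness validation study.

Two generators share one constructive patient builder:

* :func:`reconstruct_fixture` — a deterministic 200-patient dataset
  whose assigned x abstracted joint distribution, demographic blocks,
  and category margins equal the published validation sample exactly.
  The joint table itself is recovered by :func:`joint_table_oracle`, a
  brute-force integer search over the contingency cells constrained by
  the published margins and by the half-up rounding windows of every
  printed accuracy percentage.
* :func:`sample_cohort` — i.i.d. patients of arbitrary size drawn from
  a configurable joint distribution, for parameter-recovery and
  robustness experiments.

Generation is constructive: each patient's diagnosis-event stream is
built so that the index-date classifier provably returns the planted
category (the planted label is recorded for round-trip testing).  The
streams exercise the algorithm's edge cases — same-date code collapse,
nearest-date selection with pre/post-diagnosis ties, missing diagnosis
dates, specific codes at non-index dates that must not override an
unspecified index date — and span the ICD-9 to ICD-10 transition
(events before 2015-10-01 carry ICD-9 codes, later events ICD-10).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd

from .assignment import Category, DiagnosisEvent, PatientTimeline, parse_label
from .lexicon import (
    ICD9_ICD10_PAIRS,
    AnatomicSite,
    SideCategory,
    lexicon_codes,
    normalize_code,
)

# ---------------------------------------------------------------------------
# Published study constants (inputs to the reconstruction)
# ---------------------------------------------------------------------------

GOLD_COLS: tuple[str, ...] = ("LEFT", "RIGHT", "TRANSVERSE", "UNSPECIFIED")
ASSIGNED_ROWS: tuple[str, ...] = (
    "LEFT",
    "RIGHT",
    "TRANSVERSE",
    "UNSPECIFIED",
    "RECTUM",
    "MULTIPLE[RIGHT+TRANSVERSE]",
)

#: Assigned-category margins of the 200-patient validation sample.
ROW_MARGINS: tuple[int, ...] = (70, 35, 10, 76, 8, 1)
#: Abstracted-side margins of the same sample.
COL_MARGINS: tuple[int, ...] = (99, 67, 12, 22)

#: Printed per-side accuracy grid (integer percents) that constrains the
#: reconstruction: (sensitivity, specificity, PPV, NPV) per analysis.
PRINTED_ACCURACY: dict[str, tuple[int, int, int, int]] = {
    "LEFT": (63, 92, 89, 72),
    "RIGHT": (49, 98, 92, 79),
    "TRANSVERSE": (58, 98, 64, 97),
    "RIGHT_OR_TRANSVERSE": (52, 96, 89, 75),
}
#: Printed share of unspecified-assigned patients whose side the
#: abstraction recovered ("83%" of 76), and the printed full-sample
#: observed agreement at two decimals.
PRINTED_UNSPECIFIED_RECOVERED_PCT = 83
PRINTED_OBSERVED_AGREEMENT_2DP = 0.58

#: Demographic count blocks of the validation sample.
FIXTURE_DEMOGRAPHICS: dict[str, dict[str, int]] = {
    "sex": {"Female": 100, "Male": 100},
    "age_band": {"18-34": 2, "35-49": 25, "50-64": 55, ">=65": 118},
    "stage": {"0-I": 5, "II": 18, "III": 55, "IV": 107, "Not documented": 15},
    "region": {"Northeast": 53, "Midwest": 40, "South": 71, "West": 30, "Other": 6},
    "practice_type": {"Community": 188, "Academic": 12},
}

#: Diagnosis-year mix (pooled from the parent cohort's year rows).
YEAR_WEIGHTS: dict[int, float] = {
    2011: 0.0858,
    2012: 0.1486,
    2013: 0.2186,
    2014: 0.2288,
    2015: 0.2367,
    2016: 0.0815,
}

ICD10_TRANSITION = dt.date(2015, 10, 1)

_AGE_RANGES = {"18-34": (18, 34), "35-49": (35, 49), "50-64": (50, 64), ">=65": (65, 90)}

# Site pools used when planting a code of a given side.
_SIDE_SITE_POOL: dict[SideCategory, tuple[AnatomicSite, ...]] = {
    SideCategory.LEFT: (
        AnatomicSite.SPLENIC_FLEXURE,
        AnatomicSite.DESCENDING_COLON,
        AnatomicSite.SIGMOID_COLON,
        AnatomicSite.RECTOSIGMOID_JUNCTION,
    ),
    SideCategory.RIGHT: (
        AnatomicSite.CECUM,
        AnatomicSite.ASCENDING_COLON,
        AnatomicSite.HEPATIC_FLEXURE,
    ),
    SideCategory.TRANSVERSE: (AnatomicSite.TRANSVERSE_COLON,),
    SideCategory.RECTUM: (AnatomicSite.RECTUM,),
    SideCategory.UNSPECIFIED: (AnatomicSite.UNSPECIFIED_COLON,),
}


def _dotted(canonical: str) -> str:
    return canonical if len(canonical) <= 3 else f"{canonical[:3]}.{canonical[3:]}"


def _site_code_map() -> dict[AnatomicSite, tuple[str, str]]:
    """site -> (ICD-9 raw code, ICD-10 raw code)."""
    codes = lexicon_codes()
    out: dict[AnatomicSite, tuple[str, str]] = {}
    for c9, c10 in ICD9_ICD10_PAIRS:
        site = codes[c9]
        if site not in out:
            out[site] = (_dotted(c9), _dotted(c10))
    return out


_SITE_CODES = _site_code_map()


# ---------------------------------------------------------------------------
# Joint-table reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JointTable:
    """Assigned x abstracted integer counts of the 200-patient sample."""

    counts: pd.DataFrame  # index ASSIGNED_ROWS, columns GOLD_COLS

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def pairs(self) -> list[tuple[str, str]]:
        """Expand to one (assigned label, gold label) pair per patient,
        in row-major table order."""
        out: list[tuple[str, str]] = []
        for row_label, row in self.counts.iterrows():
            for col_label, count in row.items():
                out.extend([(str(row_label), str(col_label))] * int(count))
        return out


class ReconstructionError(RuntimeError):
    """The constraint system admits no integer completion (implementation bug)."""


def _percent_hu(num: int, den: int) -> int:
    # integer half-up percent: floor(100*num/den + 1/2)
    return (200 * num + den) // (2 * den)


def _window(printed: int, den: int) -> frozenset[int]:
    """Integers k in [0, den] whose half-up integer percent over den is
    the printed value."""
    return frozenset(k for k in range(den + 1) if _percent_hu(k, den) == printed)


def _row_fills(total: int, caps: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    """All non-negative 4-tuples summing to ``total`` under per-column
    caps, in ascending lexicographic order."""
    c0, c1, c2, c3 = caps
    for a in range(max(0, total - c1 - c2 - c3), min(c0, total) + 1):
        r1 = total - a
        for b in range(max(0, r1 - c2 - c3), min(c1, r1) + 1):
            r2 = r1 - b
            for c in range(max(0, r2 - c3), min(c2, r2) + 1):
                yield (a, b, c, r2 - c)


def _verify_windows(grid: list[tuple[int, ...]]) -> bool:
    """Check every printed accuracy percent against a full 6x4 grid."""
    pos_rows = {
        "LEFT": (0,),
        "RIGHT": (1, 5),
        "TRANSVERSE": (2, 5),
        "RIGHT_OR_TRANSVERSE": (1, 2, 5),
    }
    pos_cols = {
        "LEFT": (0,),
        "RIGHT": (1,),
        "TRANSVERSE": (2,),
        "RIGHT_OR_TRANSVERSE": (1, 2),
    }
    for name, (sens, spec, ppv, npv) in PRINTED_ACCURACY.items():
        tp = fp = fn = tn = 0
        for i, row in enumerate(grid):
            for j, v in enumerate(row):
                if i in pos_rows[name]:
                    if j in pos_cols[name]:
                        tp += v
                    else:
                        fp += v
                elif j in pos_cols[name]:
                    fn += v
                else:
                    tn += v
        if (
            _percent_hu(tp, tp + fn) != sens
            or _percent_hu(tn, tn + fp) != spec
            or _percent_hu(tp, tp + fp) != ppv
            or _percent_hu(tn, tn + fn) != npv
        ):
            return False
    return True


@lru_cache(maxsize=1)
def joint_table_oracle() -> JointTable:
    """Recover the validation sample's full contingency table.

    Brute-force integer search over the 6x4 cells constrained by the
    published row/column margins, the half-up rounding windows of all
    sixteen printed accuracy percentages, the printed 83% side-recovery
    share among unspecified-assigned patients, and the printed 0.58
    observed agreement.  Among feasible completions the row-major
    lexicographically smallest is returned; the per-side 2x2 tables and
    kappa are identical across all completions, so the choice is inert.
    """
    # The left analysis involves only the LEFT row, so its four printed
    # percents pin the left-left cell outright:
    #   fp = row_l - k, tn = n - gold_l - fp, fn = gold_l - k.
    sens_l, spec_l, ppv_l, npv_l = PRINTED_ACCURACY["LEFT"]
    n = sum(ROW_MARGINS)
    gold_l, row_l = COL_MARGINS[0], ROW_MARGINS[0]
    left_set = frozenset(
        k
        for k in range(min(row_l, gold_l) + 1)
        if _percent_hu(k, gold_l) == sens_l
        and _percent_hu(k, row_l) == ppv_l
        and _percent_hu(n - gold_l - row_l + k, n - gold_l) == spec_l
        and _percent_hu(n - gold_l - row_l + k, n - row_l) == npv_l
    )
    # 83% of the 76 unspecified-assigned had a side recovered:
    uu_set = frozenset(
        ROW_MARGINS[3] - k
        for k in _window(PRINTED_UNSPECIFIED_RECOVERED_PCT, ROW_MARGINS[3])
    )
    # Right/transverse tp totals include the MULTIPLE row's cell.
    right_set = _window(PRINTED_ACCURACY["RIGHT"][0], COL_MARGINS[1])
    trans_set = _window(PRINTED_ACCURACY["TRANSVERSE"][0], COL_MARGINS[2])
    comp_set = _window(
        PRINTED_ACCURACY["RIGHT_OR_TRANSVERSE"][0], COL_MARGINS[1] + COL_MARGINS[2]
    )
    # Observed-agreement window at two decimals (0.58 -> diagonal/200
    # must round half-up to 58%).
    agree_pct = round(PRINTED_OBSERVED_AGREEMENT_2DP * 100)
    diag_set = frozenset(d for d in range(n + 1) if _percent_hu(d, n) == agree_pct)

    best: list[tuple[int, ...]] | None = None
    col_used = [0, 0, 0, 0]

    def caps() -> tuple[int, ...]:
        return tuple(COL_MARGINS[j] - col_used[j] for j in range(4))

    def close(rows: list[tuple[int, ...]]) -> list[tuple[int, ...]] | None:
        """Given rows L,R,T,U, force the RECTUM and MULTIPLE rows from
        the column remainders and verify every window."""
        rem = [COL_MARGINS[j] - sum(r[j] for r in rows) for j in range(4)]
        if any(v < 0 for v in rem) or sum(rem) != ROW_MARGINS[4] + ROW_MARGINS[5]:
            return None
        candidates = []
        for j in range(4):  # which column the single MULTIPLE patient lands in
            if rem[j] < 1:
                continue
            m = tuple(1 if k == j else 0 for k in range(4))
            rec = tuple(rem[k] - m[k] for k in range(4))
            if sum(rec) != ROW_MARGINS[4] or any(v < 0 for v in rec):
                continue
            grid = rows + [rec, m]
            tp_r = grid[1][1] + grid[5][1]
            tp_t = grid[2][2] + grid[5][2]
            tp_rt = (
                grid[1][1] + grid[1][2] + grid[2][1] + grid[2][2] + grid[5][1] + grid[5][2]
            )
            diag = grid[0][0] + grid[1][1] + grid[2][2] + grid[3][3]
            if (
                tp_r in right_set
                and tp_t in trans_set
                and tp_rt in comp_set
                and diag in diag_set
                and _verify_windows(grid)
            ):
                candidates.append((rec, m))
        if not candidates:
            return None
        rec, m = min(candidates)
        return rows + [rec, m]

    def dfs(rows: list[tuple[int, ...]]) -> list[tuple[int, ...]] | None:
        depth = len(rows)
        if depth == 4:
            return close(rows)
        for fill in _row_fills(ROW_MARGINS[depth], caps()):
            # row-specific window pruning
            if depth == 0 and fill[0] not in left_set:
                continue
            if depth == 1 and not any(fill[1] + m in right_set for m in (0, 1)):
                continue
            if depth == 2:
                if not any(fill[2] + m in trans_set for m in (0, 1)):
                    continue
                partial = rows[1][1] + rows[1][2] + fill[1] + fill[2]
                if not any(partial + m in comp_set for m in (0, 1)):
                    continue
            if depth == 3 and fill[3] not in uu_set:
                continue
            for j in range(4):
                col_used[j] += fill[j]
            result = dfs(rows + [fill])
            for j in range(4):
                col_used[j] -= fill[j]
            if result is not None:
                return result
        return None

    solution = dfs([])
    if solution is None:
        raise ReconstructionError("no integer completion satisfies the constraints")
    counts = pd.DataFrame(
        [list(r) for r in solution],
        index=list(ASSIGNED_ROWS),
        columns=list(GOLD_COLS),
        dtype=int,
    )
    return JointTable(counts=counts)


# ---------------------------------------------------------------------------
# Dataset containers and configuration
# ---------------------------------------------------------------------------


@dataclass
class ValidationDataset:
    """A simulated validation sample: timelines, gold labels, and the
    generator's planted assigned category per patient."""

    patients: list[PatientTimeline]
    abstraction: dict[str, str]
    intended: dict[str, str]
    demographics: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.patients)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """(patients, events, abstraction) tables ready for CSV output."""
        pat_rows = []
        evt_rows = []
        demo = self.demographics.set_index("patient_id") if len(self.demographics) else None
        for tl in self.patients:
            d = demo.loc[tl.patient_id] if demo is not None else {}
            pat_rows.append(
                {
                    "patient_id": tl.patient_id,
                    "diagnosis_date": (
                        tl.initial_diagnosis_date.isoformat()
                        if tl.initial_diagnosis_date
                        else ""
                    ),
                    "sex": d.get("sex", ""),
                    "age_band": d.get("age_band", ""),
                    "stage": d.get("stage", ""),
                    "region": d.get("region", ""),
                    "practice_type": d.get("practice_type", ""),
                }
            )
            for e in tl.events:
                evt_rows.append(
                    {
                        "patient_id": e.patient_id,
                        "icd_code": e.code.raw,
                        "code_system": e.code.system.value,
                        "event_date": e.event_date.isoformat() if e.event_date else "",
                    }
                )
        cols_p = ["patient_id", "diagnosis_date", "sex", "age_band", "stage", "region", "practice_type"]
        cols_e = ["patient_id", "icd_code", "code_system", "event_date"]
        patients = pd.DataFrame(pat_rows, columns=cols_p)
        events = pd.DataFrame(evt_rows, columns=cols_e)
        abstraction = pd.DataFrame(
            {
                "patient_id": list(self.abstraction),
                "abstracted_side": [v.lower() for v in self.abstraction.values()],
            }
        )
        return patients, events, abstraction


def _fractions(block: dict[str, int]) -> dict[str, float]:
    total = sum(block.values())
    return {k: v / total for k, v in block.items()}


@dataclass
class CohortConfig:
    """Parameters of the stochastic cohort generator.

    The joint distribution is over (abstracted side, assigned category)
    pairs and defaults to the reconstructed validation sample's
    empirical distribution; demographic marginals default to the
    validation sample's blocks.  ``p_specific_code``, when set,
    reweights the assigned-category marginal so that the probability of
    a side-specific assignment (anything but UNSPECIFIED) equals it.
    ``extra_covariates`` carries inert categorical covariates (e.g.
    therapy or biomarker flags) sampled independently of everything
    else.
    """

    n: int
    joint: dict[tuple[str, str], float] | None = None
    demographics: dict[str, dict[str, float]] | None = None
    extra_covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    year_weights: dict[int, float] = field(default_factory=lambda: dict(YEAR_WEIGHTS))
    icd10_transition_date: dt.date = ICD10_TRANSITION
    p_missing_diagnosis_date: float = 0.05
    p_same_date_unspecified_extra: float = 0.15
    p_specific_code: float | None = None
    seed: int = 0

    def resolved_joint(self) -> dict[tuple[str, str], float]:
        if self.joint is None:
            jt = joint_table_oracle()
            joint = {
                (str(col), str(row)): int(jt.counts.loc[row, col]) / jt.n
                for row in jt.counts.index
                for col in jt.counts.columns
            }
        else:
            joint = dict(self.joint)
        if self.p_specific_code is not None:
            spec_mass = sum(p for (g, a), p in joint.items() if a != "UNSPECIFIED")
            unspec_mass = 1.0 - spec_mass
            out = {}
            for (g, a), p in joint.items():
                if a != "UNSPECIFIED":
                    out[(g, a)] = p * self.p_specific_code / spec_mass if spec_mass else 0.0
                else:
                    out[(g, a)] = (
                        p * (1 - self.p_specific_code) / unspec_mass if unspec_mass else 0.0
                    )
            joint = out
        return joint

    def resolved_demographics(self) -> dict[str, dict[str, float]]:
        if self.demographics is not None:
            return self.demographics
        return {k: _fractions(v) for k, v in FIXTURE_DEMOGRAPHICS.items()}

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name, block in [("joint", self.resolved_joint())] + [
            (k, v) for k, v in self.resolved_demographics().items()
        ] + list(self.extra_covariates.items()) + [("year_weights", self.year_weights)]:
            total = sum(block.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probability block {name!r} sums to {total}, not 1")
            if any(p < 0 for p in block.values()):
                raise ValueError(f"probability block {name!r} has negative entries")
        for p in (
            self.p_missing_diagnosis_date,
            self.p_same_date_unspecified_extra,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_specific_code is not None and not 0 <= self.p_specific_code <= 1:
            raise ValueError("p_specific_code must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Constructive patient builder
# ---------------------------------------------------------------------------


def _code_for(side: SideCategory, on: dt.date, rng: np.random.Generator, transition: dt.date):
    pool = _SIDE_SITE_POOL[side]
    site = pool[int(rng.integers(0, len(pool)))] if len(pool) > 1 else pool[0]
    raw9, raw10 = _SITE_CODES[site]
    return normalize_code(raw9 if on < transition else raw10)


def _build_patient(
    rng: np.random.Generator,
    pid: str,
    assigned_label: str,
    *,
    year: int,
    missing_dx_date: bool,
    unspecified_extra: bool,
    decoy_specific_later: bool,
    extra_decoy: bool,
    tie_case: bool,
    transition: dt.date,
) -> PatientTimeline:
    """Materialize one patient whose timeline the classifier maps to
    ``assigned_label`` by construction."""
    category, components = parse_label(assigned_label)
    dx_date = dt.date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
    offset = -5 if tie_case else int(rng.integers(-14, 15))
    index_date = dx_date + dt.timedelta(days=offset)

    events: list[DiagnosisEvent] = []
    if category is Category.MULTIPLE:
        for side in sorted(components, key=lambda s: s.value):
            events.append(
                DiagnosisEvent(pid, _code_for(side, index_date, rng, transition), index_date)
            )
    else:
        side = SideCategory(category.value)
        events.append(
            DiagnosisEvent(pid, _code_for(side, index_date, rng, transition), index_date)
        )
        if unspecified_extra and category is not Category.UNSPECIFIED:
            events.append(
                DiagnosisEvent(
                    pid,
                    _code_for(SideCategory.UNSPECIFIED, index_date, rng, transition),
                    index_date,
                )
            )

    def farther_date() -> dt.date:
        delta = abs(offset) + int(rng.integers(7, 30))
        if missing_dx_date:
            return index_date + dt.timedelta(days=delta)  # must stay after the index
        sign = 1 if rng.random() < 0.5 else -1
        return dx_date + dt.timedelta(days=sign * delta)

    if tie_case:
        # Equidistant post-diagnosis date carrying a different side: the
        # earlier (pre-diagnosis) date must win.
        other = (
            SideCategory.RIGHT
            if assigned_label != "RIGHT"
            else SideCategory.LEFT
        )
        tie_date = dx_date + dt.timedelta(days=-offset)
        events.append(DiagnosisEvent(pid, _code_for(other, tie_date, rng, transition), tie_date))
    if decoy_specific_later and category is Category.UNSPECIFIED:
        d = farther_date()
        specific = (SideCategory.LEFT, SideCategory.RIGHT, SideCategory.TRANSVERSE)
        side = specific[int(rng.integers(0, 3))]
        events.append(DiagnosisEvent(pid, _code_for(side, d, rng, transition), d))
    if extra_decoy:
        d = farther_date()
        # A repeat of the patient's own index-date coding at another visit.
        events.append(DiagnosisEvent(pid, events[0].code, d))

    return PatientTimeline(
        patient_id=pid,
        initial_diagnosis_date=None if missing_dx_date else dx_date,
        events=events,
    )


def _demographics_frame(
    rng: np.random.Generator,
    ids: list[str],
    blocks: dict[str, list[str]],
    years: list[int],
) -> pd.DataFrame:
    data: dict[str, list] = {"patient_id": ids}
    for var, values in blocks.items():
        data[var] = values
    data["diagnosis_year"] = years
    df = pd.DataFrame(data)
    df["stage_group"] = df["stage"].map(
        lambda s: s if s in ("IV", "Not documented") else "I-III"
    )
    lo = df["age_band"].map(lambda b: _AGE_RANGES[b][0]).to_numpy()
    hi = df["age_band"].map(lambda b: _AGE_RANGES[b][1]).to_numpy()
    df["age"] = lo + (rng.random(len(df)) * (hi - lo + 1)).astype(int)
    return df


def reconstruct_fixture(seed: int = 0) -> ValidationDataset:
    """Materialize the 200-patient validation sample.

    Category pairs come from :func:`joint_table_oracle`; demographic
    blocks are exact counts, shuffled across patients by ``seed``.  The
    seed controls only inert realization detail (dates, site choice
    within a side, which patients carry which edge case); every margin,
    cell and demographic block is identical for every seed.
    """
    rng = np.random.default_rng(seed)
    pairs = joint_table_oracle().pairs()
    n = len(pairs)
    years = list(rng.choice(list(YEAR_WEIGHTS), size=n, p=list(YEAR_WEIGHTS.values())))
    u = rng.random((n, 4))

    first_unspecified = next(i for i, (a, _) in enumerate(pairs) if a == "UNSPECIFIED")
    patients: list[PatientTimeline] = []
    abstraction: dict[str, str] = {}
    intended: dict[str, str] = {}
    for i, (assigned_label, gold) in enumerate(pairs):
        pid = f"P{i + 1:04d}"
        tie = i == 0  # guaranteed equidistant-date case
        patients.append(
            _build_patient(
                rng,
                pid,
                assigned_label,
                year=int(years[i]),
                missing_dx_date=(not tie) and u[i, 0] < 0.05,
                unspecified_extra=(i == 1) or u[i, 1] < 0.15,
                decoy_specific_later=(i == first_unspecified) or u[i, 2] < 0.5,
                extra_decoy=u[i, 3] < 0.4,
                tie_case=tie,
                transition=ICD10_TRANSITION,
            )
        )
        abstraction[pid] = gold
        intended[pid] = assigned_label

    blocks = {
        var: [lv for lv, cnt in counts.items() for _ in range(cnt)]
        for var, counts in FIXTURE_DEMOGRAPHICS.items()
    }
    ids = [p.patient_id for p in patients]
    shuffled = {
        var: [values[j] for j in rng.permutation(len(values))]
        for var, values in blocks.items()
    }
    demographics = _demographics_frame(rng, ids, shuffled, [int(y) for y in years])
    return ValidationDataset(patients, abstraction, intended, demographics)


def sample_cohort(config: CohortConfig) -> ValidationDataset:
    """Draw an i.i.d. cohort from the configured joint distribution.

    Each patient's (abstracted side, assigned category) pair is drawn
    from the joint; the event stream is then built constructively so
    the classifier recovers the planted category exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    joint = config.resolved_joint()
    cells = list(joint)
    probs = np.asarray([joint[c] for c in cells], dtype=float)
    probs = probs / probs.sum() if probs.sum() > 0 else probs
    n = config.n

    if n == 0:
        demo = pd.DataFrame(
            columns=["patient_id", "sex", "age_band", "stage", "region",
                     "practice_type", "diagnosis_year", "stage_group", "age"]
        )
        return ValidationDataset([], {}, {}, demo)

    draws = rng.choice(len(cells), size=n, p=probs)
    yrs = rng.choice(list(config.year_weights), size=n, p=list(config.year_weights.values()))
    u = rng.random((n, 4))
    patients: list[PatientTimeline] = []
    abstraction: dict[str, str] = {}
    intended: dict[str, str] = {}
    for i in range(n):
        gold, assigned_label = cells[draws[i]]
        pid = f"S{i + 1:06d}"
        patients.append(
            _build_patient(
                rng,
                pid,
                assigned_label,
                year=int(yrs[i]),
                missing_dx_date=u[i, 0] < config.p_missing_diagnosis_date,
                unspecified_extra=u[i, 1] < config.p_same_date_unspecified_extra,
                decoy_specific_later=u[i, 2] < 0.5,
                extra_decoy=u[i, 3] < 0.4,
                tie_case=False,
                transition=config.icd10_transition_date,
            )
        )
        abstraction[pid] = gold
        intended[pid] = assigned_label

    demo_marginals = config.resolved_demographics()
    blocks = {
        var: [
            list(levels)[j]
            for j in rng.choice(len(levels), size=n, p=list(levels.values()))
        ]
        for var, levels in demo_marginals.items()
    }
    ids = [p.patient_id for p in patients]
    demographics = _demographics_frame(rng, ids, blocks, [int(y) for y in yrs])
    for var, levels in config.extra_covariates.items():
        demographics[var] = [
            list(levels)[j]
            for j in rng.choice(len(levels), size=n, p=list(levels.values()))
        ]
    return ValidationDataset(patients, abstraction, intended, demographics)
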