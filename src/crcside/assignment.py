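"""Patient-level sidedness assignment from dated ICD diagnosis codes.

The classifier reduces a patient's diagnosis-code timeline to a single
category using the index-date rule: the diagnosis-table date closest to
the patient's initial diagnosis date is selected (earliest relevant
code when no diagnosis date is recorded), and only the colorectal codes
on that date determine the category.  Multiple distinct specific sides
on the index date yield ``MULTIPLE``; an unspecified code co-occurring
with a specific one is dropped in favor of the specific code.

Tie-breaks and edge cases:

* two event dates equidistant from the diagnosis date -> the earlier
  (pre-diagnosis) date wins, on the rationale that pre-diagnosis workup
  codes are the likelier record of the primary site;
* undated events are ignored; a patient with no dated colorectal event
  is unclassifiable;
* codes at non-index dates never override the index date — a specific
  code recorded later does not rescue an unspecified index date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .lexicon import NormalizedCode, SideCategory, is_inclusion_code, side_of_code


class Category(str, Enum):
    """Patient-level assigned category."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"
    TRANSVERSE = "TRANSVERSE"
    UNSPECIFIED = "UNSPECIFIED"
    RECTUM = "RECTUM"
    MULTIPLE = "MULTIPLE"


#: Canonical ordering of side components inside a MULTIPLE label.
_SIDE_ORDER = {
    SideCategory.LEFT: 0,
    SideCategory.RIGHT: 1,
    SideCategory.TRANSVERSE: 2,
    SideCategory.RECTUM: 3,
}


class UnclassifiableError(ValueError):
    """Raised when a timeline has no dated colorectal diagnosis event."""


@dataclass(frozen=True)
class DiagnosisEvent:
    """One dated ICD diagnosis-code observation for a patient."""

    patient_id: str
    code: NormalizedCode
    event_date: dt.date | None


@dataclass
class PatientTimeline:
    """A patient's diagnosis-code history.

    Events are kept sorted by date (undated events last) so that
    assignment is independent of input order.
    """

    patient_id: str
    initial_diagnosis_date: dt.date | None
    events: list[DiagnosisEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(
            self.events,
            key=lambda e: (e.event_date is None, e.event_date or dt.date.min),
        )

    def dated_inclusion_events(self) -> list[DiagnosisEvent]:
        return [
            e
            for e in self.events
            if e.event_date is not None and is_inclusion_code(e.code)
        ]


@dataclass(frozen=True)
class AssignedCategory:
    """Output of the structured-data algorithm for one patient.

    ``components`` is non-empty exactly for MULTIPLE and lists the
    distinct specific sides found on the index date; ``evidence`` holds
    the colorectal codes observed at ``index_date``.
    """

    category: Category
    components: frozenset[SideCategory] = frozenset()
    index_date: dt.date | None = None
    evidence: tuple[NormalizedCode, ...] = ()

    def __post_init__(self) -> None:
        if self.category is Category.MULTIPLE:
            if len(self.components) < 2 or SideCategory.UNSPECIFIED in self.components:
                raise ValueError(
                    "MULTIPLE requires >=2 specific side components, got "
                    f"{sorted(c.value for c in self.components)}"
                )
        elif self.components:
            raise ValueError("components must be empty unless category is MULTIPLE")

    @property
    def label(self) -> str:
        """Flat string label (``LEFT`` ... ``MULTIPLE[RIGHT+TRANSVERSE]``)."""
        if self.category is not Category.MULTIPLE:
            return self.category.value
        parts = sorted(self.components, key=_SIDE_ORDER.__getitem__)
        return "MULTIPLE[" + "+".join(p.value for p in parts) + "]"

    def is_positive_for(self, side: SideCategory) -> bool:
        """Test-positivity for one specific side (MULTIPLE counts for
        each of its components)."""
        if self.category is Category.MULTIPLE:
            return side in self.components
        return self.category.value == side.value


def parse_label(label: str) -> tuple[Category, frozenset[SideCategory]]:
    """Inverse of :attr:`AssignedCategory.label`."""
    if label.startswith("MULTIPLE[") and label.endswith("]"):
        parts = label[len("MULTIPLE[") : -1].split("+")
        return Category.MULTIPLE, frozenset(SideCategory(p) for p in parts)
    return Category(label), frozenset()


def select_index_date(timeline: PatientTimeline) -> dt.date:
    """Pick the event date whose codes classify the patient.

    With a known initial diagnosis date, the dated colorectal event
    date with the smallest absolute day-offset wins, the earlier date
    breaking ties; without one, the earliest dated colorectal event.
    """
    events = timeline.dated_inclusion_events()
    if not events:
        raise UnclassifiableError(
            f"patient {timeline.patient_id!r} has no dated colorectal diagnosis event"
        )
    dates = sorted({e.event_date for e in events})
    anchor = timeline.initial_diagnosis_date
    if anchor is None:
        return dates[0]
    return min(dates, key=lambda d: (abs((d - anchor).days), d))


def collapse_same_date(codes: Iterable[NormalizedCode]) -> AssignedCategory:
    """Collapse the colorectal codes of a single date to one category.

    Unspecified-side codes are dropped whenever any specific-side code
    is present; two or more distinct specific sides yield MULTIPLE.
    Rectal codes count as a specific side, so {rectum, sigmoid} is
    MULTIPLE[LEFT+RECTUM] rather than RECTUM alone.
    """
    codes = tuple(codes)
    if not codes:
        raise ValueError("collapse_same_date requires a non-empty code set")
    sides = {side_of_code(c) for c in codes}
    specific = sides - {SideCategory.UNSPECIFIED}
    if not specific:
        return AssignedCategory(Category.UNSPECIFIED, evidence=codes)
    if len(specific) == 1:
        (only,) = specific
        return AssignedCategory(Category(only.value), evidence=codes)
    return AssignedCategory(
        Category.MULTIPLE, components=frozenset(specific), evidence=codes
    )


def assign_side(timeline: PatientTimeline) -> AssignedCategory:
    """Run the full index-date classification on one patient."""
    index_date = select_index_date(timeline)
    codes = tuple(
        e.code for e in timeline.dated_inclusion_events() if e.event_date == index_date
    )
    collapsed = collapse_same_date(codes)
    return AssignedCategory(
        category=collapsed.category,
        components=collapsed.components,
        index_date=index_date,
        evidence=codes,
    )
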