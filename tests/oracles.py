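"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import datetime as dt
import itertools

from crcside.assignment import DiagnosisEvent, PatientTimeline
from crcside.lexicon import is_inclusion_code, normalize_code, side_of, site_of

#: One code per side category, the reduced alphabet for exhaustive search.
CODE_ALPHABET = {
    "sigmoid": "153.3",       # LEFT
    "cecum": "C18.0",         # RIGHT
    "transverse": "153.1",    # TRANSVERSE
    "unspecified": "C18.9",   # UNSPECIFIED
    "rectum": "C20",          # RECTUM
}


def naive_assign(timeline: PatientTimeline) -> str:
    """Brute-force reference classifier: enumerate the candidate dates
    explicitly, pick the winner, and apply the collapse rules naively.
    Returns a flat label; raises ValueError on unclassifiable input."""
    usable = []
    for event in timeline.events:
        if event.event_date is None:
            continue
        if not is_inclusion_code(event.code):
            continue
        usable.append(event)
    if not usable:
        raise ValueError("unclassifiable")

    anchor = timeline.initial_diagnosis_date
    if anchor is None:
        winner = min(e.event_date for e in usable)
    else:
        # enumerate every date, keep those at minimal |offset|, then the earliest
        offsets = {}
        for e in usable:
            offsets[e.event_date] = abs((e.event_date - anchor).days)
        smallest = min(offsets.values())
        winner = min(d for d, off in offsets.items() if off == smallest)

    sides = []
    for e in usable:
        if e.event_date == winner:
            sides.append(side_of(site_of(e.code)).value)
    specific = sorted(set(s for s in sides if s != "UNSPECIFIED"))
    if not specific:
        return "UNSPECIFIED"
    if len(specific) == 1:
        return specific[0]
    order = {"LEFT": 0, "RIGHT": 1, "TRANSVERSE": 2, "RECTUM": 3}
    return "MULTIPLE[" + "+".join(sorted(specific, key=order.__getitem__)) + "]"


def enumerate_small_timelines(max_codes_per_date: int = 2):
    """Yield every timeline over the reduced code alphabet with event
    dates drawn from offsets {-3, 0, +3} around an anchor (and the
    same timelines without an anchor), 1..3 dates, 1..max_codes codes
    per date.  The {-3, +3} subsets exercise the equidistant tie."""
    anchor = dt.date(2014, 6, 1)
    codes = [normalize_code(c) for c in CODE_ALPHABET.values()]
    date_options = [anchor + dt.timedelta(days=d) for d in (-3, 0, 3)]
    multisets = []
    for k in range(1, max_codes_per_date + 1):
        multisets.extend(itertools.combinations_with_replacement(codes, k))
    counter = itertools.count()
    for r in range(1, 4):
        for dates in itertools.combinations(date_options, r):
            for assignment in itertools.product(multisets, repeat=r):
                events = [
                    DiagnosisEvent(pid := f"T{next(counter)}", code, date)
                    for date, codes_at in zip(dates, assignment)
                    for code in codes_at
                ]
                yield PatientTimeline(pid, anchor, list(events))
                yield PatientTimeline(pid, None, list(events))
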