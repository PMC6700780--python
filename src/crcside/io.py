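"""Delimited-text input/output for the validation pipeline.

Three comma-separated tables with headers describe a study:

* ``patients``: patient_id, diagnosis_date (ISO-8601, may be empty),
  sex, age_band, stage, region, practice_type;
* ``events``: patient_id, icd_code, code_system (optional), event_date;
* ``abstraction``: patient_id, abstracted_side in
  {left, right, transverse, unspecified}.

Reading validates every row and fails with a per-row error report on
structural problems (missing columns, unparseable dates, orphan
events, out-of-vocabulary abstraction labels — the gold vocabulary is
colon-only, so ``rectum`` is rejected).  Diagnosis codes outside the
colorectal inclusion families are not errors: they are excluded from
assignment and logged.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assignment import DiagnosisEvent, PatientTimeline
from .lexicon import CodeSystem, MalformedCodeError, is_inclusion_code, normalize_code
from .synthetic import ValidationDataset

logger = logging.getLogger("crcside")

GOLD_VOCABULARY = ("left", "right", "transverse", "unspecified")

_PATIENT_COLUMNS = (
    "patient_id",
    "diagnosis_date",
    "sex",
    "age_band",
    "stage",
    "region",
    "practice_type",
)
_EVENT_COLUMNS = ("patient_id", "icd_code", "event_date")  # code_system optional


class TableError(ValueError):
    """Structural problem in an input table; carries per-row messages."""

    def __init__(self, message: str, rows: list[str] | None = None):
        self.rows = rows or []
        detail = "".join(f"\n  - {r}" for r in self.rows[:50])
        super().__init__(message + detail)


@dataclass
class ReadResult:
    """Parsed and validated study inputs."""

    timelines: list[PatientTimeline]
    gold: dict[str, str]
    demographics: pd.DataFrame
    excluded_events: list[str] = field(default_factory=list)


def _read_csv(path: str | Path, required: tuple[str, ...], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"{what} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{what} table {path} is missing columns {missing}")
    return df


def _parse_date(text: str) -> dt.date | None:
    text = text.strip()
    if not text:
        return None
    return dt.date.fromisoformat(text)


def read_tables(
    patients_path: str | Path,
    events_path: str | Path,
    abstraction_path: str | Path,
) -> ReadResult:
    """Read, validate and join the three study tables."""
    patients = _read_csv(patients_path, _PATIENT_COLUMNS, "patients")
    events = _read_csv(events_path, _EVENT_COLUMNS, "events")
    abstraction = _read_csv(
        abstraction_path, ("patient_id", "abstracted_side"), "abstraction"
    )

    errors: list[str] = []
    dx_dates: dict[str, dt.date | None] = {}
    for i, row in patients.iterrows():
        pid = row["patient_id"].strip()
        if not pid:
            errors.append(f"patients row {i + 2}: empty patient_id")
            continue
        if pid in dx_dates:
            errors.append(f"patients row {i + 2}: duplicate patient_id {pid!r}")
            continue
        try:
            dx_dates[pid] = _parse_date(row["diagnosis_date"])
        except ValueError:
            errors.append(
                f"patients row {i + 2}: unparseable diagnosis_date "
                f"{row['diagnosis_date']!r} for patient {pid!r}"
            )

    event_lists: dict[str, list[DiagnosisEvent]] = {pid: [] for pid in dx_dates}
    excluded: list[str] = []
    for i, row in events.iterrows():
        pid = row["patient_id"].strip()
        if pid not in event_lists:
            errors.append(f"events row {i + 2}: orphan event for unknown patient {pid!r}")
            continue
        try:
            event_date = _parse_date(row["event_date"])
        except ValueError:
            errors.append(
                f"events row {i + 2}: unparseable event_date {row['event_date']!r}"
            )
            continue
        hint = row.get("code_system", "").strip() if "code_system" in events.columns else ""
        try:
            code = normalize_code(
                row["icd_code"], CodeSystem(hint) if hint else None
            )
        except (MalformedCodeError, ValueError) as exc:
            errors.append(f"events row {i + 2}: {exc}")
            continue
        if not is_inclusion_code(code):
            excluded.append(
                f"events row {i + 2}: non-colorectal code {code.raw!r} "
                f"for patient {pid!r} excluded from assignment"
            )
            continue
        event_lists[pid].append(DiagnosisEvent(pid, code, event_date))

    gold: dict[str, str] = {}
    for i, row in abstraction.iterrows():
        pid = row["patient_id"].strip()
        label = row["abstracted_side"].strip().lower()
        if pid not in dx_dates:
            errors.append(
                f"abstraction row {i + 2}: unknown patient {pid!r}"
            )
            continue
        if label not in GOLD_VOCABULARY:
            errors.append(
                f"abstraction row {i + 2}: abstracted_side {row['abstracted_side']!r} "
                f"outside the vocabulary {GOLD_VOCABULARY}"
            )
            continue
        if pid in gold:
            errors.append(f"abstraction row {i + 2}: duplicate patient {pid!r}")
            continue
        gold[pid] = label.upper()

    if errors:
        raise TableError("input validation failed", errors)
    for msg in excluded:
        logger.warning(msg)

    timelines = [
        PatientTimeline(pid, dx_dates[pid], event_lists[pid]) for pid in dx_dates
    ]
    demographics = patients.copy()
    demographics["stage_group"] = demographics["stage"].map(
        lambda s: s if s in ("IV", "Not documented") else "I-III"
    )
    return ReadResult(
        timelines=timelines,
        gold=gold,
        demographics=demographics,
        excluded_events=excluded,
    )


def write_tables(dataset: ValidationDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic dataset as the three study CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, events, abstraction = dataset.to_frames()
    paths = {
        "patients": out / "patients.csv",
        "events": out / "events.csv",
        "abstraction": out / "abstraction.csv",
    }
    patients.to_csv(paths["patients"], index=False)
    events.to_csv(paths["events"], index=False)
    abstraction.to_csv(paths["abstraction"], index=False)
    return paths
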