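# crcside

Validation toolkit for assigning colorectal **tumor sidedness** (left vs.
right vs. transverse colon) from ICD-9-CM and ICD-10-CM diagnosis codes in
electronic health records, with manual chart abstraction as the reference
standard.

## The scientific problem

Primary tumor location in colon cancer is prognostic and predictive: right-
and left-sided tumors differ in biology, outcomes, and response to targeted
therapy. Large EHR-derived registries rarely record sidedness as a
structured field, but billing data carry site-specific ICD codes (ICD-9
153.x, ICD-10 C18.x, plus rectosigmoid/rectal/anal codes 154.x and
C19–C21). The question this package operationalizes: *how accurately does a
simple, rule-based classifier over a patient's ICD codes recover tumor
sidedness, judged against chart abstraction?*

The package implements:

1. **An ICD lexicon** (`crcside.lexicon`) — normalization of ICD-9/ICD-10
   code strings, the colorectal inclusion families, the code → anatomic
   site map, and the grouping of sites into sidedness categories
   (LEFT = splenic flexure through rectosigmoid junction; RIGHT = cecum
   through hepatic flexure; TRANSVERSE; RECTUM = rectum/anus;
   UNSPECIFIED).
2. **The index-date assignment algorithm** (`crcside.assignment`) — among a
   patient's dated colorectal ICD events, the *index date* is the event
   date closest to the initial diagnosis date (ties broken toward the
   earlier date; no diagnosis date → earliest event date). Only codes on
   the index date count. Same-date unspecified codes are dropped when a
   side-specific code is present; two or more distinct specific sides on
   the index date yield a `MULTIPLE[...]` category.
3. **Validation metrics** (`crcside.metrics`) — the assigned × abstracted
   cross-tabulation, per-side 2×2 collapses, sensitivity / specificity /
   PPV / NPV with exact Clopper–Pearson 95% intervals (Wilson and Wald
   available), Cohen's kappa computed in exact rational arithmetic, and a
   restricted concordance over side-specific assignments only.
4. **A synthetic EHR generator** (`crcside.synthetic`) — a constructive
   simulator that plants a (abstracted side, assigned category) pair per
   patient and emits an ICD event stream guaranteed to classify to the
   planted category, plus a deterministic 200-patient reference fixture
   whose joint table is reconstructed by integer search from published
   margins and rounding constraints.
5. **Cohort reporting** (`crcside.reporting`) and a **CLI pipeline**
   (`crcside.cli`) that ties simulation, assignment, validation, and
   Markdown/JSON report rendering together.

## Worked example

### Python API

```python
import datetime as dt
from crcside import assign_side, DiagnosisEvent, PatientTimeline, normalize_code

timeline = PatientTimeline(
    patient_id="EX01",
    initial_diagnosis_date=dt.date(2016, 3, 10),
    events=[
        DiagnosisEvent("EX01", normalize_code("C18.9"), dt.date(2016, 2, 1)),   # unspecified colon
        DiagnosisEvent("EX01", normalize_code("C18.7"), dt.date(2016, 3, 12)),  # sigmoid
        DiagnosisEvent("EX01", normalize_code("C18.0"), dt.date(2016, 9, 1)),   # cecum, far from dx
    ],
)
assigned = assign_side(timeline)
print(assigned.label, assigned.index_date, [c.format() for c in assigned.evidence])
```

prints

```
LEFT 2016-03-12 ['C18.7']
```

The sigmoid code on 2016-03-12 is 2 days from the initial diagnosis date,
closer than either other event, so it alone determines the category; the
cecum code months later never overrides it.

### Command line

```bash
crcside simulate --mode fixture --seed 7 --out-dir demo/sim
crcside validate \
    --patients demo/sim/patients.csv \
    --events demo/sim/events.csv \
    --abstraction demo/sim/abstraction.csv \
    --strata stage_group \
    --out-dir demo/val
```

`demo/val/report.md` then contains (excerpt, output verbatim):

```
## Assigned vs abstracted side

| Assigned \ Abstracted | LEFT | RIGHT | TRANSVERSE | UNSPECIFIED | Total |
| --- | --- | --- | --- | --- | --- |
| LEFT | 62 | 0 | 0 | 8 | 70 |
| RIGHT | 0 | 33 | 1 | 1 | 35 |
| TRANSVERSE | 3 | 0 | 7 | 0 | 10 |
| UNSPECIFIED | 25 | 34 | 4 | 13 | 76 |
| RECTUM | 8 | 0 | 0 | 0 | 8 |
| MULTIPLE[RIGHT+TRANSVERSE] | 1 | 0 | 0 | 0 | 1 |
| Total | 99 | 67 | 12 | 22 | 200 |

## Accuracy of the ICD assignment, % (95% CI)

| Metric | LEFT | RIGHT | TRANSVERSE | RIGHT_OR_TRANSVERSE |
| --- | --- | --- | --- | --- |
| sensitivity | 63 (52, 72) | 49 (37, 62) | 58 (28, 85) | 52 (40, 63) |
| specificity | 92 (85, 97) | 98 (94, 100) | 98 (95, 99) | 96 (91, 99) |
| ppv | 89 (79, 95) | 92 (78, 98) | 64 (31, 89) | 89 (76, 96) |
| npv | 72 (63, 79) | 79 (72, 85) | 97 (94, 99) | 75 (68, 82) |

## Concordance

- observed agreement 0.58 (kappa = 0.41) over n=200
- side-specific assignments only (UNSPECIFIED/RECTUM removed): observed agreement 0.88 (kappa = 0.79) over n=116
- share of patients with a side-specific assignment: 0.620
```

A matching `report.json` carries the same numbers in machine-readable
form. `crcside simulate --mode cohort --n 5000` draws an arbitrary-size
cohort from a configurable joint distribution instead of the fixed
200-patient fixture, and `crcside assign` writes per-patient assignments
without requiring abstraction data.

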