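"""Pipeline orchestration: simulate or load a study, assign, validate,
and write machine- and human-readable reports."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .assignment import assign_side
from .io import read_tables
from .metrics import (
    ConcordanceResult,
    MetricEstimate,
    ValidationReport,
    stratified_validate,
    validate,
)
from .reporting import specific_code_share
from .rounding import round_half_up
from .synthetic import CohortConfig, ValidationDataset, reconstruct_fixture, sample_cohort

logger = logging.getLogger("crcside")


@dataclass
class RunConfig:
    """One validation run: either three input CSVs or a simulation.

    Exactly one of (``patients_path``/``events_path``/
    ``abstraction_path``) and ``simulate`` must be provided.
    ``simulate`` is ``"fixture"`` or a :class:`CohortConfig`.
    """

    patients_path: str | None = None
    events_path: str | None = None
    abstraction_path: str | None = None
    simulate: str | CohortConfig | None = None
    ci_method: str = "clopper_pearson"
    strata: str | None = None
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        paths = (self.patients_path, self.events_path, self.abstraction_path)
        has_paths = any(p is not None for p in paths)
        if has_paths and any(p is None for p in paths):
            raise ValueError("patients, events and abstraction paths must be given together")
        if has_paths == (self.simulate is not None):
            raise ValueError("exactly one of input paths or a simulation config is required")

    def fingerprint(self) -> str:
        payload = dataclasses.asdict(self)
        if isinstance(self.simulate, CohortConfig):
            payload["simulate"] = dataclasses.asdict(self.simulate)
            payload["simulate"] = json.loads(json.dumps(payload["simulate"], default=str))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _estimate_dict(est: MetricEstimate) -> dict[str, Any]:
    return {
        "numerator": est.numerator,
        "denominator": est.denominator,
        "point": est.point,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "display_percent": est.display_percent(),
        "display_ci_percent": (
            [
                int(round_half_up(100 * est.ci_low)),
                int(round_half_up(100 * est.ci_high)),
            ]
            if est.defined
            else None
        ),
    }


def _concordance_dict(c: ConcordanceResult | None) -> dict[str, Any] | None:
    if c is None:
        return None
    po_disp, kappa_disp = c.display(2)
    return {
        "n": c.n,
        "observed_agreement": c.observed_agreement,
        "expected_agreement": c.expected_agreement,
        "kappa": c.kappa,
        "observed_agreement_display": po_disp,
        "kappa_display": kappa_disp,
        "category_convention": c.category_convention,
    }


def report_to_dict(report: ValidationReport) -> dict[str, Any]:
    crosstab = {
        "rows": list(map(str, report.crosstab.counts.index)),
        "columns": list(map(str, report.crosstab.counts.columns)),
        "counts": report.crosstab.counts.to_numpy().tolist(),
        "n": report.crosstab.n,
    }
    per_side = {}
    for name, (tbl, acc) in report.per_side.items():
        per_side[name] = {
            "tp": tbl.tp,
            "fp": tbl.fp,
            "fn": tbl.fn,
            "tn": tbl.tn,
            "sensitivity": _estimate_dict(acc.sensitivity),
            "specificity": _estimate_dict(acc.specificity),
            "ppv": _estimate_dict(acc.ppv),
            "npv": _estimate_dict(acc.npv),
        }
    return {
        "crosstab": crosstab,
        "per_side": per_side,
        "concordance": _concordance_dict(report.concordance),
        "restricted_concordance": _concordance_dict(report.restricted),
        "ci_method": report.ci_method,
    }


def _md_table(headers: list[str], rows: list[list[Any]]) -> str:
    def fmt(v: Any) -> str:
        return "" if v is None else str(v)

    lines = [
        "| " + " | ".join(headers) + " |",
        "| " + " | ".join("---" for _ in headers) + " |",
    ]
    lines += ["| " + " | ".join(fmt(v) for v in row) + " |" for row in rows]
    return "\n".join(lines)


def render_markdown(result: dict[str, Any]) -> str:
    """Human-readable report from the JSON payload."""
    pooled = result["pooled"]
    ct = pooled["crosstab"]
    out = ["# Sidedness validation report", ""]
    out.append(f"- patients: {ct['n']}")
    out.append(f"- seed: {result['config']['seed']}")
    out.append(f"- CI method: {pooled['ci_method']}")
    out.append(f"- config fingerprint: {result['config']['fingerprint']}")
    out.append("")
    out.append("## Assigned vs abstracted side")
    out.append("")
    rows = [
        [r] + counts + [sum(counts)]
        for r, counts in zip(ct["rows"], ct["counts"])
    ]
    col_totals = [sum(c[j] for c in ct["counts"]) for j in range(len(ct["columns"]))]
    rows.append(["Total"] + col_totals + [ct["n"]])
    out.append(_md_table(["Assigned \\ Abstracted"] + ct["columns"] + ["Total"], rows))
    out.append("")
    out.append("## Accuracy of the ICD assignment, % (95% CI)")
    out.append("")
    sides = list(pooled["per_side"])
    acc_rows = []
    for metric in ("sensitivity", "specificity", "ppv", "npv"):
        row = [metric]
        for s in sides:
            m = pooled["per_side"][s][metric]
            if m["display_percent"] is None:
                row.append("undefined")
            else:
                lo, hi = m["display_ci_percent"]
                row.append(f"{m['display_percent']} ({lo}, {hi})")
        acc_rows.append(row)
    out.append(_md_table(["Metric"] + sides, acc_rows))
    out.append("")
    conc = pooled["concordance"]
    out.append("## Concordance")
    out.append("")
    out.append(
        f"- observed agreement {conc['observed_agreement_display']:.2f} "
        f"(kappa = {conc['kappa_display']:.2f}) over n={conc['n']}"
    )
    rc = pooled["restricted_concordance"]
    if rc is not None:
        out.append(
            f"- side-specific assignments only (UNSPECIFIED/RECTUM removed): "
            f"observed agreement {rc['observed_agreement_display']:.2f} "
            f"(kappa = {rc['kappa_display']:.2f}) over n={rc['n']}"
        )
    share = result.get("specific_code_share")
    if share is not None:
        out.append(f"- share of patients with a side-specific assignment: {share:.3f}")
    out.append("")
    return "\n".join(out)


def run_validation(config: RunConfig) -> dict[str, Any]:
    """Execute simulate/load -> assign -> validate -> report.

    Writes ``report.json`` and ``report.md`` under ``config.out_dir``
    and returns the JSON payload.
    """
    dataset: ValidationDataset | None = None
    if config.simulate is not None:
        if config.simulate == "fixture":
            dataset = reconstruct_fixture(config.seed)
        elif isinstance(config.simulate, CohortConfig):
            dataset = sample_cohort(config.simulate)
        else:
            raise ValueError(f"unknown simulation spec {config.simulate!r}")
        timelines = dataset.patients
        gold = dataset.abstraction
        demographics = dataset.demographics
        excluded: list[str] = []
    else:
        loaded = read_tables(
            config.patients_path, config.events_path, config.abstraction_path
        )
        timelines, gold = loaded.timelines, loaded.gold
        demographics = loaded.demographics
        excluded = loaded.excluded_events

    logger.info(
        "run %s: %d patients, %d abstraction labels, seed=%d",
        config.fingerprint(),
        len(timelines),
        len(gold),
        config.seed,
    )
    assigned = {tl.patient_id: assign_side(tl) for tl in timelines}

    result: dict[str, Any] = {
        "config": {
            "patients_path": config.patients_path,
            "events_path": config.events_path,
            "abstraction_path": config.abstraction_path,
            "simulate": (
                "fixture"
                if config.simulate == "fixture"
                else ("cohort" if config.simulate is not None else None)
            ),
            "ci_method": config.ci_method,
            "strata": config.strata,
            "seed": config.seed,
            "fingerprint": config.fingerprint(),
        },
        "n_patients": len(timelines),
        "n_events": sum(len(tl.events) for tl in timelines),
        "n_excluded_events": len(excluded),
        "assignments": {pid: a.label for pid, a in assigned.items()},
        "specific_code_share": specific_code_share(assigned),
    }

    if config.strata:
        if config.strata not in demographics.columns:
            raise KeyError(f"unknown stratum variable {config.strata!r}")
        strata = dict(
            zip(demographics["patient_id"].astype(str), demographics[config.strata].astype(str))
        )
        reports = stratified_validate(assigned, gold, strata, config.ci_method)
        result["pooled"] = report_to_dict(reports["pooled"])
        result["strata"] = {
            k: report_to_dict(v) for k, v in reports.items() if k != "pooled"
        }
    else:
        result["pooled"] = report_to_dict(validate(assigned, gold, config.ci_method))

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    (out_dir / "report.md").write_text(render_markdown(result))
    logger.info("report written to %s", out_dir)
    return result
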