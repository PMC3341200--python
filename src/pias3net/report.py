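"""Machine-readable reports for experiment batches and sensitivity runs."""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Mapping

from .config import RunConfig
from .experiments import ExperimentResult
from .params import CoreParameters
from .sensitivity import SensitivityResult

__all__ = ["build_report", "write_report", "validate_report", "REPORT_SCHEMA"]

#: Minimal structural schema for an experiment-batch report.
REPORT_SCHEMA: dict = {
    "required": ["config", "parameters", "n_experiments", "n_passed",
                 "failed_ids", "experiments", "timestamp"],
    "experiment_required": ["id", "passed", "errored", "readouts", "clauses"],
}


def build_report(
    results: Mapping[int, ExperimentResult],
    params: CoreParameters,
    config: RunConfig | None = None,
) -> dict:
    """Assemble the reproducibility report for one experiment batch.

    Embeds the fully resolved parameter set, the run configuration
    (including the seed) and per-clause diagnostics for every experiment.
    """
    config = config or RunConfig()
    experiments = []
    for eid in sorted(results):
        r = results[eid]
        experiments.append({
            "id": eid,
            "passed": bool(r.passed),
            "errored": r.errored,
            "error": r.error,
            "readouts": {k: float(v) for k, v in r.readouts.items()},
            "clauses": r.clauses,
        })
    failed = [e["id"] for e in experiments if not e["passed"]]
    return {
        "config": config.to_dict(),
        "parameters": params.to_dict(),
        "n_experiments": len(experiments),
        "n_passed": sum(e["passed"] for e in experiments),
        "failed_ids": failed,
        "experiments": experiments,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def validate_report(report: dict) -> None:
    """Raise ``ValueError`` if the report does not match the shipped schema."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for exp in report["experiments"]:
        for key in REPORT_SCHEMA["experiment_required"]:
            if key not in exp:
                raise ValueError(f"experiment entry missing key {key!r}")
    if report["n_passed"] != sum(e["passed"] for e in report["experiments"]):
        raise ValueError("n_passed inconsistent with experiment entries")


def write_report(
    results: Mapping[int, ExperimentResult],
    params: CoreParameters,
    path: str | Path,
    config: RunConfig | None = None,
    sensitivity: SensitivityResult | None = None,
) -> dict:
    """Write the JSON report (and CSV sensitivity matrices alongside it)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report = build_report(results, params, config)
    validate_report(report)
    path.write_text(json.dumps(report, indent=2) + "\n")
    if sensitivity is not None:
        stem = path.with_suffix("")
        for name, frame in sensitivity.to_frames().items():
            frame.to_csv(f"{stem}_{name}.csv")
    return report
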