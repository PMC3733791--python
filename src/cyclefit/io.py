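"""CSV dataset I/O and JSON serialization of results, ensembles and reports.

JSON documents carry a ``schema_version`` field.  Floats are serialized via
Python's shortest round-trip repr, and keys are sorted, so writing the same
object twice yields byte-identical files and reading one back reconstructs
an equal object.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .bootstrap import BootstrapEnsemble, BootstrapTrial, IdentifiabilityReport
from .collocation import EstimateResult
from .data import TimeSeriesDataset
from .errors import ArgumentError

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_results",
    "read_result",
    "read_ensemble",
    "read_report",
]

SCHEMA_VERSION = 1


def read_dataset(path: str | Path) -> TimeSeriesDataset:
    """Read a dataset CSV: ``time`` column plus ``<state>_mean``/``<state>_std``.

    Validation failures report the offending columns/rows.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ArgumentError(f"cannot parse {path}: {exc}") from exc
    if "time" not in frame.columns:
        raise ArgumentError(f"{path}: missing required 'time' column")
    bad_cols = []
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad_rows = frame.index[coerced.isna() & frame[col].notna()].tolist()
            bad_cols.append(f"{col} (rows {bad_rows[:5]})")
    if bad_cols:
        raise ArgumentError(f"{path}: non-numeric cells in column(s) {bad_cols}")
    for col in frame.columns:
        if col.endswith("_std"):
            vals = frame[col].to_numpy(float)
            bad = np.where(~np.isnan(vals) & (vals <= 0))[0]
            if bad.size:
                raise ArgumentError(
                    f"{path}: non-positive sigma in column {col!r} "
                    f"at row(s) {bad[:5].tolist()}"
                )
    try:
        return TimeSeriesDataset.from_frame(frame)
    except ArgumentError as exc:
        raise ArgumentError(f"{path}: {exc}") from exc


def write_dataset(dataset: TimeSeriesDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# JSON result documents
# ---------------------------------------------------------------------------


def _dump(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def _load(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if "schema_version" not in doc:
        raise ArgumentError(f"{path}: missing schema_version")
    return doc


def _result_doc(result: EstimateResult) -> dict:
    return {
        "kind": "estimate_result",
        "schema_version": SCHEMA_VERSION,
        "params": dict(zip(result.param_names or [], map(float, result.p_star))),
        "param_names": list(result.param_names or []),
        "state_names": list(result.state_names or []),
        "period": result.period,
        "cost": result.cost,
        "status": result.status,
        "n_iterations": result.n_iterations,
        "phase_grid": None if result.phase_grid is None else result.phase_grid.tolist(),
        "phase_trajectory": (
            None if result.phase_trajectory is None else result.phase_trajectory.tolist()
        ),
    }


def _result_from_doc(doc: dict) -> EstimateResult:
    names = doc["param_names"]
    return EstimateResult(
        p_star=np.array([doc["params"][n] for n in names]),
        period=doc["period"],
        cost=doc["cost"],
        status=doc["status"],
        n_iterations=doc["n_iterations"],
        phase_grid=None if doc["phase_grid"] is None else np.array(doc["phase_grid"]),
        phase_trajectory=(
            None if doc["phase_trajectory"] is None
            else np.array(doc["phase_trajectory"])
        ),
        param_names=names,
        state_names=doc["state_names"],
    )


def _ensemble_doc(ens: BootstrapEnsemble) -> dict:
    return {
        "kind": "bootstrap_ensemble",
        "schema_version": SCHEMA_VERSION,
        "n_requested": ens.n_requested,
        "n_failed": ens.n_failed,
        "n_steady": ens.n_steady,
        "master_seed": ens.master_seed,
        "param_names": list(ens.param_names),
        "state_names": list(ens.state_names),
        "phase_grid": ens.phase_grid.tolist(),
        "trials": [
            {
                "index": t.index,
                "params": t.params.tolist(),
                "period": t.period,
                "cost": t.cost,
                "n_iterations": t.n_iterations,
                "sensitivities": [
                    None if np.isnan(v) else float(v) for v in t.sensitivities
                ],
                "phase_trajectory": t.phase_trajectory.tolist(),
            }
            for t in ens.results
        ],
    }


def _ensemble_from_doc(doc: dict) -> BootstrapEnsemble:
    trials = [
        BootstrapTrial(
            index=t["index"],
            params=np.array(t["params"]),
            period=t["period"],
            cost=t["cost"],
            n_iterations=t["n_iterations"],
            sensitivities=np.array(
                [np.nan if v is None else v for v in t["sensitivities"]]
            ),
            phase_trajectory=np.array(t["phase_trajectory"]),
        )
        for t in doc["trials"]
    ]
    return BootstrapEnsemble(
        results=trials,
        n_requested=doc["n_requested"],
        n_failed=doc["n_failed"],
        n_steady=doc["n_steady"],
        master_seed=doc["master_seed"],
        param_names=doc["param_names"],
        state_names=doc["state_names"],
        phase_grid=np.array(doc["phase_grid"]),
    )


def _report_doc(report: IdentifiabilityReport) -> dict:
    def _nanlist(arr):
        return [None if np.isnan(v) else float(v) for v in np.asarray(arr).ravel()]

    return {
        "kind": "identifiability_report",
        "schema_version": SCHEMA_VERSION,
        "param_names": list(report.param_names),
        "level": report.level,
        "n_results": report.n_results,
        "low_power": report.low_power,
        "quantile_probs": list(report.quantile_probs),
        "param_quantiles": report.param_quantiles.tolist(),
        "param_medians": report.param_medians.tolist(),
        "sens_quantiles": [_nanlist(row) for row in report.sens_quantiles],
        "sens_medians": _nanlist(report.sens_medians),
        "sign_consistent_fraction": report.sign_consistent_fraction.tolist(),
        "identifiable": report.identifiable.tolist(),
        "identifiable_interval": report.identifiable_interval.tolist(),
    }


def _report_from_doc(doc: dict) -> IdentifiabilityReport:
    def _nanarr(values):
        return np.array(
            [np.nan if v is None else v for v in values], dtype=float
        )

    return IdentifiabilityReport(
        param_names=doc["param_names"],
        level=doc["level"],
        n_results=doc["n_results"],
        low_power=doc["low_power"],
        param_quantiles=np.array(doc["param_quantiles"]),
        param_medians=np.array(doc["param_medians"]),
        sens_quantiles=np.vstack([_nanarr(r) for r in doc["sens_quantiles"]]),
        sens_medians=_nanarr(doc["sens_medians"]),
        sign_consistent_fraction=np.array(doc["sign_consistent_fraction"]),
        identifiable=np.array(doc["identifiable"], dtype=bool),
        identifiable_interval=np.array(doc["identifiable_interval"], dtype=bool),
        quantile_probs=tuple(doc["quantile_probs"]),
    )


def write_results(obj: Any, path: str | Path) -> None:
    """Serialize an EstimateResult, BootstrapEnsemble or IdentifiabilityReport."""
    if isinstance(obj, EstimateResult):
        _dump(_result_doc(obj), path)
    elif isinstance(obj, BootstrapEnsemble):
        _dump(_ensemble_doc(obj), path)
    elif isinstance(obj, IdentifiabilityReport):
        _dump(_report_doc(obj), path)
    else:
        raise ArgumentError(f"cannot serialize object of type {type(obj).__name__}")


def read_result(path: str | Path) -> EstimateResult:
    doc = _load(path)
    if doc.get("kind") != "estimate_result":
        raise ArgumentError(f"{path} is not an estimate result document")
    return _result_from_doc(doc)


def read_ensemble(path: str | Path) -> BootstrapEnsemble:
    doc = _load(path)
    if doc.get("kind") != "bootstrap_ensemble":
        raise ArgumentError(f"{path} is not a bootstrap ensemble document")
    return _ensemble_from_doc(doc)


def read_report(path: str | Path) -> IdentifiabilityReport:
    doc = _load(path)
    if doc.get("kind") != "identifiability_report":
        raise ArgumentError(f"{path} is not an identifiability report document")
    return _report_from_doc(doc)
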