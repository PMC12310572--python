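"""Standardized CSV/JSON output writing with embedded provenance."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .params import ValidationError
from .scenarios import ScenarioSet
from .simulate import MultiStartResult, TrajectoryRecord
from .stability import EquilibriumReport, StabilityReport
from .sweeps import SweepResult

__all__ = ["to_jsonable", "write_report", "read_report"]


def to_jsonable(result: Any, seed: int | None = None) -> dict:
    """Convert a result object to a JSON-serializable dict with provenance."""
    meta: dict[str, Any] = {"tool": "trigov", "version": __version__}
    if seed is not None:
        meta["seed"] = seed

    if isinstance(result, TrajectoryRecord):
        body = {
            "kind": "trajectory",
            "params": result.params.to_dict(),
            "initial": list(result.initial),
            "settings": {
                "horizon": result.settings.horizon,
                "rel_tol": result.settings.rel_tol,
                "abs_tol": result.settings.abs_tol,
                "convergence_radius": result.settings.convergence_radius,
                "max_extension": result.settings.max_extension,
            },
            "converged": result.converged,
            "limit_vertex": result.limit_vertex.label if result.limit_vertex else None,
            "final_state": [float(v) for v in result.final_state],
            "times": result.times.tolist(),
            "states": result.states.tolist(),
        }
    elif isinstance(result, (StabilityReport, SweepResult, ScenarioSet, MultiStartResult)):
        body = {"kind": type(result).__name__, **result.to_dict()}
    elif isinstance(result, EquilibriumReport):
        body = {"kind": "EquilibriumReport", **result.to_dict()}
    elif isinstance(result, dict):
        body = {"kind": "mapping"}
        for key, value in result.items():
            body[key] = to_jsonable(value) if hasattr(value, "to_dict") else value
    else:
        raise ValidationError(f"do not know how to serialize {type(result).__name__}")
    body["meta"] = meta
    return body


def write_report(result: Any, format: str, path: str | Path, seed: int | None = None) -> Path:
    """Serialize a result to ``path`` as CSV or JSON; returns the path.

    JSON reports round-trip: reading one back reproduces the in-memory
    values to full float precision (floats are written with repr precision).
    """
    path = Path(path)
    try:
        if format == "json":
            with open(path, "w") as handle:
                json.dump(to_jsonable(result, seed=seed), handle, indent=1)
        elif format == "csv":
            _write_csv(result, path)
        else:
            raise ValidationError(f"unknown report format {format!r} (csv or json)")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return path


def _write_csv(result: Any, path: Path) -> None:
    if isinstance(result, TrajectoryRecord):
        frame = pd.DataFrame(result.to_rows(), columns=["t", "x", "y", "z"])
    elif isinstance(result, SweepResult):
        frame = result.to_dataframe()
    elif isinstance(result, StabilityReport):
        frame = pd.DataFrame(
            {
                "label": [r.profile.label for r in result.reports],
                "x": [r.profile.coordinates[0] for r in result.reports],
                "y": [r.profile.coordinates[1] for r in result.reports],
                "z": [r.profile.coordinates[2] for r in result.reports],
                "lambda1": [r.eigenvalues[0] for r in result.reports],
                "lambda2": [r.eigenvalues[1] for r in result.reports],
                "lambda3": [r.eigenvalues[2] for r in result.reports],
                "classification": [r.classification for r in result.reports],
            }
        )
    else:
        raise ValidationError(f"no CSV schema for {type(result).__name__}")
    frame.to_csv(path, index=False, float_format="%.17g")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as handle:
        return json.load(handle)
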