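"""One-parameter sensitivity sweeps over the replicator simulation.

A sweep replaces one game constant by each value in a list, integrates from
a common initial state, and records where (and how fast) each run settles.
The standard six-sweep suite varies the policy levers of the model --
subsidy, fine, remediation cost, regulatory cost, reasonable-treatment
income, and overtreatment income -- against the reasonable-treatment-stable
base scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PARAM_NAMES, ConfigurationError, GameParameters, StrategyState
from .simulate import SimulationSettings, TrajectoryRecord, first_entry_time, integrate

__all__ = [
    "SweepSpec",
    "SweepRecord",
    "SweepResult",
    "sweep_parameter",
    "relative_increment_scenarios",
    "run_sensitivity_suite",
    "SUITE_VALUES",
]


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep: base parameters, symbol, values, start, protocol."""

    base_params: GameParameters
    swept_name: str
    values: tuple[float, ...]
    initial: StrategyState = StrategyState(0.5, 0.5, 0.5)
    settings: SimulationSettings = SimulationSettings()

    def __post_init__(self) -> None:
        if self.swept_name not in PARAM_NAMES:
            raise ConfigurationError(
                f"unknown sweep symbol {self.swept_name!r}; expected one of {PARAM_NAMES}"
            )
        values = tuple(float(v) for v in self.values)
        if not values:
            raise ConfigurationError("sweep value list must be non-empty")
        if any(v < 0 or not math.isfinite(v) for v in values):
            raise ConfigurationError("sweep values must be nonnegative finite reals")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class SweepRecord:
    """Outcome of one swept value."""

    value: float
    converged: bool
    limit_vertex: str | None
    entry_time: float  # first entry into the convergence radius; inf if never
    final_state: tuple[float, float, float]
    trajectory: TrajectoryRecord | None = None


@dataclass(frozen=True)
class SweepResult:
    """Per-value records, in input order, plus the spec they came from."""

    spec: SweepSpec
    records: tuple[SweepRecord, ...] = field(default_factory=tuple)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "swept_name": self.spec.swept_name,
                "value": [r.value for r in self.records],
                "converged": [r.converged for r in self.records],
                "limit_vertex": [r.limit_vertex for r in self.records],
                "entry_time": [r.entry_time for r in self.records],
            }
        )

    def to_dict(self) -> dict:
        return {
            "swept_name": self.spec.swept_name,
            "base_params": self.spec.base_params.to_dict(),
            "initial": list(self.spec.initial),
            "records": [
                {
                    "value": r.value,
                    "converged": r.converged,
                    "limit_vertex": r.limit_vertex,
                    "entry_time": r.entry_time,
                    "final_state": list(r.final_state),
                }
                for r in self.records
            ],
        }


def sweep_parameter(spec: SweepSpec, keep_trajectories: bool = False) -> SweepResult:
    """Run the sweep: one integration per value, outcomes in input order."""
    records = []
    for value in spec.values:
        params = spec.base_params.replace(**{spec.swept_name: value})
        traj = integrate(params, spec.initial, spec.settings)
        records.append(
            SweepRecord(
                value=value,
                converged=traj.converged,
                limit_vertex=traj.limit_vertex.label if traj.limit_vertex else None,
                entry_time=first_entry_time(traj),
                final_state=tuple(float(v) for v in traj.final_state),
                trajectory=traj if keep_trajectories else None,
            )
        )
    return SweepResult(spec=spec, records=tuple(records))


def relative_increment_scenarios(
    base_params: GameParameters,
    name: str,
    fractions: tuple[float, ...],
    initial: StrategyState = StrategyState(0.5, 0.5, 0.5),
    settings: SimulationSettings = SimulationSettings(),
) -> SweepResult:
    """Sweep ``name`` over ``base * (1 + fraction)`` for each fraction.

    Used for percentage fine-increment experiments (e.g. +5%/+10%/+15%).
    Fractions at or below -1 would produce negative values and are rejected.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= -1 for f in fractions):
        raise ConfigurationError("increment fractions must each be > -1")
    base_value = getattr(base_params, name) if name in PARAM_NAMES else None
    if base_value is None:
        raise ConfigurationError(f"unknown sweep symbol {name!r}")
    values = tuple(base_value * (1 + f) for f in fractions)
    return sweep_parameter(
        SweepSpec(base_params, name, values, initial=initial, settings=settings)
    )


#: The standard six sensitivity sweeps (symbol -> values).  The fine sweep
#: varies the fine Gf by default; passing ``fine_symbol="Pg"`` reproduces the
#: credibility-symbol variant instead.  Note the fine Gf does not enter the
#: regulator's own advantage function, so fines act on institutions and
#: patients but cannot move the regulator's strategy in this model.
SUITE_VALUES: dict[str, tuple[float, ...]] = {
    "Gs": (5.0, 10.0, 15.0),
    "fine": (20.0, 150.0, 300.0),
    "Gg": (50.0, 150.0, 200.0),
    "Cr": (40.0, 100.0, 150.0),
    "Wt": (4.0, 8.0, 12.0),
    "Wm": (15.0, 10.0, 5.0),
}


def run_sensitivity_suite(
    base_params: GameParameters | None = None,
    initial: StrategyState = StrategyState(0.5, 0.5, 0.5),
    settings: SimulationSettings = SimulationSettings(),
    fine_symbol: str = "Gf",
) -> dict[str, SweepResult]:
    """Run the six standard sweeps against the base scenario.

    Defaults to the reasonable-treatment-stable base (the Wt=7 variant of
    the printed parameter set), in which (0,1,0) is the unique ESS.
    """
    if base_params is None:
        from .scenarios import baseline_scenarios

        _, base_params, _ = baseline_scenarios()
    if fine_symbol not in ("Gf", "Pg"):
        raise ConfigurationError("fine_symbol must be 'Gf' or 'Pg'")
    results: dict[str, SweepResult] = {}
    for key, values in SUITE_VALUES.items():
        symbol = fine_symbol if key == "fine" else key
        results[symbol] = sweep_parameter(
            SweepSpec(base_params, symbol, values, initial=initial, settings=settings)
        )
    return results
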