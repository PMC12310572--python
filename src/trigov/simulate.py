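"""Numerical integration of the replicator system and convergence detection.

Trajectories live in the unit cube; the cube's faces are invariant, so an
exact solution started inside stays inside.  The adaptive solver can
overshoot a face by an amount on the order of its absolute tolerance --
those excursions are clamped back, while anything larger is treated as a
bug in the supplied field and raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model import make_rhs
from .params import GameParameters, StrategyState, ValidationError
from .stability import PURE_PROFILES, PureProfile

__all__ = [
    "SimulationSettings",
    "TrajectoryRecord",
    "IntegrationError",
    "integrate",
    "detect_convergence",
    "first_entry_time",
    "multi_start",
    "MultiStartResult",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid state if one exists."""

    def __init__(self, message: str, last_state: Optional[np.ndarray] = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class SimulationSettings:
    """Integration protocol.

    horizon            : final (unitless) time, default 50 -- the study's
                         fixed evolution window.
    rel_tol, abs_tol   : adaptive solver tolerances.
    convergence_radius : max-norm distance to a vertex counting as converged.
    max_extension      : number of horizon doublings allowed when the
                         trajectory is still drifting at the horizon
                         (0 keeps the fixed window).
    n_saved            : size of the uniform output time grid per window.
    """

    horizon: float = 50.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    convergence_radius: float = 1e-3
    max_extension: int = 0
    n_saved: int = 1001

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValidationError(f"horizon must be positive, got {self.horizon!r}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValidationError("solver tolerances must be positive")
        if not 0.0 < self.convergence_radius < 0.5:
            raise ValidationError(
                f"convergence_radius must lie in (0, 0.5), got {self.convergence_radius!r}"
            )
        if self.max_extension < 0 or self.n_saved < 2:
            raise ValidationError("max_extension must be >= 0 and n_saved >= 2")


@dataclass(frozen=True)
class TrajectoryRecord:
    """A solved trajectory with its convergence verdict."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3), columns x, y, z
    converged: bool
    limit_vertex: Optional[PureProfile]
    params: GameParameters
    settings: SimulationSettings
    initial: StrategyState

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_rows(self):
        """Rows (t, x, y, z) for CSV export."""
        return np.column_stack([self.times, self.states])


def _nearest_vertex(state: np.ndarray) -> tuple[PureProfile, float]:
    best, best_dist = None, math.inf
    for profile in PURE_PROFILES.values():
        dist = float(np.max(np.abs(state - profile.as_array())))
        if dist < best_dist:
            best, best_dist = profile, dist
    return best, best_dist


def detect_convergence(
    traj: "TrajectoryRecord | np.ndarray", radius: float
) -> Optional[PureProfile]:
    """Vertex within max-norm ``radius`` of the final state, else ``None``.

    Radii of 0.5 or more would make two vertices eligible at once and are
    rejected.
    """
    if radius >= 0.5:
        raise ValidationError(f"ambiguous convergence radius {radius!r} (must be < 0.5)")
    state = traj.final_state if isinstance(traj, TrajectoryRecord) else np.asarray(traj, float)
    vertex, dist = _nearest_vertex(state)
    return vertex if dist <= radius else None


def integrate(
    params: GameParameters,
    initial: StrategyState,
    settings: SimulationSettings = SimulationSettings(),
) -> TrajectoryRecord:
    """Adaptive-step integration of the replicator field over [0, horizon].

    States are clamped to the cube after solving; a clamp larger than
    ``10 * (abs_tol + rel_tol)`` raises :class:`IntegrationError`, since
    face invariance bounds legitimate round-off excursions by the solver's
    local error scale ``atol + rtol * |y|`` (|y| <= 1 here).  If the
    trajectory has not entered the convergence radius at the horizon and
    ``max_extension > 0``, the window is doubled (continuing from the last
    state) up to that many times.
    """
    rhs = make_rhs(params)
    slack = 10.0 * (settings.abs_tol + settings.rel_tol)

    times_acc: list[np.ndarray] = []
    states_acc: list[np.ndarray] = []
    t0, s0 = 0.0, initial.as_array()
    horizon = settings.horizon
    for extension in range(settings.max_extension + 1):
        t_eval = np.linspace(t0, horizon, settings.n_saved)
        sol = solve_ivp(
            rhs, (t0, horizon), s0, method="RK45",
            rtol=settings.rel_tol, atol=settings.abs_tol, t_eval=t_eval,
        )
        if not sol.success:
            last = sol.y[:, -1] if sol.y.size else s0
            raise IntegrationError(f"solver failed: {sol.message}", last_state=last)
        states = sol.y.T
        excess = max(float(np.max(-states, initial=0.0)),
                     float(np.max(states - 1.0, initial=0.0)))
        if excess > slack:
            raise IntegrationError(
                f"state left the unit cube by {excess:.3e} "
                "(> 10*(abs_tol+rel_tol)); the supplied field violates face "
                "invariance",
                last_state=states[-1],
            )
        states = np.clip(states, 0.0, 1.0)
        skip = 1 if times_acc else 0  # drop duplicated junction point
        times_acc.append(sol.t[skip:])
        states_acc.append(states[skip:])
        limit = detect_convergence(states[-1], settings.convergence_radius)
        if limit is not None or extension == settings.max_extension:
            break
        t0, s0 = horizon, states[-1]
        horizon *= 2.0

    times = np.concatenate(times_acc)
    states = np.concatenate(states_acc)
    limit = detect_convergence(states[-1], settings.convergence_radius)
    return TrajectoryRecord(
        times=times,
        states=states,
        converged=limit is not None,
        limit_vertex=limit,
        params=params,
        settings=settings,
        initial=initial,
    )


def first_entry_time(traj: TrajectoryRecord, radius: Optional[float] = None) -> float:
    """First time the trajectory enters the convergence ball of its limit.

    Linearly interpolates the max-norm distance between saved steps; returns
    ``inf`` for an unconverged trajectory.
    """
    if traj.limit_vertex is None:
        return math.inf
    radius = traj.settings.convergence_radius if radius is None else radius
    dist = np.max(np.abs(traj.states - traj.limit_vertex.as_array()), axis=1)
    inside = dist <= radius
    if not inside.any():
        return math.inf
    i = int(np.argmax(inside))
    if i == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    d0, d1 = dist[i - 1], dist[i]
    if d0 == d1:
        return float(t1)
    return float(t0 + (d0 - radius) / (d0 - d1) * (t1 - t0))


@dataclass(frozen=True)
class MultiStartResult:
    """Batch of trajectories from an interior lattice, with basin counts."""

    trajectories: tuple[TrajectoryRecord, ...]
    basin_counts: dict[str, int]
    unconverged: int
    failures: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "basin_counts": dict(self.basin_counts),
            "unconverged": self.unconverged,
            "n_trajectories": len(self.trajectories),
            "failures": list(self.failures),
        }


def interior_lattice(points_per_axis: int) -> list[StrategyState]:
    """Lattice of initial states strictly inside the cube.

    Coordinates ``(2i+1)/(2n)`` keep every point off the invariant faces;
    one point per axis degenerates to the cube center (0.5, 0.5, 0.5).
    """
    if points_per_axis < 1:
        raise ValidationError("points_per_axis must be >= 1")
    coords = [(2 * i + 1) / (2 * points_per_axis) for i in range(points_per_axis)]
    return [
        StrategyState(a, b, c)
        for a in coords for b in coords for c in coords
    ]


def multi_start(
    params: GameParameters,
    lattice_points_per_axis: int,
    settings: SimulationSettings = SimulationSettings(),
) -> MultiStartResult:
    """Integrate from every interior lattice point and tabulate basins.

    Per-trajectory solver failures are collected rather than aborting the
    batch.
    """
    trajectories: list[TrajectoryRecord] = []
    failures: list[str] = []
    counts: dict[str, int] = {}
    unconverged = 0
    for start in interior_lattice(lattice_points_per_axis):
        try:
            traj = integrate(params, start, settings)
        except IntegrationError as exc:
            failures.append(f"start {tuple(start)}: {exc}")
            continue
        trajectories.append(traj)
        if traj.limit_vertex is None:
            unconverged += 1
        else:
            counts[traj.limit_vertex.label] = counts.get(traj.limit_vertex.label, 0) + 1
    return MultiStartResult(
        trajectories=tuple(trajectories),
        basin_counts=counts,
        unconverged=unconverged,
        failures=tuple(failures),
    )
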