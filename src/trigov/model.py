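"""Expected payoffs, advantage functions, and the replicator vector field.

Each population chooses between two actions:

* patients: recognize / not recognize treatment outcomes (frequency ``x``);
* institutions: reasonable treatment / overtreatment (frequency ``y``);
* regulators: strict / loose supervision (frequency ``z``).

A population's *advantage function* is the expected-payoff difference between
its two actions given the other two populations' current frequencies.  Under
replicator dynamics each frequency ``s`` evolves as ``ds/dt = s(1-s)A(s)``
where ``A`` is that population's advantage: an action spreads through
imitation exactly when it outperforms the within-population alternative.

Two algebraically identical routes to the advantage vector are kept on
purpose.  :func:`expected_payoffs` mixes the pure-action payoff cells by
probability, while :func:`advantage_functions` evaluates the expanded
bilinear polynomials; their agreement is a standing internal check on both
transcriptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import GameParameters, StrategyState

__all__ = [
    "ExpectedPayoffs",
    "AdvantageVector",
    "ReplicatorField",
    "expected_payoffs",
    "advantage_functions",
    "advantage_array",
    "replicator_rhs",
    "make_rhs",
    "make_advantage",
]


@dataclass(frozen=True)
class ExpectedPayoffs:
    """Mixture-weighted expected payoff of each pure action (money units)."""

    patient_recognize: float
    patient_reject: float
    institution_reasonable: float
    institution_overtreat: float
    regulator_strict: float
    regulator_loose: float

    def differences(self) -> tuple[float, float, float]:
        """Advantage of (recognize, reasonable, strict) over the alternative."""
        return (
            self.patient_recognize - self.patient_reject,
            self.institution_reasonable - self.institution_overtreat,
            self.regulator_strict - self.regulator_loose,
        )


@dataclass(frozen=True)
class AdvantageVector:
    """Per-population payoff advantage (Ax, Ay, Az).

    Each component is bilinear in the two *other* populations' frequencies:
    Ax = Ax(y, z), Ay = Ay(x, z), Az = Az(x, y).
    """

    patient: float
    institution: float
    regulator: float

    def as_array(self) -> np.ndarray:
        return np.array([self.patient, self.institution, self.regulator], dtype=float)


@dataclass(frozen=True)
class ReplicatorField:
    """Time derivatives (dx/dt, dy/dt, dz/dt), units 1/time."""

    patient: float
    institution: float
    regulator: float

    def as_array(self) -> np.ndarray:
        return np.array([self.patient, self.institution, self.regulator], dtype=float)


def expected_payoffs(state: StrategyState, params: GameParameters) -> ExpectedPayoffs:
    """Expected payoff of each action, mixing the payoff cells by probability.

    Patients average over (institution, regulator) actions, institutions over
    (patient, regulator), regulators over (patient, institution).  The payoff
    cells follow the game's payoff table; the patient cell for
    (recognize, overtreated, strict supervision) is ``Cp + Ci - Cm``
    (complaint weight plus compensation net of the overtreatment cost).
    """
    p = params
    x, y, z = state

    patient_recognize = (
        y * z * p.Ct
        + y * (1 - z) * (p.Ct - p.Cp - p.Ci)
        + (1 - y) * z * (p.Cp + p.Ci - p.Cm)
        + (1 - y) * (1 - z) * p.Cm
    )
    patient_reject = (
        y * z * (p.Ct + p.Cp + p.Ci)
        + y * (1 - z) * (p.Ct - p.Cp)
        + (1 - y) * z * (p.Cp + p.Ci - p.Cm)
        + (1 - y) * (1 - z) * (-p.Cm - p.Cp - p.Ci)
    )
    institution_reasonable = (
        x * z * (p.Wt + p.Gs + p.Er - p.Oc)
        + x * (1 - z) * (p.Wt + p.Gs + p.Er)
        + (1 - x) * z * (p.Wt + p.Gs + p.Er - p.Oc)
        + (1 - x) * (1 - z) * (p.Wt + p.Gs + p.Er - p.Oc)
    )
    institution_overtreat = (
        x * z * (p.Wm - p.Gf - p.Oc)
        + x * (1 - z) * (p.Wm + p.Gs - p.Oc)
        + (1 - x) * z * (p.Wm - p.Gf - p.Oc)
        + (1 - x) * (1 - z) * (p.Wm - p.Oc)
    )
    regulator_strict = (
        x * y * (p.Eg - p.Cr - p.Gg)
        + x * (1 - y) * (-p.Cr - p.Gg - p.Pg)
        + (1 - x) * y * (p.Eg - p.Cr - p.Gg + p.Pg)
        + (1 - x) * (1 - y) * (p.Pg - p.Cr - p.Gg)
    )
    regulator_loose = (
        x * y * p.Eg
        + x * (1 - y) * p.Pg
        + (1 - x) * y * (p.Eg + p.Pg)
        + (1 - x) * (1 - y) * (-p.Eg - p.Pg)
    )
    return ExpectedPayoffs(
        patient_recognize,
        patient_reject,
        institution_reasonable,
        institution_overtreat,
        regulator_strict,
        regulator_loose,
    )


def _advantage_coefficients(params: GameParameters) -> tuple[tuple[float, ...], ...]:
    """Bilinear coefficients (c0, c1, c2, c12) of each advantage function.

    A(u, v) = c0 + c1*u + c2*v + c12*u*v with (u, v) the two foreign
    frequencies: (y, z) for patients, (x, z) for institutions, (x, y) for
    regulators.  These are the canonical expanded polynomials of the
    replicator system.
    """
    p = params
    ax = (
        p.Ci + 2 * p.Cm + p.Cp,
        -(2 * p.Ci + 2 * p.Cm + p.Cp),
        -(p.Ci + 2 * p.Cm + p.Cp),
        p.Ci + 2 * p.Cm,
    )
    ay = (
        p.Er + p.Gs + p.Wt - p.Wm,
        p.Oc - p.Gs,
        p.Gf,
        p.Gs - p.Oc,
    )
    az = (
        p.Eg - p.Cr - p.Gg + 2 * p.Pg,
        -(p.Eg + 4 * p.Pg),
        -(p.Eg + 2 * p.Pg),
        p.Eg + 4 * p.Pg,
    )
    return ax, ay, az


def advantage_array(s: np.ndarray, params: GameParameters) -> np.ndarray:
    """Vectorized (Ax, Ay, Az) at state array ``s = (x, y, z)``."""
    x, y, z = s
    (ax0, ax1, ax2, ax3), (ay0, ay1, ay2, ay3), (az0, az1, az2, az3) = (
        _advantage_coefficients(params)
    )
    return np.array([
        ax0 + ax1 * y + ax2 * z + ax3 * y * z,
        ay0 + ay1 * x + ay2 * z + ay3 * x * z,
        az0 + az1 * x + az2 * y + az3 * x * y,
    ])


def advantage_functions(state: StrategyState, params: GameParameters) -> AdvantageVector:
    """Advantage vector from the canonical expanded bracket polynomials.

    Algebraically identical to ``expected_payoffs(...).differences()``; the
    polynomial route is the one the integrator and stability analysis use.
    """
    a = advantage_array(state.as_array(), params)
    return AdvantageVector(*a)


def replicator_rhs(state: StrategyState, params: GameParameters) -> ReplicatorField:
    """Replicator field F = (x(1-x)Ax, y(1-y)Ay, z(1-z)Az).

    Every face of the cube is invariant: a component at 0 or 1 has zero
    derivative regardless of payoffs, so vertices are always fixed points.
    """
    s = state.as_array()
    return ReplicatorField(*(s * (1.0 - s) * advantage_array(s, params)))


def make_advantage(params: GameParameters) -> Callable[[np.ndarray], np.ndarray]:
    """Closure computing the advantage vector with coefficients precomputed."""
    (ax0, ax1, ax2, ax3), (ay0, ay1, ay2, ay3), (az0, az1, az2, az3) = (
        _advantage_coefficients(params)
    )

    def advantage(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([
            ax0 + ax1 * y + ax2 * z + ax3 * y * z,
            ay0 + ay1 * x + ay2 * z + ay3 * x * z,
            az0 + az1 * x + az2 * y + az3 * x * y,
        ])

    return advantage


def make_rhs(params: GameParameters) -> Callable[[float, np.ndarray], np.ndarray]:
    """ODE right-hand side ``f(t, s)`` for scipy's initial value solvers."""
    advantage = make_advantage(params)

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        return s * (1.0 - s) * advantage(s)

    return rhs
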