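"""Equilibrium and stability analysis of the tripartite replicator system.

Every vertex of the unit cube is a fixed point of the replicator flow.  At a
vertex the Jacobian is diagonal (each off-diagonal entry carries a factor
``s(1-s)`` that vanishes there), so the three diagonal entries are the
eigenvalues and admit closed forms in the fourteen game constants.  The
indirect Lyapunov method then classifies a vertex as an evolutionarily
stable strategy (ESS) exactly when all three eigenvalues are negative.

For strictly positive parameters only two profiles can ever be ESS:

* ``E2 = (1, 0, 0)`` -- patients recognize outcomes, institutions overtreat,
  regulators stay loose -- stable iff ``Wm > Er + Oc + Wt``;
* ``E3 = (0, 1, 0)`` -- institutions treat reasonably under loose
  supervision -- stable iff ``Wm < Gs + Wt + Er``.

The remaining six vertices always carry a positive or zero eigenvalue.
Interior (mixed-strategy) fixed points require all three advantage
functions to vanish simultaneously; a grid-bracketing search with Newton
polishing looks for them, and any root found is re-verified by an
independent solver.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import advantage_array, make_advantage, make_rhs, _advantage_coefficients
from .params import GameParameters, StrategyState, ValidationError

__all__ = [
    "PureProfile",
    "PURE_PROFILES",
    "EquilibriumReport",
    "StabilityReport",
    "FixedPoint",
    "jacobian",
    "vertex_eigenvalues",
    "classify_equilibrium",
    "ess_conditions",
    "enumerate_pure_equilibria",
    "conditionally_stable_profiles",
    "find_interior_fixed_points",
]


@dataclass(frozen=True)
class PureProfile:
    """A pure-strategy profile: a labelled vertex of the unit cube."""

    label: str
    coordinates: tuple[int, int, int]

    def as_array(self) -> np.ndarray:
        return np.array(self.coordinates, dtype=float)


#: The eight pure profiles in conventional order.
PURE_PROFILES: dict[str, PureProfile] = {
    label: PureProfile(label, coords)
    for label, coords in [
        ("E1", (0, 0, 0)),
        ("E2", (1, 0, 0)),
        ("E3", (0, 1, 0)),
        ("E4", (0, 0, 1)),
        ("E5", (1, 1, 0)),
        ("E6", (1, 0, 1)),
        ("E7", (0, 1, 1)),
        ("E8", (1, 1, 1)),
    ]
}

STABLE = "stable (ESS)"
UNSTABLE = "unstable"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class EquilibriumReport:
    """Eigenvalues and Lyapunov classification of one pure profile."""

    profile: PureProfile
    eigenvalues: tuple[float, float, float]
    classification: str
    binding_inequalities: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.profile.label,
            "coordinates": list(self.profile.coordinates),
            "eigenvalues": list(self.eigenvalues),
            "classification": self.classification,
            "inequalities": [
                {"expression": expr, "value": val}
                for expr, val in self.binding_inequalities
            ],
        }


@dataclass(frozen=True)
class StabilityReport:
    """Classification of all eight profiles plus the two headline conditions."""

    reports: tuple[EquilibriumReport, ...]
    e2_condition_holds: bool  # Wm > Er + Oc + Wt
    e3_condition_holds: bool  # Wm < Gs + Wt + Er

    @property
    def stable_labels(self) -> set[str]:
        return {r.profile.label for r in self.reports if r.classification == STABLE}

    def to_dict(self) -> dict:
        return {
            "profiles": [r.to_dict() for r in self.reports],
            "stable_set": sorted(self.stable_labels),
            "E2_condition_Wm_gt_Er+Oc+Wt": self.e2_condition_holds,
            "E3_condition_Wm_lt_Gs+Wt+Er": self.e3_condition_holds,
        }


@dataclass(frozen=True)
class FixedPoint:
    """A root of the replicator field found by the interior search."""

    location: StrategyState
    residual: float
    interior_flag: bool


def jacobian(state: StrategyState | np.ndarray, params: GameParameters) -> np.ndarray:
    """Analytic 3x3 Jacobian of the replicator field at ``state``.

    Diagonal entries are ``(1 - 2s_i) A_i``; off-diagonals carry the factor
    ``s_i(1 - s_i)`` times the partial derivative of the advantage function,
    hence vanish identically at every vertex.
    """
    s = state.as_array() if isinstance(state, StrategyState) else np.asarray(state, dtype=float)
    x, y, z = s
    (_, ax1, ax2, ax3), (_, ay1, ay2, ay3), (_, az1, az2, az3) = (
        _advantage_coefficients(params)
    )
    a = advantage_array(s, params)
    gate = s * (1.0 - s)
    diag = (1.0 - 2.0 * s) * a
    return np.array([
        [diag[0], gate[0] * (ax1 + ax3 * z), gate[0] * (ax2 + ax3 * y)],
        [gate[1] * (ay1 + ay3 * z), diag[1], gate[1] * (ay2 + ay3 * x)],
        [gate[2] * (az1 + az3 * y), gate[2] * (az2 + az3 * x), diag[2]],
    ])


# Closed-form eigenvalues at each vertex, in the diagonal (patient,
# institution, regulator) order.  Each entry pairs a printable expression
# with its evaluator.
_VERTEX_EIGENVALUE_FORMS: dict[str, tuple[tuple[str, ...], object]] = {
    "E1": (
        ("Ci+2*Cm+Cp", "Er+Gs-Wm+Wt", "Eg-Cr-Gg+2*Pg"),
        lambda p: (p.Ci + 2 * p.Cm + p.Cp, p.Er + p.Gs - p.Wm + p.Wt,
                   p.Eg - p.Cr - p.Gg + 2 * p.Pg),
    ),
    "E2": (
        ("-(Ci+2*Cm+Cp)", "Er+Oc-Wm+Wt", "-(Cr+Gg+2*Pg)"),
        lambda p: (-(p.Ci + 2 * p.Cm + p.Cp), p.Er + p.Oc - p.Wm + p.Wt,
                   -(p.Cr + p.Gg + 2 * p.Pg)),
    ),
    "E3": (
        ("-Ci", "Wm-Gs-Er-Wt", "-(Cr+Gg)"),
        lambda p: (-p.Ci, p.Wm - p.Gs - p.Er - p.Wt, -(p.Cr + p.Gg)),
    ),
    "E4": (
        ("0", "Er+Gf+Gs-Wm+Wt", "Cr-Eg+Gg-2*Pg"),
        lambda p: (0.0, p.Er + p.Gf + p.Gs - p.Wm + p.Wt,
                   p.Cr - p.Eg + p.Gg - 2 * p.Pg),
    ),
    "E5": (
        ("Ci", "Wm-Oc-Er-Wt", "-(Cr+Gg)"),
        lambda p: (p.Ci, p.Wm - p.Oc - p.Er - p.Wt, -(p.Cr + p.Gg)),
    ),
    "E6": (
        ("0", "Er+Gf+Gs-Wm+Wt", "Cr+Gg+2*Pg"),
        lambda p: (0.0, p.Er + p.Gf + p.Gs - p.Wm + p.Wt,
                   p.Cr + p.Gg + 2 * p.Pg),
    ),
    "E7": (
        ("-(Ci+Cp)", "Wm-Gf-Gs-Er-Wt", "Cr+Gg"),
        lambda p: (-(p.Ci + p.Cp), p.Wm - p.Gf - p.Gs - p.Er - p.Wt,
                   p.Cr + p.Gg),
    ),
    "E8": (
        ("Ci+Cp", "Wm-Gf-Gs-Er-Wt", "Cr+Gg"),
        lambda p: (p.Ci + p.Cp, p.Wm - p.Gf - p.Gs - p.Er - p.Wt,
                   p.Cr + p.Gg),
    ),
}


def _as_profile(profile: PureProfile | str) -> PureProfile:
    if isinstance(profile, PureProfile):
        return profile
    try:
        return PURE_PROFILES[profile]
    except KeyError:
        raise ValidationError(
            f"unknown pure profile {profile!r}; expected one of {sorted(PURE_PROFILES)}"
        ) from None


def vertex_eigenvalues(
    profile: PureProfile | str, params: GameParameters
) -> tuple[float, float, float]:
    """Closed-form Jacobian eigenvalues at a pure profile.

    Equal (exactly, not just numerically) to the diagonal of
    :func:`jacobian` evaluated at the vertex.
    """
    profile = _as_profile(profile)
    _, evaluate = _VERTEX_EIGENVALUE_FORMS[profile.label]
    return tuple(float(v) for v in evaluate(params))


def classify_equilibrium(
    profile: PureProfile | str, params: GameParameters, tol: float = 1e-9
) -> EquilibriumReport:
    """Lyapunov (indirect-method) classification of a pure profile.

    stable (ESS)   : all eigenvalues < -tol;
    indeterminate  : some eigenvalue within tol of zero (the linearization
                     is inconclusive along that direction; no
                     center-manifold analysis is attempted);
    unstable       : otherwise, i.e. some eigenvalue > +tol and none tied.
    """
    if tol <= 0:
        raise ValidationError(f"tol must be positive, got {tol!r}")
    profile = _as_profile(profile)
    eigenvalues = vertex_eigenvalues(profile, params)
    expressions, _ = _VERTEX_EIGENVALUE_FORMS[profile.label]
    if all(v < -tol for v in eigenvalues):
        classification = STABLE
    elif any(abs(v) <= tol for v in eigenvalues):
        classification = INDETERMINATE
    else:
        classification = UNSTABLE
    return EquilibriumReport(
        profile=profile,
        eigenvalues=eigenvalues,
        classification=classification,
        binding_inequalities=list(zip(expressions, eigenvalues)),
    )


def ess_conditions(params: GameParameters, tol: float = 1e-9) -> StabilityReport:
    """Classify all eight pure profiles and the two headline ESS conditions.

    The closed-form conditions -- E2 stable iff ``Wm > Er + Oc + Wt``, E3
    stable iff ``Wm < Gs + Wt + Er`` -- are cross-checked against the
    eigenvalue classification whenever no eigenvalue sits inside the tie
    tolerance.
    """
    reports = tuple(
        classify_equilibrium(profile, params, tol) for profile in PURE_PROFILES.values()
    )
    e2_margin = params.Wm - (params.Er + params.Oc + params.Wt)
    e3_margin = (params.Gs + params.Wt + params.Er) - params.Wm
    report = StabilityReport(
        reports=reports,
        e2_condition_holds=e2_margin > 0,
        e3_condition_holds=e3_margin > 0,
    )
    by_label = {r.profile.label: r for r in reports}
    for label, margin, holds in [("E2", e2_margin, report.e2_condition_holds),
                                 ("E3", e3_margin, report.e3_condition_holds)]:
        r = by_label[label]
        ties = any(abs(v) <= tol for v in r.eigenvalues)
        # The patient/regulator eigenvalues of E2 and E3 are nonpositive sums
        # of parameters, so for positive parameters the institution condition
        # decides stability on its own.
        if not ties and abs(margin) > tol:
            assert (r.classification == STABLE) == (
                holds and all(v < -tol for v in r.eigenvalues)
            )
    return report


def enumerate_pure_equilibria(
    params: GameParameters, tol: float = 1e-12
) -> list[PureProfile]:
    """Solve F = 0 over the pure profiles by direct evaluation.

    Returns the vertices at which the replicator field vanishes to within
    ``tol`` -- by face invariance that is always all eight, but the result is
    computed, not assumed.
    """
    rhs = make_rhs(params)
    return [
        profile
        for profile in PURE_PROFILES.values()
        if float(np.max(np.abs(rhs(0.0, profile.as_array())))) <= tol
    ]


def conditionally_stable_profiles(
    n_draws: int = 1000,
    seed: int = 0,
    low: float = 0.01,
    high: float = 20.0,
    tol: float = 1e-9,
) -> dict[str, int]:
    """Count, per profile, stable classifications over random positive draws.

    Samples ``n_draws`` strictly positive parameter sets uniformly on
    ``[low, high]`` per symbol and classifies every vertex.  Exactly the
    profiles E2 and E3 admit all-negative eigenvalue triples; the other six
    always carry a positive or zero eigenvalue for positive parameters.
    """
    from .params import PARAM_NAMES

    if low <= 0:
        raise ValidationError("draws must be strictly positive: low > 0 required")
    rng = np.random.default_rng(seed)
    counts = {label: 0 for label in PURE_PROFILES}
    for _ in range(n_draws):
        values = rng.uniform(low, high, size=len(PARAM_NAMES))
        params = GameParameters(**dict(zip(PARAM_NAMES, values)))
        for label in PURE_PROFILES:
            if classify_equilibrium(label, params, tol).classification == STABLE:
                counts[label] += 1
    return counts


def _advantage_jacobian(params: GameParameters):
    """Jacobian of the advantage vector (zero diagonal; used for polishing)."""
    (_, ax1, ax2, ax3), (_, ay1, ay2, ay3), (_, az1, az2, az3) = (
        _advantage_coefficients(params)
    )

    def jac(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([
            [0.0, ax1 + ax3 * z, ax2 + ax3 * y],
            [ay1 + ay3 * z, 0.0, ay2 + ay3 * x],
            [az1 + az3 * y, az2 + az3 * x, 0.0],
        ])

    return jac


def _confirm_root(
    advantage, root: np.ndarray, rng: np.random.Generator, tol: float
) -> bool:
    """Re-find ``root`` with an independent multi-start Levenberg-Marquardt run."""
    for _ in range(8):
        start = np.clip(root + rng.uniform(-0.05, 0.05, size=3), 1e-4, 1 - 1e-4)
        sol = optimize.root(lambda s: advantage(s), start, method="lm")
        if sol.success and np.max(np.abs(sol.x - root)) < 1e-6:
            return True
    return False


def find_interior_fixed_points(
    params: GameParameters,
    grid_n: int = 21,
    tol: float = 1e-10,
    seed: int = 0,
) -> list[FixedPoint]:
    """Search the open cube for mixed-strategy fixed points.

    Inside the cube the replicator field vanishes iff all three advantage
    functions do, so the search brackets simultaneous sign changes of
    (Ax, Ay, Az) on a ``grid_n``-per-axis lattice of cells and polishes each
    candidate cell with a Newton-type solver (analytic advantage Jacobian).
    Bilinearity of the advantage functions makes cell-corner sign checks a
    reliable bracket at this density.  Distinct roots (merge radius 1e-6)
    with residual at most ``tol`` are returned; each must also be recovered
    by an independent multi-start solver before being reported.
    """
    if grid_n < 5:
        raise ValidationError(f"grid_n must be at least 5, got {grid_n}")
    if tol <= 0:
        raise ValidationError(f"tol must be positive, got {tol!r}")

    advantage = make_advantage(params)
    adv_jac = _advantage_jacobian(params)
    axis = np.linspace(0.0, 1.0, grid_n)
    # Advantage signs on the full lattice (vectorized).
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    coeffs = _advantage_coefficients(params)
    (ax0, ax1, ax2, ax3), (ay0, ay1, ay2, ay3), (az0, az1, az2, az3) = coeffs
    A = np.stack([
        ax0 + ax1 * Y + ax2 * Z + ax3 * Y * Z,
        ay0 + ay1 * X + ay2 * Z + ay3 * X * Z,
        az0 + az1 * X + az2 * Y + az3 * X * Y,
    ])

    rng = np.random.default_rng(seed)
    roots: list[np.ndarray] = []
    eps = 1e-9
    for i, j, k in itertools.product(range(grid_n - 1), repeat=3):
        cell = A[:, i:i + 2, j:j + 2, k:k + 2].reshape(3, -1)
        if not np.all(cell.min(axis=1) <= 0) or not np.all(cell.max(axis=1) >= 0):
            continue
        start = np.array([axis[i] + 0.5 / (grid_n - 1),
                          axis[j] + 0.5 / (grid_n - 1),
                          axis[k] + 0.5 / (grid_n - 1)])
        sol = optimize.root(lambda s: advantage(s), start, jac=lambda s: adv_jac(s),
                            method="hybr")
        if not sol.success:
            continue
        root = sol.x
        if not np.all((root > eps) & (root < 1 - eps)):
            continue
        if any(np.max(np.abs(root - r)) < 1e-6 for r in roots):
            continue
        residual = float(np.max(np.abs(root * (1 - root) * advantage(root))))
        if residual > tol:
            continue
        if _confirm_root(advantage, root, rng, tol):
            roots.append(root)

    return [
        FixedPoint(
            location=StrategyState(*np.clip(r, 0.0, 1.0)),
            residual=float(np.max(np.abs(r * (1 - r) * advantage(r)))),
            interior_flag=bool(np.all((r > 0) & (r < 1))),
        )
        for r in roots
    ]
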