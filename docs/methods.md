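# Methods

## Model

`trigov` simulates a three-population evolutionary game of overtreatment
governance. Patients either *recognize* treatment outcomes (frequency `x`)
or do not; medical institutions provide *reasonable treatment* (frequency
`y`) or overtreat; government regulators supervise *strictly* (frequency
`z`) or loosely. All agents are boundedly rational and revise strategies by
imitation, which in the large-population limit yields the replicator system

    dx/dt = x(1-x) Ax(y, z)
    dy/dt = y(1-y) Ay(x, z)
    dz/dt = z(1-z) Az(x, y)

where each advantage function `A` is the expected-payoff difference between
the population's two actions given the other two populations' frequencies.
The payoffs are bilinear mixtures of the pure-action payoff cells, built
from fourteen nonnegative constants on one arbitrary money-like scale
(`GameParameters`): patient-side costs/benefits `Cm, Ct, Cp, Ci`;
institution-side incomes and costs `Wm, Wt, Gf, Gs, Er, Oc`; regulator-side
terms `Eg, Cr, Gg, Pg`. Expanded:

    Ax = (Ci+2Cm+Cp) - (2Ci+2Cm+Cp) y - (Ci+2Cm+Cp) z + (Ci+2Cm) yz
    Ay = (Er+Gs+Wt-Wm) + (Oc-Gs) x + Gf z + (Gs-Oc) xz
    Az = (Eg-Cr-Gg+2Pg) - (Eg+4Pg) x - (Eg+2Pg) y + (Eg+4Pg) xy

The package keeps two independent routes to these quantities — the
mixture-weighted payoff differences and the expanded polynomials — and the
test suite proves them identical both symbolically (sympy) and on random
draws. One payoff-cell reading deserves note: the patient cell for
(recognize, overtreated, strict supervision) is taken as `Cp + Ci - Cm`,
which is the unique reading consistent with the expanded polynomials.

A structural property worth knowing when interpreting fine sweeps: the fine
`Gf` appears in the institutions' advantage `Ay` but not in the regulators'
own advantage `Az`, so in this model fines steer institutions (and through
them patients) but cannot move the regulator's strategy directly.

## Equilibria and stability

Faces of the cube are invariant, so all eight pure profiles `E1..E8`
(vertices) are fixed points; `enumerate_pure_equilibria` verifies this by
direct evaluation rather than assumption. At a vertex the Jacobian is
diagonal — every off-diagonal entry carries a vanishing factor `s(1-s)` —
so the closed-form diagonal entries are the eigenvalues. Classification
follows the indirect Lyapunov method with tie tolerance `tol` (default
1e-9):

* **stable (ESS)** — all eigenvalues < `-tol`;
* **indeterminate** — some eigenvalue within `tol` of zero; the
  linearization is inconclusive along that direction and no center-manifold
  analysis is attempted, even when another eigenvalue is positive (the
  vertices `(0,0,1)` and `(1,0,1)` always carry an exact zero);
* **unstable** — otherwise.

For strictly positive parameters only `E2=(1,0,0)` and `E3=(0,1,0)` can be
ESS, and their stability reduces to where the overtreatment income sits:
`E2` is stable iff `Wm > Er + Oc + Wt`, `E3` iff `Wm < Gs + Wt + Er`. Both
conditions can hold at once (bistability) whenever `Oc < Gs`; the first
printed scenario is in fact bistable (7.5 < Wm = 9 < 11), and the realized
limit then depends on the initial state.

Interior (mixed) fixed points require `Ax = Ay = Az = 0` simultaneously.
`find_interior_fixed_points` scans a 21-per-axis grid for cells in which
all three components change sign (reliable for bilinear functions),
polishes candidates with a Newton-type solver using the analytic advantage
Jacobian, merges duplicates within 1e-6, and reports only roots that an
independent multi-start Levenberg–Marquardt run re-finds. Neither printed
scenario has an interior fixed point.

## Numerical integration

`integrate` uses `scipy.integrate.solve_ivp` (RK45) with `rtol = 1e-8`,
`atol = 1e-10` over the horizon `T = 50` (interpreted as continuous time;
the adaptive solver makes a fixed "iteration" count meaningless), saving
1001 uniformly spaced points. Exact solutions never leave the cube, and the
solver's local error is controlled by `atol + rtol·|y|`, so post-hoc clamps
to `[0,1]` are permitted up to `10·(atol + rtol)`; larger excursions raise
an error because they indicate a defective field, not round-off. A
trajectory is *converged* when its final state lies within max-norm
`1e-3` of a vertex; a still-drifting trajectory is reported unconverged
rather than extrapolated. `max_extension` optionally doubles the window
(continuing from the final state) up to N times for questions that are
asymptotic rather than fixed-window — e.g. basin-of-attraction audits,
where a few starts pass near the slowly repelling manifold and need
`T ≈ 200` to enter the 1e-3 ball. Time-to-converge metrics linearly
interpolate the first crossing of the convergence radius between saved
steps.

## Sensitivity sweeps

`run_sensitivity_suite` reruns the center-start integration while varying
one lever at a time: `Gs ∈ {5,10,15}`, fine `∈ {20,150,300}` (applied to
`Gf`; a flag reproduces the variant that varies the credibility symbol
`Pg` instead), `Gg ∈ {50,150,200}`, `Cr ∈ {40,100,150}`, `Wt ∈ {4,8,12}`,
`Wm ∈ {15,10,5}` — eighteen integrations against the scenario-2 base
(`Wt = 7`), the regime in which reasonable treatment is the unique ESS.
Relative-increment sweeps (e.g. +5 %/+10 %/+15 % fines) multiply the base
value instead. Every converged sweep limit is cross-checked against the
stability classification of its own parameter set.

## Scenario generation and the imitation oracle

`baseline_scenarios` returns the two printed parameter sets (identical
except `Wt` = 4 vs 7) and the neutral start `(0.5, 0.5, 0.5)`.
`sample_parameters` rejection-samples seeded parameter sets constrained to
a stability regime (`E2_stable_only`, `E3_stable_only`, `bistable`,
`neither`), with symbols drawn uniformly from `[0.5, 20]` by default — a
range spanning all printed scenario values — and a strict margin of 1e-6 on
the defining inequalities; it aborts with advice to widen the ranges when
the acceptance rate shows the regime is (near-)empty.

`finite_population_oracle` is an agent-based check on the integrator: three
populations of `N` agents update by *proportional imitation* — each
generation an agent, with probability `step_scale`, samples a same-
population peer and adopts the peer's action with probability proportional
to the positive part of the payoff advantage. Proportional imitation is
used precisely because its mean-field limit is the replicator equation, so
the oracle is an independent route to the same dynamics rather than a
re-implementation. Advantages are normalized by the exact cube-wide bound
(attained at corners, by bilinearity), making one generation worth
`step_scale / bound` time units. Default comparisons use `N = 10^4`,
`step_scale = 0.01`, and 22 500 generations (≈ 10 time units — enough to
cover the transient; both scenarios are near their limits well before
`t = 10`), where the empirical path stays within max-norm ≈ 0.05 of the
ODE.

What the generator emulates — parameter sets drawn inside analytically
characterized stability regimes, and finite-population noise around the
mean-field flow — is the structure the analysis assumes, not real hospital
data: passing tests show internal consistency of the model and its
implementation, not calibration to any healthcare system.

## Known limitations

* Only vertex equilibria are classified; edge/face equilibria are detected
  at most as non-interior roots and are not stability-analyzed.
* Zero eigenvalues are reported indeterminate; no center-manifold or
  higher-order analysis.
* The imitation oracle has no mutation or network structure, so cube faces
  are absorbing.
* Problem sizes used by the tests (1000-draw audits, 3³ multi-starts,
  `N = 10^4` oracle runs) were chosen to make each statistical check
  decisive at interactive runtimes; all are configurable.
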