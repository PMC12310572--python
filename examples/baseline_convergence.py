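"""Integrate the two printed scenarios from the neutral initial state.

Scenario 1 (Wt=4) satisfies Wm > Er+Oc+Wt, so overtreatment pays and the
system settles at (1,0,0): patients recognize outcomes, institutions
overtreat, regulators stay loose.  Scenario 2 raises reasonable-treatment
income to Wt=7, satisfying Wm < Gs+Wt+Er, and the limit flips to (0,1,0).
"""

from trigov import baseline_scenarios, integrate

scenario1, scenario2, initial = baseline_scenarios()

for name, params in [("scenario 1 (Wt=4)", scenario1), ("scenario 2 (Wt=7)", scenario2)]:
    traj = integrate(params, initial)
    x, y, z = traj.final_state
    print(f"{name}: limit vertex {traj.limit_vertex.label} "
          f"{traj.limit_vertex.coordinates}, final state "
          f"(x={x:.6f}, y={y:.6f}, z={z:.6f}) at t={traj.times[-1]:.0f}")

print()
print("x = share of patients recognizing treatment outcomes,")
print("y = share of institutions providing reasonable treatment,")
print("z = share of regulators supervising strictly.")
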