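"""Classify the eight pure-strategy equilibria for both printed scenarios.

At each cube vertex the Jacobian of the replicator field is diagonal, so
the closed-form eigenvalues decide stability directly: all negative means
evolutionarily stable (ESS), a zero eigenvalue leaves the linearization
inconclusive.
"""

from trigov import baseline_scenarios, ess_conditions

scenario1, scenario2, _ = baseline_scenarios()

for name, params in [("scenario 1 (Wt=4)", scenario1), ("scenario 2 (Wt=7)", scenario2)]:
    report = ess_conditions(params)
    print(f"\n{name}  (E2 condition Wm>Er+Oc+Wt: {report.e2_condition_holds}, "
          f"E3 condition Wm<Gs+Wt+Er: {report.e3_condition_holds})")
    for r in report.reports:
        eig = ", ".join(f"{v:+7.2f}" for v in r.eigenvalues)
        print(f"  {r.profile.label} {r.profile.coordinates}: ({eig})  {r.classification}")
    print(f"  stable set: {sorted(report.stable_labels)}")

print("\nScenario 1 is bistable (both E2 and E3 are ESS); the realized limit")
print("depends on the initial state.  Scenario 2 leaves E3 as the unique ESS.")
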