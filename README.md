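# trigov

Replicator-dynamics simulation and stability analysis for a tripartite
evolutionary game of **overtreatment governance**: patients, medical
institutions, and government regulators, each boundedly rational, each
choosing between two strategies.

Overtreatment — care beyond clinical need — persists because it pays:
institutions earn more from it (`Wm`) than from reasonable treatment
(`Wt`), patients struggle to recognize it, and supervision is costly. This
package models the three groups' co-evolution as a replicator system on
the unit cube,

```
dx/dt = x(1-x) Ax(y,z)     x: patients recognizing treatment outcomes
dy/dt = y(1-y) Ay(x,z)     y: institutions treating reasonably
dz/dt = z(1-z) Az(x,y)     z: regulators supervising strictly
```

where each advantage function `A` is the expected-payoff gap between a
population's two actions, bilinear in the other two frequencies and built
from fourteen nonnegative constants (subsidies `Gs`, fines `Gf`,
reputation `Er`, operating cost `Oc`, regulatory and remediation costs
`Cr`, `Gg`, credibility `Pg`, …). The package provides:

* closed-form eigenvalues and ESS classification of the eight pure
  profiles (the cube vertices), including the two headline conditions —
  overtreatment locks in at `(1,0,0)` iff `Wm > Er+Oc+Wt`; reasonable
  treatment is stable at `(0,1,0)` iff `Wm < Gs+Wt+Er`;
* adaptive integration of trajectories with convergence detection,
  multi-start basin audits, and interior fixed-point search;
* one-parameter sensitivity sweeps over the policy levers;
* seeded generation of parameter sets inside prescribed stability regimes
  and a finite-population imitation oracle whose mean-field limit is the
  replicator flow.

## Worked example

```python
from trigov import baseline_scenarios, ess_conditions, integrate

scenario1, scenario2, start = baseline_scenarios()   # start = (0.5, 0.5, 0.5)

print(sorted(ess_conditions(scenario1).stable_labels))
print(integrate(scenario1, start).final_state.round(4))
print(sorted(ess_conditions(scenario2).stable_labels))
print(integrate(scenario2, start).final_state.round(4))
```

prints

```
['E2', 'E3']
[1. 0. 0.]
['E3']
[0. 1. 0.]
```

Under the first parameter set (`Wt = 4`) both pure outcomes are locally
stable, and from the neutral start the system converges to `(1, 0, 0)`:
patients learn to recognize outcomes, but institutions keep overtreating
while regulators relax. Raising reasonable-treatment income to `Wt = 7`
(second set) destabilizes the overtreatment vertex and the same start now
reaches `(0, 1, 0)` — institutions treat reasonably and strict supervision
becomes unnecessary.

The `examples/` directory holds one short script per capability
(equilibrium table, baseline convergence, sensitivity sweeps, the
imitation oracle, regime sampling); each prints the numbers it computes
with a line of interpretation. A thin CLI mirrors the main entry points:

```
trigov simulate --scenario baseline --horizon 50 --out-dir out/
trigov stability --scenario scenario2
trigov sweep --name Wm --values 15,10,5
```

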