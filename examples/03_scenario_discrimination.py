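"""Simulate the five secretion-response scenarios and classify them back.

The endpoint response is a.A + b.A^2: a is the direct (enzyme-level)
coefficient, b the regulatory one.  Feedback inhibition without gene
regulation is a < 0 with b = 0.
"""

from overflux.scenarios import (
    Scenario,
    ScenarioParams,
    classify_scenario,
    simulate_scenario,
)

levels = [0.0, 0.5, 1.0, 5.0, 10.0]
cases = [
    ScenarioParams(Scenario.additive, a=0.1),
    ScenarioParams(Scenario.balanced, x_init=0.5),
    ScenarioParams(Scenario.feedback_only, a=-0.1),
    ScenarioParams(Scenario.synergistic, a=-0.05, b=-0.02),
    ScenarioParams(Scenario.upregulation, a=0.05, b=0.02),
]

print(f"{'generated':14s} {'classified':14s} {'a_hat':>8s} {'b_hat':>8s} {'p(b)':>8s}")
for params in cases:
    ds = simulate_scenario(params, levels, noise_cv=0.1, seed=42)
    fit = classify_scenario(ds)
    print(f"{params.scenario.value:14s} {fit.best.value:14s} "
          f"{fit.a_hat:+8.3f} {fit.b_hat:+8.3f} {fit.p_value_b:8.2g}")
print("\nEach row simulates one titration (25 replicates/level, cv 0.1) and")
print("recovers the generating scenario from coefficient signs + an F test.")
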