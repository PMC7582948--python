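"""Threat-probability tuning curve of a simulated cue-excited population.

The encoding regression is repeated nine times, sweeping the probability
assigned to the uncertainty cue from 0 to 1 in 0.125 steps while danger
stays at 1 and safety at 0. Averaging each sweep's threat beta over the
ten cue intervals and across units yields a tuning curve whose peak
estimates the probability the population actually assigns to uncertainty.
"""

import numpy as np

import threatcode as tc

# units internally weight uncertainty at 0.5 (not the task's true 0.375)
spec = tc.UnitSpec(label="excited", baseline_rate=5.0, threat_gain=4.0,
                   internal_uncertainty_weight=0.5)
cohort = tc.CohortConfig(
    groups=(tc.GroupSpec(name="con", n_rats=12, units_per_session=4,
                         unit_specs=(spec,)),),
    seed=1,
)
bundles, _ = tc.generate_cohort(cohort)
results = tc.analyze_cohort(bundles)

excited = results.tuning[results.tuning["label"] == "excited"]
curve = excited.groupby("u")["mean_beta_threat"].mean()
print(f"population of {excited['unit'].nunique()} cue-excited units")
print("uncertainty assignment -> mean threat beta")
for u, b in curve.items():
    marker = "  <- peak" if u == curve.idxmax() else ""
    print(f"  {u:5.3f}  {b:6.3f}{marker}")
# The curve peaks at the units' internal weight (0.500), demonstrating
# that the sweep recovers the population's effective uncertainty tuning
# rather than the task's programmed shock probability.
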