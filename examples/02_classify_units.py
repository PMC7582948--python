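"""Screen simulated single units for cue responsiveness.

Each unit's raw firing rate in the 10 s pre-cue baseline is compared with
cue epochs by paired t tests across trials (six comparisons per unit,
threshold p < 0.05/6). Units with at least one significant increase and no
decrease are cue-excited; the converse are cue-inhibited; everything else
falls outside the selection criteria (osc).
"""

import numpy as np

import threatcode as tc
from threatcode.synthetic import fear_drive_levels

cfg = tc.TaskConfig()
rng = np.random.default_rng(3)
trials = tc.generate_trial_schedule(cfg, rng)
pokes, s_true = tc.simulate_behavior(trials, tc.BehaviorParams(), cfg, rng)
levels = fear_drive_levels(trials, pokes, s_true, cfg, "realized")

specs = {
    "excited-like": tc.UnitSpec(label="excited", baseline_rate=5.0, threat_gain=5.0),
    "inhibited-like": tc.UnitSpec(label="inhibited", baseline_rate=9.0, threat_gain=5.0),
    "flat": tc.UnitSpec(label="none", threat_gain=0.0, fear_gain=0.0),
}
for name, spec in specs.items():
    spk = tc.simulate_unit(trials, spec, levels, cfg, rng)
    cl = tc.classify_unit(name, spk, trials)
    worst = min(cl.tests, key=lambda t: t.p)
    print(f"{name:15s} -> {cl.label:9s} "
          f"(strongest epoch test: {worst.cue}/{worst.epoch}, "
          f"t = {worst.t:.2f}, p = {worst.p:.2g})")
# The labels recover each unit's generative type; the flat unit shows no
# epoch significant at the corrected threshold.
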