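"""Group-level statistics on a two-group synthetic cohort.

Simulates a control-like group and a group with inflated cue gains, runs
the full pipeline, and prints the responsive-proportion chi-square, the
suppression mixed ANOVA and the firing/signaling coupling comparisons.
"""

import json

import threatcode as tc

con = (
    tc.UnitSpec(label="excited", baseline_rate=5.0, threat_gain=3.0),
    tc.UnitSpec(label="inhibited", baseline_rate=9.0, threat_gain=3.0),
    tc.UnitSpec(label="none", threat_gain=0.0, fear_gain=0.0),
)
eaa = (
    tc.UnitSpec(label="excited", baseline_rate=5.0, threat_gain=6.0),
    tc.UnitSpec(label="inhibited", baseline_rate=9.0, threat_gain=6.0),
)
cohort = tc.CohortConfig(
    groups=(
        tc.GroupSpec(name="con", n_rats=8, units_per_session=3, unit_specs=con),
        tc.GroupSpec(name="eaa", n_rats=12, units_per_session=2, unit_specs=eaa),
    ),
    seed=11,
)
bundles, _ = tc.generate_cohort(cohort)
results = tc.analyze_cohort(bundles)
rep = results.stats_report

for grp, counts in rep["proportions"].items():
    n = rep["n_units"][grp]
    resp = counts["excited"] + counts["inhibited"]
    print(f"{grp}: {resp}/{n} responsive ({100 * resp / n:.1f}%), "
          f"{counts['excited']} excited / {counts['inhibited']} inhibited")
chi = rep["responsive_chi_square"]
if "chi2" in chi:
    print(f"chi-square (responsive x group): chi2 = {chi['chi2']:.2f}, p = {chi['p']:.3g}")
cue = rep["suppression_anova"]["cue"]
print(f"suppression ANOVA, cue effect: F({cue['df_num']},{cue['df_den']}) = "
      f"{cue['F']:.2f}, p = {cue['p']:.2g}, partial eta^2 = {cue['partial_eta_sq']:.2f}")
for name, f in rep.get("coupling", {}).items():
    print(f"coupling {name}: Z = {f['Z']:.2f}, p = {f['p']:.3g}")
# The inflated-gain group shows a higher responsive proportion; behavior
# (driven identically in both groups) shows a strong cue effect and no
# group differences.
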