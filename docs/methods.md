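# Methods

This note documents the models, conventions and design choices behind
`threatcode`: what each stage computes, what the synthetic generator does
and does not emulate, and where the design was genuinely open.

## Task structure

A session holds 32 cued trials: 6 danger (always shocked), 6
uncertainty-shock, 10 uncertainty-omission and 10 safety trials in a
uniformly random order, so the uncertainty cue's empirical shock
probability is 6/16 = 0.375. Cues last 10 s; shock, when scheduled,
arrives 2 s after cue offset so that delay-period activity is not driven
by an explicit stimulus. All event times are seconds from session start;
peri-event times are relative to cue onset; windows and 250 ms bins are
half-open `[t, t+Δ)`.

The generator compresses inter-trial spacing to
`pre_window + cue + post_window + 5 s` (60 s at defaults) instead of the
task's ~3.5 min mean interval. Every analysis consults at most the
[−20 s, +30 s] peri-onset window, so the extra dead time would change no
statistic, only runtime. Trial onsets are evenly spaced; the schedule's
randomness is the type order.

## Behavior model

Nose pokes form a piecewise-homogeneous Poisson process at
`baseline_poke_rate` (default 1.0 Hz, a typical rate for a food-deprived
rat poking on a variable-interval schedule) except during cues. The
latent fear level of a trial is `s = clamp(target[cue] + N(0, σ), 0, 1)`
with per-trial noise σ = 0.15; targets default to danger 0.90,
uncertainty 0.65, safety 0.10, the graded pattern of a well-trained
female rat on this task (uncertainty well above 0.375 × danger — the
non-linearity that lets fear output and threat probability be dissociated
in the regression; the generator's defaults keep the two design columns
correlated at ≈ 0.7, comfortably below collinearity).

Targets are expressed in *suppression-ratio units*: the cue-period poke
rate is `baseline · (1 − s)/(1 + s)`, the factor for which the measured
ratio `(b − c)/(b + c)` converges to `s` as counting noise vanishes. (A
naive proportional rate drop of `s` would instead yield a measured ratio
`s/(2 − s)`, i.e. 0.82 for a target of 0.90.)

At 1 Hz baseline the ratio is measured from ~20 baseline and ≤10 cue
pokes, so single-trial ratios carry substantial counting noise (variance
≈ 0.03–0.08 depending on the cue). This is a property of the measurement,
not the simulation; its consequences for the regression are discussed
below. Trials with no pokes in either window have an undefined (0/0)
ratio and are recorded as missing, excluded from means and dropped from
regressions (configurable to ratio = 0). The small-rate bias of the
mean measured ratio is visible at 1 Hz (order 0.01–0.05 depending on the
cue) and vanishes as the baseline rate grows; the behavior test suite
quantifies recovery at 30 Hz to within 0.05.

## Spike model

Each unit is an inhomogeneous Poisson process, piecewise constant on a
250 ms grid. Outside cues the rate is `baseline_rate` (default 5 Hz).
Within a cue,

    rate = max(0, baseline + profile(t) · (threat_gain · p_unit(cue)
                                           + fear_gain · f_trial + η_trial))

where `p_unit` assigns danger 1, safety 0 and uncertainty the unit's
`internal_uncertainty_weight` (default 0.375, the task's true value);
`η_trial ~ N(0, 0.5 Hz)` enters once per trial, matching the trial-level
structure the encoding regression assumes; inhibited units negate the
gains; and `profile` is flat by default, with `onset_phasic_fraction`
mixing in an onset-concentrated profile of equal integral. Shock
responses are not simulated: all analyses target the cue period.

`f_trial` is the fear-output level a fear-coding unit couples to. By
default (`fear_drive="realized"`) it is the trial's *measured*
suppression ratio — fear output is operationally defined as that ratio,
so a fear-output coder covaries with the behavior the animal actually
expressed (with the latent level substituted on the rare trials whose
ratio is undefined). The alternative `fear_drive="latent"` couples the
unit to the hidden suppression level instead. The distinction matters:
with latent coupling the regressor (the measured ratio) is an
errors-in-variables proxy for the drive, and at a 1 Hz poke rate the
attenuation is severe enough that roughly half of a pure fear coder's
signal loads onto the noise-free threat column (measured at defaults:
mean β_threat ≈ 0.8–1.0 against β_fear ≈ 1.0 for a latent-driven fear
coder, versus β_threat ≈ 0.01 for a realized-driven one). Analyses of
real recordings face the same attenuation whenever neural drive and
measured behavior are imperfectly coupled; the generator's default
isolates the pipeline's correctness from it, and the latent mode exposes
it for study.

Cohorts default to 8 control and 12 adversity-model rats. All randomness
flows from one master seed through stable (group, rat, session, unit)
keys, so any slice of a cohort is reproducible independently of
generation order.

What the generator does **not** emulate: learning across sessions,
shock-evoked firing, slow drift in excitability or motivation,
non-Poisson spiking (bursting, refractoriness), correlated noise across
simultaneously recorded units, and electrode artifacts. Passing tests
therefore certify the estimators under the stated generative model, not
robustness to these features of real data.

## Normalization

For each unit and trial type the 200-bin trial-averaged trace is
differenced against that type's own mean over [−2 s, 0) and the
differential traces of all types are jointly Z-scored — one (μ, σ) per
unit over the concatenation, each type contributing its 200 bins once.
Normalizing over the whole epoch rather than the baseline keeps units
with little baseline activity well-defined, at the cost that normalized
baseline activity need not sit at zero. A unit whose differential traces
have zero variance is flagged degenerate and excluded from all
normalized analyses. The classification baseline ([−10 s, 0)) and the
differencing baseline ([−2 s, 0)) are deliberately distinct windows.

Single-trial normalized firing for an interval applies the same affine
transform to the trial's interval rate. Two constructions are exposed:
differencing the trial against its own 2 s baseline first (consistent
with the plotted mean z-traces: a trial equal to its type's mean trace
reproduces the z-trace exactly), or using the undifferenced rate. The
*regression* default is the undifferenced rate: the 2 s baseline estimate
(~10 spikes at 5 Hz) is pure noise shared by all ten intervals of a
trial, and subtracting it roughly doubles the spread of recovered betas
(cross-beta SD 0.73 vs 0.40 over 200 simulated units) while the
regression's constant term already absorbs any baseline level. Both
modes are available everywhere (`per_trial_baseline`).

## Classification

Screening uses raw rates (Hz), not normalized values. The corrected
threshold is the exact fraction 0.05/6 ≈ 0.008333. Zero-variance paired
differences (e.g. a silent unit) cannot support a t test and are flagged
and treated as non-significant. Two epoch schemes are implemented:
`class_specific` (default) screens excitation on {first 1 s, last 5 s}
and inhibition on {first 5 s, last 5 s}; `uniform` screens both
directions on {first 1 s, last 5 s}. A unit significant in both
directions falls outside the criteria. Measured on 2,000 stationary 5 Hz
units, the familywise false-positive rate is ≈ 0.05 for both schemes
(bounded by 0.06 in the acceptance suite); at a per-trial effect of
Cohen's d = 1.5 on the 16-trial cue, ≥ 95% of units are labeled
correctly.

## Encoding regression and tuning

The design matrix holds a constant, the trial's measured 10 s suppression
ratio (fear output) and the cue's assigned shock probability (threat).
Columns are left on their native scales, so betas are in
normalized-firing units per unit regressor; no standardization is
applied. Sessions with fewer than 8 usable trials are excluded;
rank-deficient designs (e.g. constant fear column) return the
minimum-norm solution with a flag. OLS is solved by `numpy.linalg.lstsq`
and is verified against the normal-equations solution on 1,000 random
problems at 1e-8.

The tuning sweep holds danger at 1 and safety at 0 while the uncertainty
assignment u runs over {0, 0.125, …, 1}; each unit's curve is the mean
β_threat over the ten 1 s intervals, and the population curve averages
units. For a population whose internal uncertainty weight w matches the
assignment, β_threat equals the unit's (normalized) gain exactly at
u = w; away from w the ratio of covariances bends the curve downward, the
more sharply the noisier the fear column. A subtlety worth recording:
for units tuned at w = 0.375 the population curve is near-flat between
0.375 and 0.500 (the two grid points bracket the curve's analytic
maximum under fear-column noise), so the empirical argmax can land on
either point; for w = 0.500 the peak is unambiguous. An observed peak at
0.500 therefore need not contradict a true weight of 0.375 — the same
displacement the real recordings show.

## Population statistics

The chi-square on responsive proportions is Pearson's, 1 df, no
continuity correction. The mixed-design ANOVA is a hand-written
univariate partitioning supporting one between-subjects factor and one or
two within-subjects factors: the between effect is tested against
subjects-within-groups, each within effect and its group interactions
against the effect × subjects-within-groups stratum; no sphericity
correction. It reproduces R's `aov` multistratum decomposition exactly
on a balanced two-within design and pingouin's `mixed_anova` on
one-within designs (both are test oracles). Group means are
observation-weighted; for balanced designs this coincides with the
Type III decomposition, and for unbalanced group sizes (the usual case:
unit counts differ by group) it is the classic approximation rather than
a cell-means Type III solution. Partial eta squared is
SS_effect/(SS_effect + SS_error) with each effect's own error stratum.
"Observed power", an SPSS reporting artifact, is intentionally not
computed.

Firing/signaling coupling regresses a beta on epoch z-firing across
units (per group, population and cue: onset firing vs threat beta for
cue-excited units; late-cue firing vs fear beta for cue-inhibited units)
via `scipy.stats.linregress`; groups are compared by
Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) with a two-tailed
normal p.

## Numerical conventions

- Windows and bins half-open; events exactly at a window's end are
  excluded, at its start included.
- 0-based trial indices; times written with six decimal places; derived
  tables with six significant digits and fixed column order, so re-runs
  are byte-identical.
- Cue labels canonicalized to lowercase on read; validation errors name
  the offending file and line.
- Uncertainty subtypes are kept distinct in records and pooled by
  default in trace averaging and screening (during the cue the animal
  cannot know the outcome); `collapse_uncertainty=False` keeps them
  separate.
- Seeds below 2³¹; all sub-streams derived by stable integer keys.

## Problem sizes

Simulation-backed tests use populations of 48 units (tuning peak), 50
units per coder class (beta recovery), 2,000 null units (classifier
false positives) and 150–200 units per direction (classifier power) —
sizes at which each check's statistic is stable across seeds while the
whole suite runs in minutes on a single core. The acceptance script's
tuning experiment uses 12 rats × 4 units = 48 cue-excited units, one
session each.

## Known limitations

- The Poisson spike model understates the variance of real spike counts
  (no bursting/refractoriness), so real-data betas will be noisier than
  the recovery tests suggest.
- The latent fear-drive mode demonstrates that a noisy behavioral
  regressor leaks genuine fear signal into the threat beta; the pipeline
  cannot correct this (no errors-in-variables model is fit), it can only
  make it visible in simulation.
- The unbalanced-groups ANOVA is the observation-weighted approximation
  described above, not a full Type III solution.
- Tuning curves are only computed per unit-session; units recorded over
  multiple sessions are treated as distinct units, as in the recording
  setting that motivated the design.
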