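"""Synthetic fear-discrimination sessions with known ground truth.

The generator reproduces the task structure used throughout the package:
32-trial sessions (6 danger, 6 uncertainty-shock, 10 uncertainty-omission,
10 safety trials in random order), 10 s auditory cues, shock 2 s after cue
offset on shocked trials. Behavior is a piecewise-homogeneous Poisson
nose-poke process whose rate drops during cues according to a per-trial
latent suppression level; spike trains are inhomogeneous Poisson processes
whose cue-period rate is driven by the cue's threat probability (as the
unit internally weights it) and/or by the trial's latent fear level. The
latent variables are returned so downstream estimators can be tested
against ground truth.

Inter-trial spacing is compressed relative to a real 93-minute session:
peri-event analyses only consult a [-20, +30] s window around each onset,
so the long intervals contribute nothing but runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import (
    CUES,
    SHOCK_PROBABILITIES,
    SessionBundle,
    SessionMeta,
    TrialRecord,
    trial_type,
)

#: Extra spacing added beyond the pre+cue+post peri-event span.
GAP_MARGIN_S = 5.0

DEFAULT_TRIAL_COUNTS = {
    "danger": 6,
    "uncertainty_shock": 6,
    "uncertainty_omission": 10,
    "safety": 10,
}


@dataclass(frozen=True)
class TaskConfig:
    """Trial-schedule parameters of the discrimination task."""

    cue_duration: float = 10.0
    shock_delay_after_offset: float = 2.0
    pre_window: float = 20.0
    post_window: float = 20.0
    trial_counts: dict = field(default_factory=lambda: dict(DEFAULT_TRIAL_COUNTS))
    gap_margin: float = GAP_MARGIN_S

    def __post_init__(self) -> None:
        for name in ("cue_duration", "shock_delay_after_offset", "pre_window", "post_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for tt, n in self.trial_counts.items():
            if tt not in DEFAULT_TRIAL_COUNTS:
                raise ValueError(f"unknown trial type {tt!r}")
            if int(n) != n or n < 0:
                raise ValueError(f"trial count for {tt!r} must be a non-negative integer")

    @property
    def spacing(self) -> float:
        return self.pre_window + self.cue_duration + self.post_window + self.gap_margin

    def shock_probability(self, cue: str) -> float:
        """Empirical shock probability implied by the trial counts."""
        if cue == "uncertainty":
            ns = self.trial_counts.get("uncertainty_shock", 0)
            no = self.trial_counts.get("uncertainty_omission", 0)
            return ns / (ns + no) if ns + no else 0.0
        return SHOCK_PROBABILITIES[cue]


@dataclass(frozen=True)
class BehaviorParams:
    """Latent behavioral model for nose poking.

    ``target_suppression`` maps each cue to the mean *suppression ratio*
    the rat expresses during that cue (the unit the behavioral analysis
    reports); per-trial levels are the target plus Gaussian noise, clamped
    to [0, 1]. A trained rat shows danger >= uncertainty >= safety.
    """

    baseline_poke_rate: float = 1.0
    target_suppression: dict = field(
        default_factory=lambda: {"danger": 0.90, "uncertainty": 0.65, "safety": 0.10}
    )
    trial_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.baseline_poke_rate < 0:
            raise ValueError("baseline_poke_rate must be >= 0")
        for cue, s in self.target_suppression.items():
            if cue not in CUES:
                raise ValueError(f"unknown cue {cue!r}")
            if not 0.0 <= s <= 1.0:
                raise ValueError("suppression targets must lie in [0, 1]")
        if self.trial_noise_sd < 0:
            raise ValueError("trial_noise_sd must be >= 0")


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth firing model of one simulated unit.

    During a cue the rate is

        max(0, baseline + profile(t) * (threat_gain * p_unit(cue)
                                        + fear_gain * s_trial + eta_trial))

    where ``p_unit`` assigns danger 1, safety 0 and the uncertainty cue the
    unit's ``internal_uncertainty_weight`` (the probability the unit's own
    tuning attributes to uncertainty), ``s_trial`` is the latent behavioral
    suppression level of that trial and ``eta_trial`` is one Gaussian rate
    offset per trial. Inhibited units use negative gains.
    """

    label: str = "excited"  # {"excited", "inhibited", "none"}
    baseline_rate: float = 5.0
    threat_gain: float = 4.0
    fear_gain: float = 0.0
    internal_uncertainty_weight: float = 0.375
    onset_phasic_fraction: float = 0.0
    trial_noise_sd: float = 0.5
    #: what a fear-coding unit couples to: the trial's realized (measured)
    #: suppression ratio, or the latent suppression level behind it.
    #: Fear output is operationally defined as the measured ratio, so
    #: "realized" makes fear coders covary with that quantity; "latent"
    #: instead couples to the hidden level, whose noisy measurement then
    #: attenuates the fear beta and leaks fear signal into the threat beta.
    fear_drive: str = "realized"

    def __post_init__(self) -> None:
        if self.label not in ("excited", "inhibited", "none"):
            raise ValueError(f"unknown unit label {self.label!r}")
        if self.fear_drive not in ("realized", "latent"):
            raise ValueError(f"unknown fear_drive {self.fear_drive!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if not 0.0 <= self.internal_uncertainty_weight <= 1.0:
            raise ValueError("internal_uncertainty_weight must lie in [0, 1]")
        if not 0.0 <= self.onset_phasic_fraction <= 1.0:
            raise ValueError("onset_phasic_fraction must lie in [0, 1]")

    def p_unit(self, cue: str) -> float:
        if cue == "uncertainty":
            return self.internal_uncertainty_weight
        return SHOCK_PROBABILITIES[cue]

    def profile(self, cue_duration: float, dt: float = 0.25) -> np.ndarray:
        """Within-cue gain profile on a ``dt`` grid, unit mean over the cue.

        ``onset_phasic_fraction`` f mixes a flat profile with one that
        concentrates the same integrated gain into the first second of the
        cue: profile = (1-f) + f * cue_duration * 1[t < 1 s].
        """
        n = int(round(cue_duration / dt))
        prof = np.full(n, 1.0 - self.onset_phasic_fraction)
        n_onset = int(round(1.0 / dt))
        prof[:n_onset] += self.onset_phasic_fraction * cue_duration
        return prof


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _poisson_times(rng: np.random.Generator, rate: float, start: float, end: float) -> np.ndarray:
    """Homogeneous Poisson event times on [start, end)."""
    dur = end - start
    if rate <= 0 or dur <= 0:
        return np.empty(0)
    n = rng.poisson(rate * dur)
    return np.sort(start + rng.random(n) * dur)


def generate_trial_schedule(
    config: TaskConfig, rng: np.random.Generator
) -> list[TrialRecord]:
    """Draw a uniformly random trial order with the configured multiset of types.

    Onsets start at ``pre_window + gap_margin`` and are evenly spaced by
    ``config.spacing`` so that peri-event windows never overlap.
    """
    types: list[str] = []
    for tt in DEFAULT_TRIAL_COUNTS:  # stable canonical order before shuffling
        types += [tt] * int(config.trial_counts.get(tt, 0))
    order = rng.permutation(len(types))
    trials = []
    for i, j in enumerate(order):
        tt = types[j]
        cue = "uncertainty" if tt.startswith("uncertainty") else tt
        shock = tt in ("danger", "uncertainty_shock")
        onset = config.pre_window + config.gap_margin + i * config.spacing
        trials.append(TrialRecord(index=i, cue=cue, shock=shock, onset=onset))
    return trials


def session_end(trials: list[TrialRecord], config: TaskConfig) -> float:
    if not trials:
        return config.spacing
    return trials[-1].onset + config.cue_duration + config.post_window + config.gap_margin


def simulate_behavior(
    trials: list[TrialRecord],
    params: BehaviorParams,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate nose pokes; return (poke timestamps, latent per-trial suppression).

    Pokes follow a piecewise-homogeneous Poisson process at the baseline
    rate everywhere except during cues. The latent suppression level
    s_trial (clamped noisy target) is expressed in suppression-ratio
    units, so the cue-period rate is baseline * (1 - s)/(1 + s): with that
    factor the measured ratio (b - c)/(b + c) converges to s as counting
    noise vanishes. s = 1 silences poking entirely; s = 0 leaves it at
    baseline.
    """
    t_end = session_end(trials, config)
    s_true = np.empty(len(trials))
    segments: list[tuple[float, float, float]] = []
    cursor = 0.0
    for i, tr in enumerate(trials):
        s = params.target_suppression[tr.cue] + rng.normal(0.0, params.trial_noise_sd)
        s_true[i] = min(1.0, max(0.0, s))
        segments.append((cursor, tr.onset, params.baseline_poke_rate))
        cue_rate = params.baseline_poke_rate * (1.0 - s_true[i]) / (1.0 + s_true[i])
        segments.append((tr.onset, tr.onset + config.cue_duration, cue_rate))
        cursor = tr.onset + config.cue_duration
    segments.append((cursor, t_end, params.baseline_poke_rate))
    pokes = np.sort(np.concatenate([_poisson_times(rng, r, a, b) for a, b, r in segments]))
    return pokes, s_true


def fear_drive_levels(
    trials: list[TrialRecord],
    pokes: np.ndarray,
    s_true: np.ndarray,
    config: TaskConfig,
    mode: str = "realized",
) -> np.ndarray:
    """Per-trial fear-output levels that drive a fear-coding unit.

    ``"latent"`` returns the generator's hidden suppression levels;
    ``"realized"`` returns the measured suppression ratio of each trial
    (what the fear-output regressor will contain), falling back to the
    latent level on trials whose ratio is undefined (no pokes at all).
    """
    if mode == "latent":
        return np.asarray(s_true, dtype=float)
    if mode != "realized":
        raise ValueError(f"unknown fear_drive mode {mode!r}")
    from .behavior import poke_rate, suppression_ratio  # local: avoids import cycle at module load

    out = np.empty(len(trials))
    for i, tr in enumerate(trials):
        b = poke_rate(pokes, tr.onset - config.pre_window, tr.onset)
        c = poke_rate(pokes, tr.onset, tr.onset + config.cue_duration)
        r = suppression_ratio(b, c, zero_zero="nan")
        out[i] = r if np.isfinite(r) else s_true[i]
    return out


def simulate_unit(
    trials: list[TrialRecord],
    spec: UnitSpec,
    fear_levels: np.ndarray,
    config: TaskConfig,
    rng: np.random.Generator,
    dt: float = 0.25,
) -> np.ndarray:
    """Simulate one unit's spike train for the whole session.

    ``fear_levels`` holds the per-trial fear-output value the unit couples
    to (see :func:`fear_drive_levels`). The rate is ``baseline_rate``
    outside cues; within a cue it follows the model described on
    :class:`UnitSpec`, piecewise constant on a ``dt`` grid, clamped at
    zero.
    """
    t_end = session_end(trials, config)
    sign = -1.0 if spec.label == "inhibited" else 1.0
    prof = spec.profile(config.cue_duration, dt)
    pieces = []
    cursor = 0.0
    for i, tr in enumerate(trials):
        pieces.append(_poisson_times(rng, spec.baseline_rate, cursor, tr.onset))
        drive = sign * (
            spec.threat_gain * spec.p_unit(tr.cue) + spec.fear_gain * fear_levels[i]
        ) + rng.normal(0.0, spec.trial_noise_sd)
        for k, g in enumerate(prof):
            rate = max(0.0, spec.baseline_rate + g * drive)
            a = tr.onset + k * dt
            pieces.append(_poisson_times(rng, rate, a, a + dt))
        cursor = tr.onset + config.cue_duration
    pieces.append(_poisson_times(rng, spec.baseline_rate, cursor, t_end))
    return np.sort(np.concatenate(pieces))


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class GroupSpec:
    """Simulation recipe for one between-subjects group."""

    name: str
    n_rats: int = 8
    sessions_per_rat: int = 1
    units_per_session: int = 2
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    unit_specs: tuple = (UnitSpec(),)  # cycled across units within a session

    def __post_init__(self) -> None:
        if min(self.n_rats, self.sessions_per_rat, self.units_per_session) < 1:
            raise ValueError("cohort dimensions must be >= 1")
        if not self.unit_specs:
            raise ValueError("at least one UnitSpec required")


@dataclass(frozen=True)
class CohortConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    groups: tuple = (
        GroupSpec(name="con", n_rats=8),
        GroupSpec(name="eaa", n_rats=12),
    )
    seed: int = 0


def generate_cohort(config: CohortConfig):
    """Generate all sessions of a cohort plus ground-truth tables.

    Returns ``(bundles, truth)`` where ``truth`` is a dict with two
    pandas-ready record lists: ``units`` (one row per simulated unit with
    its generative parameters) and ``trials`` (latent suppression per
    trial). Sub-streams are derived from the master seed by stable
    (group, rat, session, unit) integer keys, so any slice of the cohort
    is reproducible independently of generation order.
    """
    bundles: list[SessionBundle] = []
    unit_rows: list[dict] = []
    trial_rows: list[dict] = []
    for gi, grp in enumerate(config.groups):
        for ri in range(grp.n_rats):
            rat = f"{grp.name}_rat{ri:02d}"
            for si in range(grp.sessions_per_rat):
                sched_rng = _rng(config.seed, gi, ri, si, 0)
                trials = generate_trial_schedule(config.task, sched_rng)
                beh_rng = _rng(config.seed, gi, ri, si, 1)
                pokes, s_true = simulate_behavior(trials, grp.behavior, config.task, beh_rng)
                levels = {
                    mode: fear_drive_levels(trials, pokes, s_true, config.task, mode)
                    for mode in {spec.fear_drive for spec in grp.unit_specs}
                }
                units: dict[str, np.ndarray] = {}
                for ui in range(grp.units_per_session):
                    spec = grp.unit_specs[ui % len(grp.unit_specs)]
                    unit_id = f"{rat}_s{si:02d}_u{ui:02d}"
                    spike_rng = _rng(config.seed, gi, ri, si, 2, ui)
                    units[unit_id] = simulate_unit(
                        trials, spec, levels[spec.fear_drive], config.task, spike_rng
                    )
                    unit_rows.append(
                        {
                            "unit": unit_id,
                            "rat": rat,
                            "group": grp.name,
                            "session": f"s{si:02d}",
                            "label": spec.label,
                            "baseline_rate": spec.baseline_rate,
                            "threat_gain": spec.threat_gain,
                            "fear_gain": spec.fear_gain,
                            "internal_uncertainty_weight": spec.internal_uncertainty_weight,
                        }
                    )
                meta = SessionMeta(
                    rat=rat,
                    group=grp.name,
                    session=f"s{si:02d}",
                    seed=config.seed,
                    cue_duration=config.task.cue_duration,
                    pre_window=config.task.pre_window,
                    post_window=config.task.post_window,
                )
                bundles.append(SessionBundle(trials=trials, pokes=pokes, units=units, meta=meta))
                for tr, s in zip(trials, s_true):
                    trial_rows.append(
                        {
                            "rat": rat,
                            "group": grp.name,
                            "session": f"s{si:02d}",
                            "trial_index": tr.index,
                            "cue": tr.cue,
                            "trial_type": trial_type(tr.cue, tr.shock),
                            "s_true": s,
                        }
                    )
    return bundles, {"units": unit_rows, "trials": trial_rows}
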