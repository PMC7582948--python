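"""Core in-memory containers for a fear-discrimination recording session.

A session is a sequence of cued trials over a baseline of rewarded nose
poking. Three auditory cues predict unique foot-shock probabilities:
danger (p = 1.00), uncertainty (p = 0.375) and safety (p = 0.00). Shock,
when delivered, arrives 2 s after cue offset. Everything downstream
(suppression ratios, peri-event traces, encoding regressions) is computed
from the event lists stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical cue labels, in decreasing order of shock probability.
CUES = ("danger", "uncertainty", "safety")

#: Foot-shock probability actually assigned to each cue by the task.
SHOCK_PROBABILITIES = {"danger": 1.0, "uncertainty": 0.375, "safety": 0.0}

#: Trial types distinguish the two uncertainty outcomes; during the cue the
#: animal cannot know which one it is in, so analyses may collapse them.
TRIAL_TYPES = ("danger", "uncertainty_shock", "uncertainty_omission", "safety")


def trial_type(cue: str, shock: bool) -> str:
    """Map a (cue, shock) pair to its four-level trial-type label."""
    if cue == "uncertainty":
        return "uncertainty_shock" if shock else "uncertainty_omission"
    return cue


@dataclass(frozen=True)
class TrialRecord:
    """One cue presentation.

    Parameters
    ----------
    index : 0-based position of the trial in the session.
    cue : one of :data:`CUES`.
    shock : whether foot shock follows this trial.
    onset : cue onset, seconds from session start.
    """

    index: int
    cue: str
    shock: bool
    onset: float

    def __post_init__(self) -> None:
        if self.cue not in CUES:
            raise ValueError(f"unknown cue label {self.cue!r}")
        if self.onset < 0:
            raise ValueError("trial onset must be non-negative")

    @property
    def trial_type(self) -> str:
        return trial_type(self.cue, self.shock)


@dataclass(frozen=True)
class SessionMeta:
    rat: str
    group: str
    session: str
    seed: int | None = None
    cue_duration: float = 10.0
    pre_window: float = 20.0
    post_window: float = 20.0


@dataclass
class SessionBundle:
    """Trials, nose pokes and per-unit spike trains for one session.

    ``pokes`` and every entry of ``units`` are sorted, non-negative
    timestamp arrays in seconds from session start.
    """

    trials: list[TrialRecord]
    pokes: np.ndarray
    units: dict[str, np.ndarray]
    meta: SessionMeta

    def __post_init__(self) -> None:
        self.pokes = np.asarray(self.pokes, dtype=float)
        self.units = {k: np.asarray(v, dtype=float) for k, v in self.units.items()}

    def validate(self) -> None:
        """Check ordering/spacing invariants; raise ``ValueError`` on breach."""
        onsets = np.array([t.onset for t in self.trials])
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        min_gap = self.meta.pre_window + self.meta.cue_duration + self.meta.post_window
        if onsets.size > 1 and np.any(np.diff(onsets) < min_gap - 1e-9):
            raise ValueError(
                f"inter-onset gap below pre+cue+post = {min_gap:g} s; "
                "peri-event windows would overlap"
            )
        if onsets.size and onsets[0] < self.meta.pre_window - 1e-9:
            raise ValueError("first onset closer to session start than pre_window")
        for name, ts in [("pokes", self.pokes)] + [
            (f"unit {u}", s) for u, s in self.units.items()
        ]:
            if ts.size and ts.min() < 0:
                raise ValueError(f"{name}: negative timestamp")
            if np.any(np.diff(ts) < 0):
                raise ValueError(f"{name}: timestamps not sorted")

    def with_units(self, units: dict[str, np.ndarray]) -> "SessionBundle":
        return replace(self, units=units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_of(self, cue: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.cue == cue]
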