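"""Peri-event binning, differential firing and unit-level Z-normalization.

Firing is binned at 250 ms from 20 s before cue onset to 20 s after cue
offset (200 bins for a 10 s cue). For each trial type the trial-averaged
trace is differenced against that type's own 2 s pre-onset baseline mean,
and the differential traces of all trial types are jointly Z-scored with
one (mu, sigma) per unit, so that across the concatenation mean firing is
0 and the standard deviation is 1. Normalizing over the whole recording
epoch (rather than the baseline alone) keeps units with little or no
baseline activity well-defined; it also means normalized baseline activity
need not sit exactly at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import SessionBundle, TrialRecord

BIN_WIDTH = 0.25
PRE_S = 20.0
POST_S = 20.0

#: Named epochs used for responsiveness screening, seconds relative to onset.
EPOCHS = {
    "baseline10": (-10.0, 0.0),
    "first1": (0.0, 1.0),
    "first5": (0.0, 5.0),
    "last5": (5.0, 10.0),
}

#: Window used to baseline the differential traces, relative to onset.
DIFF_BASELINE = (-2.0, 0.0)


def bin_edges(cue_duration: float = 10.0) -> np.ndarray:
    """Half-open 250 ms bin edges spanning [-PRE_S, cue_duration + POST_S)."""
    n = int(round((PRE_S + cue_duration + POST_S) / BIN_WIDTH))
    return -PRE_S + BIN_WIDTH * np.arange(n + 1)


def bin_trial(spikes: np.ndarray, onset: float, cue_duration: float = 10.0) -> np.ndarray:
    """Firing rate (Hz) in each 250 ms peri-onset bin of one trial."""
    edges = onset + bin_edges(cue_duration)
    counts = np.diff(np.searchsorted(np.asarray(spikes), edges, side="left"))
    return counts / BIN_WIDTH


def epoch_rate(spikes: np.ndarray, onset: float, epoch: str) -> float:
    """Raw firing rate (Hz) in a named epoch of one trial."""
    a, b = EPOCHS[epoch]
    spikes = np.asarray(spikes)
    n = np.searchsorted(spikes, onset + b, side="left") - np.searchsorted(
        spikes, onset + a, side="left"
    )
    return float(n) / (b - a)


def interval_rate(spikes: np.ndarray, onset: float, start: float, end: float) -> float:
    """Raw firing rate (Hz) in [onset+start, onset+end)."""
    spikes = np.asarray(spikes)
    n = np.searchsorted(spikes, onset + end, side="left") - np.searchsorted(
        spikes, onset + start, side="left"
    )
    return float(n) / (end - start)


def _group_trials(trials: list[TrialRecord], collapse_uncertainty: bool) -> dict:
    groups: dict[str, list[TrialRecord]] = {}
    for tr in trials:
        key = tr.cue if collapse_uncertainty else tr.trial_type
        groups.setdefault(key, []).append(tr)
    return groups


def trialtype_mean_traces(
    spikes: np.ndarray,
    trials: list[TrialRecord],
    cue_duration: float = 10.0,
    collapse_uncertainty: bool = True,
) -> dict[str, np.ndarray]:
    """Trial-averaged 250 ms rate trace per trial type.

    With ``collapse_uncertainty`` the two uncertainty outcomes are pooled
    before averaging (during the cue the animal cannot distinguish them).
    """
    groups = _group_trials(trials, collapse_uncertainty)
    if not groups:
        raise ValueError("no trials supplied")
    return {
        key: np.mean([bin_trial(spikes, tr.onset, cue_duration) for tr in trs], axis=0)
        for key, trs in groups.items()
    }


@dataclass
class UnitTraces:
    """Mean, differential and Z-normalized traces for one unit.

    ``mu``/``sigma`` are computed over the concatenation of every trial
    type's differential trace (each type contributing its bins once) and
    are reused to normalize single-trial firing. ``degenerate`` marks
    units whose differential traces carry no variance; such units are
    excluded from normalized analyses.
    """

    mean: dict[str, np.ndarray]
    diff: dict[str, np.ndarray]
    z: dict[str, np.ndarray]
    mu: float
    sigma: float
    degenerate: bool
    cue_duration: float = 10.0

    @property
    def types(self) -> list[str]:
        return list(self.mean)


def znorm_unit(mean_traces: dict[str, np.ndarray], cue_duration: float = 10.0) -> UnitTraces:
    """Differential and Z-normalized traces from per-type mean traces."""
    edges = bin_edges(cue_duration)
    starts = edges[:-1]
    base_mask = (starts >= DIFF_BASELINE[0]) & (starts < DIFF_BASELINE[1])
    diff = {
        key: trace - trace[base_mask].mean() for key, trace in mean_traces.items()
    }
    concat = np.concatenate(list(diff.values()))
    mu = float(concat.mean())
    sigma = float(concat.std(ddof=0))
    degenerate = not sigma > 0.0
    if degenerate:
        z = {key: np.full_like(d, np.nan) for key, d in diff.items()}
        sigma = 0.0
    else:
        z = {key: (d - mu) / sigma for key, d in diff.items()}
    return UnitTraces(
        mean=dict(mean_traces), diff=diff, z=z, mu=mu, sigma=sigma,
        degenerate=degenerate, cue_duration=cue_duration,
    )


def unit_traces(
    spikes: np.ndarray,
    trials: list[TrialRecord],
    cue_duration: float = 10.0,
    collapse_uncertainty: bool = True,
) -> UnitTraces:
    """Convenience: binning, averaging and normalization in one call."""
    return znorm_unit(
        trialtype_mean_traces(spikes, trials, cue_duration, collapse_uncertainty),
        cue_duration,
    )


def znorm_trial_firing(
    spikes: np.ndarray,
    trial: TrialRecord,
    interval: tuple[float, float],
    traces: UnitTraces,
    per_trial_baseline: bool = True,
) -> float:
    """Single-trial normalized firing in ``interval`` (s relative to onset).

    The trial's mean rate over the interval is differenced against that
    trial's own 2 s pre-onset baseline (set ``per_trial_baseline=False``
    to skip the differencing) and transformed with the unit's (mu, sigma).
    With per-trial differencing, a trial whose firing equals its type's
    mean trace in every bin reproduces the mean of the z-trace over the
    interval's bins exactly.
    """
    if traces.degenerate:
        raise ValueError("unit is degenerate (zero-variance differential firing)")
    x = interval_rate(spikes, trial.onset, interval[0], interval[1])
    if per_trial_baseline:
        x -= interval_rate(spikes, trial.onset, DIFF_BASELINE[0], DIFF_BASELINE[1])
    return (x - traces.mu) / traces.sigma


def epoch_rate_table(
    spikes: np.ndarray, trials: list[TrialRecord], epochs: tuple[str, ...] | None = None
) -> dict[str, np.ndarray]:
    """Per-trial raw rates for the named epochs, as arrays over trials."""
    names = tuple(EPOCHS) if epochs is None else epochs
    return {
        name: np.array([epoch_rate(spikes, tr.onset, name) for tr in trials])
        for name in names
    }
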