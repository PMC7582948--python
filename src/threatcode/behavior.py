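"""Conditioned suppression of rewarded nose poking.

Fear on a trial is quantified by the suppression ratio

    (baseline poke rate - cue poke rate) / (baseline poke rate + cue poke rate)

with the baseline rate taken from the 20 s immediately preceding cue onset
(that trial's own baseline only) and the cue rate from the 10 s cue. A
ratio of 1 indicates complete suppression (high fear), 0 no suppression
(low fear); negative values indicate poking above baseline.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .session import SessionBundle


def poke_rate(pokes: np.ndarray, window_start: float, window_end: float) -> float:
    """Event rate (Hz) in the half-open window [start, end)."""
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    pokes = np.asarray(pokes)
    n = np.searchsorted(pokes, window_end, side="left") - np.searchsorted(
        pokes, window_start, side="left"
    )
    return float(n) / (window_end - window_start)


def suppression_ratio(
    baseline_rate: float, cue_rate: float, zero_zero: str = "nan"
) -> float:
    """Suppression ratio; ``zero_zero`` selects the 0/0 policy ("nan" or "zero").

    A trial with no pokes in either window carries no information about
    fear, so by default the ratio is recorded as missing (NaN) and the
    trial drops out of means and regressions downstream.
    """
    if baseline_rate < 0 or cue_rate < 0:
        raise ValueError("rates must be non-negative")
    denom = baseline_rate + cue_rate
    if denom == 0:
        if zero_zero == "zero":
            return 0.0
        if zero_zero == "nan":
            return math.nan
        raise ValueError(f"unknown zero_zero policy {zero_zero!r}")
    return (baseline_rate - cue_rate) / denom


def session_suppression(
    bundle: SessionBundle,
    baseline_window: float = 20.0,
    zero_zero: str = "nan",
) -> pd.DataFrame:
    """Per-trial suppression records for one session.

    Returns a DataFrame with columns (rat, group, session, trial_index,
    cue, shock, baseline_rate_hz, cue_rate_hz, ratio); each trial's ratio
    uses exclusively its own pre-onset baseline.
    """
    cue_dur = bundle.meta.cue_duration
    rows = []
    for tr in bundle.trials:
        b = poke_rate(bundle.pokes, tr.onset - baseline_window, tr.onset)
        c = poke_rate(bundle.pokes, tr.onset, tr.onset + cue_dur)
        rows.append(
            {
                "rat": bundle.meta.rat,
                "group": bundle.meta.group,
                "session": bundle.meta.session,
                "trial_index": tr.index,
                "cue": tr.cue,
                "shock": tr.shock,
                "baseline_rate_hz": b,
                "cue_rate_hz": c,
                "ratio": suppression_ratio(b, c, zero_zero=zero_zero),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rat", "group", "session", "trial_index", "cue", "shock",
            "baseline_rate_hz", "cue_rate_hz", "ratio",
        ],
    )
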