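"""Trial-by-trial encoding regression and the threat-probability tuning curve.

For one unit and one time interval, normalized single-trial firing y is
modeled by ordinary least squares as

    y = b0 + b_fear * (suppression ratio of the trial, full 10 s cue)
           + b_threat * (shock probability assigned to the trial's cue)

over the session's trials. Danger is assigned probability 1, safety 0 and
uncertainty a configurable value u (the task's actual value is 0.375).
Because measured fear to uncertainty sits well above 0.375 times fear to
danger, the two regressors decorrelate enough for distinct betas to be
identifiable. Regressors are left on their native scales (probabilities
and ratios), so betas are in normalized-firing units per unit regressor.

The tuning curve repeats the regression for u = 0.000 to 1.000 in 0.125
steps, averaging the threat beta over the ten 1 s cue intervals; the grid
point with the largest mean beta estimates the probability the population
actually assigns to the uncertainty cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import TrialRecord
from .spikes import UnitTraces, znorm_trial_firing

#: The nine uncertainty assignments of the tuning sweep.
U_GRID = np.linspace(0.0, 1.0, 9)

#: Minimum usable trials for a session-level regression.
MIN_TRIALS = 8


class ExcludedUnitError(ValueError):
    """Raised when a unit-session cannot support the regression."""


@dataclass
class DesignMatrix:
    """Constant + fear-output + threat-probability design for one session."""

    X: np.ndarray  # (n_usable, 3): [1, fear, threat]
    trial_indices: np.ndarray  # session trial indices of the usable rows
    u: float
    rank: int

    @property
    def full_rank(self) -> bool:
        return self.rank == 3


def build_design(
    trials: list[TrialRecord], ratios: pd.Series | dict, u: float
) -> DesignMatrix:
    """Assemble the design matrix; trials with missing suppression drop out.

    ``ratios`` maps trial_index -> suppression ratio (NaN allowed).
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    get = ratios.get if isinstance(ratios, dict) else lambda i: ratios.loc[i]
    threat_of = {"danger": 1.0, "uncertainty": float(u), "safety": 0.0}
    rows, idx = [], []
    for tr in trials:
        r = float(get(tr.index))
        if np.isfinite(r):
            rows.append([1.0, r, threat_of[tr.cue]])
            idx.append(tr.index)
    if len(rows) < MIN_TRIALS:
        raise ExcludedUnitError(
            f"only {len(rows)} usable trials (< {MIN_TRIALS}); unit-session excluded"
        )
    X = np.asarray(rows)
    return DesignMatrix(
        X=X, trial_indices=np.asarray(idx), u=float(u),
        rank=int(np.linalg.matrix_rank(X)),
    )


def ols_betas(y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Least-squares coefficients (b0, b_fear, b_threat).

    A rank-deficient design (e.g. constant suppression column) yields the
    minimum-norm solution; callers should check ``design.full_rank`` and
    treat the betas as unidentified.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.X.shape[0]:
        raise ValueError("y length does not match design rows")
    beta, *_ = np.linalg.lstsq(design.X, y, rcond=None)
    return beta


def unit_beta_series(
    spikes: np.ndarray,
    trials: list[TrialRecord],
    ratios: pd.Series | dict,
    traces: UnitTraces,
    u: float = 0.375,
    per_trial_baseline: bool = False,
) -> pd.DataFrame:
    """Fear/threat betas for each 1 s interval of the cue.

    Returns a DataFrame with columns (interval, u, beta_const, beta_fear,
    beta_threat, full_rank); intervals are [k, k+1) s from cue onset.

    By default y is the undifferenced normalized rate: the per-trial 2 s
    baseline estimate is noise shared across all ten intervals (the
    constant regressor already absorbs baseline level), so differencing
    roughly doubles the spread of the recovered betas without removing
    any bias. Set ``per_trial_baseline=True`` for values consistent with
    the differenced mean z-traces.
    """
    design = build_design(trials, ratios, u)
    by_index = {tr.index: tr for tr in trials}
    used = [by_index[i] for i in design.trial_indices]
    n_int = int(round(traces.cue_duration))
    rows = []
    for k in range(n_int):
        y = np.array(
            [
                znorm_trial_firing(
                    spikes, tr, (float(k), float(k + 1)), traces, per_trial_baseline
                )
                for tr in used
            ]
        )
        b = ols_betas(y, design)
        rows.append(
            {
                "interval": k,
                "u": design.u,
                "beta_const": b[0],
                "beta_fear": b[1],
                "beta_threat": b[2],
                "full_rank": design.full_rank,
            }
        )
    return pd.DataFrame(rows)


def tuning_curve(
    spikes: np.ndarray,
    trials: list[TrialRecord],
    ratios: pd.Series | dict,
    traces: UnitTraces,
    u_grid: np.ndarray = U_GRID,
    per_trial_baseline: bool = False,
) -> pd.DataFrame:
    """Mean threat beta (over the ten 1 s intervals) per uncertainty assignment."""
    rows = []
    for u in u_grid:
        series = unit_beta_series(
            spikes, trials, ratios, traces, u=float(u),
            per_trial_baseline=per_trial_baseline,
        )
        rows.append(
            {
                "u": float(u),
                "mean_beta_threat": series["beta_threat"].mean(),
                "mean_beta_fear": series["beta_fear"].mean(),
                "full_rank": bool(series["full_rank"].all()),
            }
        )
    return pd.DataFrame(rows)


def tuning_peak(curve: pd.DataFrame) -> float:
    """Uncertainty assignment at which the mean threat beta is maximal."""
    return float(curve.loc[curve["mean_beta_threat"].idxmax(), "u"])
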