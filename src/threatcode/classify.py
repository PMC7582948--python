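"""Screening units into cue-excited, cue-inhibited or outside selection criteria.

For each cue, raw firing rate (Hz) in the 10 s pre-onset baseline is
compared against cue epochs with a two-tailed paired t test across trials,
Bonferroni-corrected for six comparisons (threshold 0.05/6; the exact
fraction, not its display rounding). A unit is cue-excited if at least one
test shows a significant increase and none shows a significant decrease;
cue-inhibited conversely; anything else is outside the selection criteria
(osc). Screening uses raw rates, not normalized firing.

Two epoch schemes are available. The default, ``class_specific``, screens
excitation on the first 1 s and last 5 s of the cue and inhibition on the
first 5 s and last 5 s; ``uniform`` screens both directions on the first
1 s and last 5 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .session import CUES, TrialRecord
from .spikes import epoch_rate

#: Bonferroni-corrected threshold: six comparisons at familywise 0.05.
ALPHA_CORRECTED = 0.05 / 6

EPOCH_SCHEMES = {
    "class_specific": {"excited": ("first1", "last5"), "inhibited": ("first5", "last5")},
    "uniform": {"excited": ("first1", "last5"), "inhibited": ("first1", "last5")},
}


@dataclass(frozen=True)
class EpochTest:
    cue: str
    epoch: str
    t: float
    p: float
    direction: int  # sign of mean(epoch - baseline)
    zero_variance: bool = False


@dataclass
class UnitClassification:
    unit: str
    label: str  # {"excited", "inhibited", "osc"}
    tests: list[EpochTest] = field(default_factory=list)
    alpha: float = ALPHA_CORRECTED


def epoch_ttest(
    spikes: np.ndarray, trials: list[TrialRecord], cue: str, epoch: str
) -> EpochTest:
    """Paired t test of per-trial epoch rate vs 10 s pre-cue baseline rate.

    Zero-variance differences (including the all-zero case) cannot support
    a t test; they are flagged and reported non-significant (p = 1).
    """
    trs = [t for t in trials if t.cue == cue]
    if len(trs) < 2:
        raise ValueError(f"need >= 2 trials of cue {cue!r} for a paired t test")
    base = np.array([epoch_rate(spikes, t.onset, "baseline10") for t in trs])
    ep = np.array([epoch_rate(spikes, t.onset, epoch) for t in trs])
    d = ep - base
    direction = int(np.sign(d.mean()))
    if np.allclose(d, d[0]):
        return EpochTest(cue, epoch, t=0.0, p=1.0, direction=direction, zero_variance=True)
    t_stat, p = stats.ttest_rel(ep, base)
    return EpochTest(cue, epoch, t=float(t_stat), p=float(p), direction=direction)


def classify_unit(
    unit: str,
    spikes: np.ndarray,
    trials: list[TrialRecord],
    epoch_scheme: str = "class_specific",
    alpha: float = ALPHA_CORRECTED,
) -> UnitClassification:
    """Label one unit excited / inhibited / osc from its six epoch tests."""
    scheme = EPOCH_SCHEMES[epoch_scheme]
    epochs_needed = sorted(set(scheme["excited"]) | set(scheme["inhibited"]))
    tests = {
        (cue, epoch): epoch_ttest(spikes, trials, cue, epoch)
        for cue in CUES
        for epoch in epochs_needed
    }
    sig_inc = any(
        tests[(cue, e)].p < alpha and tests[(cue, e)].direction > 0
        for cue in CUES
        for e in scheme["excited"]
    )
    sig_dec = any(
        tests[(cue, e)].p < alpha and tests[(cue, e)].direction < 0
        for cue in CUES
        for e in scheme["inhibited"]
    )
    if sig_inc and not sig_dec:
        label = "excited"
    elif sig_dec and not sig_inc:
        label = "inhibited"
    else:
        label = "osc"
    return UnitClassification(unit=unit, label=label, tests=list(tests.values()), alpha=alpha)


def responsive_proportions(labels_by_group: dict[str, list[str]]) -> np.ndarray:
    """2x2 counts [responsive, non-responsive] per group for a chi-square test.

    Responsive pools excited and inhibited units; rows follow the dict's
    key order.
    """
    if len(labels_by_group) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for grp, labels in labels_by_group.items():
        if not labels:
            raise ValueError(f"group {grp!r} has no units")
        responsive = sum(1 for lab in labels if lab in ("excited", "inhibited"))
        rows.append([responsive, len(labels) - responsive])
    return np.array(rows, dtype=int)
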