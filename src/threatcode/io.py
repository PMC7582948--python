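"""On-disk dialect for session bundles and derived tables.

A session directory contains four mandatory files::

    trials.csv   trial_index, cue, shock, onset_s
    pokes.csv    time_s
    spikes.csv   unit_id, time_s
    meta.json    rat, group, session, seed, cue_duration, pre_window, post_window

plus an optional ``truth.csv`` with simulator ground truth. All event
times are seconds from session start, written with six decimal places;
headers are mandatory; cue labels are canonicalized to lowercase on read.
Derived tables are CSV with a fixed column order and floats at six
significant digits, so re-running an analysis on identical inputs yields
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import CUES, SessionBundle, SessionMeta, TrialRecord

MANDATORY_FILES = ("trials.csv", "pokes.csv", "spikes.csv", "meta.json")

TIME_FMT = "%.6f"


class SessionFormatError(ValueError):
    """A session directory violates the on-disk dialect."""


def write_session(bundle: SessionBundle, path: str | Path, truth: pd.DataFrame | None = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials = pd.DataFrame(
        {
            "trial_index": [t.index for t in bundle.trials],
            "cue": [t.cue for t in bundle.trials],
            "shock": [int(t.shock) for t in bundle.trials],
            "onset_s": [t.onset for t in bundle.trials],
        }
    )
    trials.to_csv(path / "trials.csv", index=False, float_format=TIME_FMT)
    pd.DataFrame({"time_s": bundle.pokes}).to_csv(
        path / "pokes.csv", index=False, float_format=TIME_FMT
    )
    spike_frames = [
        pd.DataFrame({"unit_id": uid, "time_s": ts}) for uid, ts in bundle.units.items()
    ]
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    spikes.to_csv(path / "spikes.csv", index=False, float_format=TIME_FMT)
    meta = {
        "rat": bundle.meta.rat,
        "group": bundle.meta.group,
        "session": bundle.meta.session,
        "seed": bundle.meta.seed,
        "cue_duration": bundle.meta.cue_duration,
        "pre_window": bundle.meta.pre_window,
        "post_window": bundle.meta.post_window,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    if truth is not None:
        truth.to_csv(path / "truth.csv", index=False, float_format=TIME_FMT)
    return path


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{fname}: missing column(s) {missing}")


def _check_sorted(times: np.ndarray, fname: str, offset: int = 2) -> None:
    bad = np.flatnonzero(np.diff(times) < 0)
    if bad.size:
        # +offset: header line plus 1-based indexing of the first offender's row
        raise SessionFormatError(
            f"{fname}, line {bad[0] + 1 + offset}: timestamps decrease"
        )


def read_session(path: str | Path) -> SessionBundle:
    """Load and validate a session directory.

    Violations of the dialect (missing files, unknown cue labels, unsorted
    timestamps, trial-spacing breaches) raise :class:`SessionFormatError`
    naming the offending file and line.
    """
    path = Path(path)
    for fname in MANDATORY_FILES:
        if not (path / fname).exists():
            raise SessionFormatError(f"missing mandatory file {fname} in {path}")
    meta_raw = json.loads((path / "meta.json").read_text())
    meta = SessionMeta(
        rat=str(meta_raw["rat"]),
        group=str(meta_raw["group"]),
        session=str(meta_raw["session"]),
        seed=meta_raw.get("seed"),
        cue_duration=float(meta_raw.get("cue_duration", 10.0)),
        pre_window=float(meta_raw.get("pre_window", 20.0)),
        post_window=float(meta_raw.get("post_window", 20.0)),
    )
    tdf = pd.read_csv(path / "trials.csv")
    _require_columns(tdf, ("trial_index", "cue", "shock", "onset_s"), "trials.csv")
    trials = []
    for row_no, row in enumerate(tdf.itertuples(index=False), start=2):
        cue = str(row.cue).strip().lower()
        if cue not in CUES:
            raise SessionFormatError(
                f"trials.csv, line {row_no}: unknown cue label {row.cue!r}"
            )
        trials.append(
            TrialRecord(
                index=int(row.trial_index),
                cue=cue,
                shock=bool(int(row.shock)),
                onset=float(row.onset_s),
            )
        )
    pdf = pd.read_csv(path / "pokes.csv")
    _require_columns(pdf, ("time_s",), "pokes.csv")
    pokes = pdf["time_s"].to_numpy(dtype=float)
    _check_sorted(pokes, "pokes.csv", offset=1)
    sdf = pd.read_csv(path / "spikes.csv")
    _require_columns(sdf, ("unit_id", "time_s"), "spikes.csv")
    units: dict[str, np.ndarray] = {}
    for uid, grp in sdf.groupby("unit_id", sort=False):
        ts = grp["time_s"].to_numpy(dtype=float)
        _check_sorted(ts, f"spikes.csv (unit {uid})", offset=int(grp.index[0]) + 1)
        units[str(uid)] = ts
    bundle = SessionBundle(trials=trials, pokes=pokes, units=units, meta=meta)
    try:
        bundle.validate()
    except ValueError as e:
        raise SessionFormatError(f"{path}: {e}") from e
    return bundle


def read_truth(path: str | Path) -> pd.DataFrame | None:
    f = Path(path) / "truth.csv"
    return pd.read_csv(f) if f.exists() else None


# ---------------------------------------------------------------------------
# Derived tables

TABLE_SCHEMAS = {
    "suppression": [
        "rat", "group", "session", "trial_index", "cue",
        "baseline_rate_hz", "cue_rate_hz", "ratio",
    ],
    "classification": ["unit", "rat", "group", "session", "label", "cue", "epoch", "t", "p"],
    "traces": ["unit", "group", "trial_type", "bin_index", "bin_start_s", "diff_hz", "z"],
    "epoch_rates": ["unit", "group", "trial_index", "cue", "epoch", "rate_hz"],
    "betas": ["unit", "group", "interval", "u", "beta_fear", "beta_threat"],
    "tuning": ["unit", "group", "u", "mean_beta_threat"],
}

FLOAT_FMT = "%.6g"


def write_outputs(results: dict[str, pd.DataFrame], path: str | Path) -> dict[str, Path]:
    """Write derived tables as deterministic CSV (fixed columns, %.6g floats).

    Unknown table names are written with their existing column order.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in results.items():
        cols = TABLE_SCHEMAS.get(name)
        if cols is not None:
            df = df.reindex(columns=cols)
        out = path / f"{name}.csv"
        df.to_csv(out, index=False, float_format=FLOAT_FMT)
        written[name] = out
    return written
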