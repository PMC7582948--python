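"""End-to-end analysis: behavior -> spikes -> classify -> encoding -> popstats.

`analyze_cohort` runs every stage over a list of session bundles and
returns long-format tables plus a JSON-serializable statistics report.
Exclusions (degenerate units, rank-deficient designs, trials without a
defined suppression ratio) are recorded, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, classify, encoding, popstats, spikes
from .session import SessionBundle
from .spikes import bin_edges

log = logging.getLogger("threatcode")


@dataclass(frozen=True)
class AnalysisConfig:
    """Switches governing a pipeline run."""

    collapse_uncertainty: bool = True
    epoch_scheme: str = "class_specific"
    per_trial_baseline: bool = False
    u_primary: float = 0.375
    u_grid: tuple = tuple(encoding.U_GRID)
    zero_zero: str = "nan"
    #: bins entering the population firing ANOVA, s relative to onset
    anova_bin_window: tuple = (-2.0, 12.0)


@dataclass
class CohortResults:
    suppression: pd.DataFrame
    classification: pd.DataFrame
    traces: pd.DataFrame
    betas: pd.DataFrame
    tuning: pd.DataFrame
    coupling: pd.DataFrame
    stats_report: dict
    exclusions: list = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "suppression": self.suppression,
            "classification": self.classification,
            "traces": self.traces,
            "betas": self.betas,
            "tuning": self.tuning,
            "coupling": self.coupling,
        }


def _unit_label_table(classifications: list) -> pd.DataFrame:
    rows = []
    for meta, cl in classifications:
        for test in cl.tests:
            rows.append(
                {
                    "unit": cl.unit,
                    "rat": meta.rat,
                    "group": meta.group,
                    "session": meta.session,
                    "label": cl.label,
                    "cue": test.cue,
                    "epoch": test.epoch,
                    "t": test.t,
                    "p": test.p,
                }
            )
    return pd.DataFrame(rows)


def analyze_cohort(
    bundles: list[SessionBundle], config: AnalysisConfig = AnalysisConfig()
) -> CohortResults:
    if not bundles:
        raise ValueError("no session bundles supplied")
    for b in bundles:
        b.validate()

    sup_frames, class_rows, trace_rows, beta_rows, tuning_rows = [], [], [], [], []
    exclusions: list[dict] = []
    unit_summary_rows = []

    for bundle in bundles:
        sup = behavior.session_suppression(bundle, zero_zero=config.zero_zero)
        sup_frames.append(sup)
        ratios = sup.set_index("trial_index")["ratio"]
        n_missing = int((~np.isfinite(ratios)).sum())
        if n_missing:
            exclusions.append(
                {
                    "kind": "missing_suppression_trials",
                    "where": f"{bundle.meta.rat}/{bundle.meta.session}",
                    "n": n_missing,
                }
            )
        edges = bin_edges(bundle.meta.cue_duration)
        for unit_id, train in bundle.units.items():
            cl = classify.classify_unit(
                unit_id, train, bundle.trials, epoch_scheme=config.epoch_scheme
            )
            class_rows.append((bundle.meta, cl))
            traces = spikes.unit_traces(
                train,
                bundle.trials,
                cue_duration=bundle.meta.cue_duration,
                collapse_uncertainty=config.collapse_uncertainty,
            )
            for tt, z in traces.z.items():
                d = traces.diff[tt]
                for k in range(z.size):
                    trace_rows.append(
                        (unit_id, bundle.meta.group, cl.label, tt, k, edges[k], d[k], z[k])
                    )
            if traces.degenerate:
                exclusions.append(
                    {"kind": "degenerate_unit", "where": unit_id, "n": 1}
                )
                unit_summary_rows.append(
                    _unit_summary(bundle, unit_id, cl.label, None, None)
                )
                continue
            try:
                series = encoding.unit_beta_series(
                    train, bundle.trials, ratios, traces,
                    u=config.u_primary, per_trial_baseline=config.per_trial_baseline,
                )
                curve = encoding.tuning_curve(
                    train, bundle.trials, ratios, traces,
                    u_grid=np.asarray(config.u_grid),
                    per_trial_baseline=config.per_trial_baseline,
                )
            except encoding.ExcludedUnitError as e:
                exclusions.append({"kind": "too_few_trials", "where": unit_id, "n": 1})
                log.warning("unit %s excluded from regression: %s", unit_id, e)
                unit_summary_rows.append(
                    _unit_summary(bundle, unit_id, cl.label, None, None)
                )
                continue
            if not series["full_rank"].all():
                exclusions.append({"kind": "rank_deficient", "where": unit_id, "n": 1})
            for row in series.itertuples(index=False):
                beta_rows.append(
                    (unit_id, bundle.meta.group, cl.label, row.interval, row.u,
                     row.beta_fear, row.beta_threat)
                )
            for row in curve.itertuples(index=False):
                tuning_rows.append(
                    (unit_id, bundle.meta.group, cl.label, row.u,
                     row.mean_beta_threat, row.mean_beta_fear)
                )
            unit_summary_rows.append(
                _unit_summary(bundle, unit_id, cl.label, traces, series)
            )

    suppression = pd.concat(sup_frames, ignore_index=True)
    classification = _unit_label_table(class_rows)
    traces_df = pd.DataFrame(
        trace_rows,
        columns=["unit", "group", "label", "trial_type", "bin_index", "bin_start_s",
                 "diff_hz", "z"],
    )
    betas = pd.DataFrame(
        beta_rows,
        columns=["unit", "group", "label", "interval", "u", "beta_fear", "beta_threat"],
    )
    tuning = pd.DataFrame(
        tuning_rows,
        columns=["unit", "group", "label", "u", "mean_beta_threat", "mean_beta_fear"],
    )
    units = pd.DataFrame(unit_summary_rows)

    coupling, coupling_stats = _coupling_tables(units)
    report = _stats_report(
        suppression, classification, traces_df, betas, tuning, units, config
    )
    report["coupling"] = coupling_stats
    report["exclusions"] = exclusions
    return CohortResults(
        suppression=suppression,
        classification=classification,
        traces=traces_df,
        betas=betas,
        tuning=tuning,
        coupling=coupling,
        stats_report=report,
        exclusions=exclusions,
    )


def _unit_summary(bundle, unit_id, label, traces, series):
    """Per-unit scalars feeding the firing/signaling coupling analysis."""
    row = {
        "unit": unit_id,
        "rat": bundle.meta.rat,
        "group": bundle.meta.group,
        "session": bundle.meta.session,
        "label": label,
    }
    train = bundle.units[unit_id]
    for cue in ("danger", "uncertainty", "safety"):
        trs = bundle.trials_of(cue)
        if traces is not None and not traces.degenerate:
            key = cue  # collapse on: traces keyed by cue
            z = traces.z.get(key)
            edges = bin_edges(bundle.meta.cue_duration)[:-1]
            if z is not None:
                first1 = (edges >= 0.0) & (edges < 1.0)
                last5 = (edges >= 5.0) & (edges < 10.0)
                row[f"z_first1_{cue}"] = float(z[first1].mean())
                row[f"z_last5_{cue}"] = float(z[last5].mean())
    if series is not None:
        row["mean_beta_threat"] = float(series["beta_threat"].mean())
        row["mean_beta_fear"] = float(series["beta_fear"].mean())
        last = series[series["interval"] >= 5]
        row["beta_fear_last5"] = float(last["beta_fear"].mean())
        row["beta_threat_last5"] = float(last["beta_threat"].mean())
    return row


#: firing epoch and regressor compared per functional population,
#: mirroring the onset-firing/threat and late-firing/fear analyses
COUPLING_PLAN = {
    "excited": ("z_first1", "mean_beta_threat"),
    "inhibited": ("z_last5", "beta_fear_last5"),
}


def _coupling_tables(units: pd.DataFrame):
    rows, stats_out = [], {}
    if units.empty or "label" not in units:
        return pd.DataFrame(), stats_out
    groups = sorted(units["group"].unique())
    for pop, (epoch_col, beta_col) in COUPLING_PLAN.items():
        if beta_col not in units.columns:
            continue
        sub = units[(units["label"] == pop) & units[beta_col].notna()]
        for cue in ("danger", "uncertainty", "safety"):
            xcol = f"{epoch_col}_{cue}"
            if xcol not in sub.columns:
                continue
            per_group = {}
            for grp in groups:
                gsub = sub[sub["group"] == grp].dropna(subset=[xcol, beta_col])
                if len(gsub) < 4:
                    continue
                try:
                    res = popstats.pearson_coupling(gsub[xcol], gsub[beta_col])
                except ValueError:
                    continue
                per_group[grp] = res
                rows.append(
                    {
                        "population": pop, "cue": cue, "group": grp,
                        "firing_epoch": epoch_col, "regressor": beta_col,
                        "slope": res.slope, "intercept": res.intercept,
                        "r": res.r, "r_squared": res.r_squared,
                        "p": res.p, "n": res.n,
                    }
                )
            if len(per_group) == 2:
                (g1, r1), (g2, r2) = per_group.items()
                z, pz = popstats.fisher_r_to_z(r1.r, r1.n, r2.r, r2.n)
                stats_out[f"{pop}_{cue}_fisher"] = {
                    "groups": [g1, g2], "Z": z, "p": pz,
                }
    return pd.DataFrame(rows), stats_out


def _anova_to_dict(res: dict) -> dict:
    return {
        name: {
            "F": r.F, "df_num": r.df_num, "df_den": r.df_den,
            "p": r.p, "partial_eta_sq": r.partial_eta_sq,
        }
        for name, r in res.items()
        if name != "subjects"
    }


def _stats_report(suppression, classification, traces_df, betas, tuning, units, config):
    report: dict = {}

    # behavioral discrimination: group x cue on per-rat mean ratios
    rat_means = (
        suppression.dropna(subset=["ratio"])
        .groupby(["rat", "group", "cue"], as_index=False, observed=True)["ratio"]
        .mean()
    )
    if rat_means["rat"].nunique() > rat_means["group"].nunique():
        try:
            report["suppression_anova"] = _anova_to_dict(
                popstats.mixed_anova(
                    rat_means, dv="ratio", between="group", within="cue", subject="rat"
                )
            )
        except ValueError as e:
            report["suppression_anova"] = {"error": str(e)}

    # responsive proportions
    labels = classification.drop_duplicates("unit")
    by_group = {
        g: labels.loc[labels["group"] == g, "label"].tolist()
        for g in sorted(labels["group"].unique())
    }
    report["n_units"] = {g: len(v) for g, v in by_group.items()}
    report["proportions"] = {
        g: {
            lab: sum(1 for x in v if x == lab) for lab in ("excited", "inhibited", "osc")
        }
        for g, v in by_group.items()
    }
    if len(by_group) == 2 and all(by_group.values()):
        table = classify.responsive_proportions(by_group)
        try:
            chi2, p = popstats.chi_square_2x2(table)
            report["responsive_chi_square"] = {
                "table": table.tolist(), "chi2": chi2, "p": p,
            }
        except ValueError as e:  # degenerate margin (e.g. everyone responsive)
            report["responsive_chi_square"] = {
                "table": table.tolist(), "error": str(e),
            }

    # population firing ANOVA per functional population: group x cue x bin
    lo, hi = config.anova_bin_window
    win = traces_df[(traces_df["bin_start_s"] >= lo) & (traces_df["bin_start_s"] < hi)]
    for pop in ("excited", "inhibited"):
        sub = win[win["label"] == pop].dropna(subset=["z"])
        if sub.empty or sub.groupby("group")["unit"].nunique().min() < 2:
            continue
        if sub["group"].nunique() < 2:
            continue
        try:
            report[f"z_firing_anova_{pop}"] = _anova_to_dict(
                popstats.mixed_anova(
                    sub, dv="z", between="group",
                    within=["trial_type", "bin_index"], subject="unit",
                )
            )
        except ValueError as e:
            report[f"z_firing_anova_{pop}"] = {"error": str(e)}

    # beta ANOVA per population: group x regressor x interval
    for pop in ("excited", "inhibited"):
        sub = betas[betas["label"] == pop]
        if sub.empty or sub["group"].nunique() < 2:
            continue
        long = sub.melt(
            id_vars=["unit", "group", "interval"],
            value_vars=["beta_fear", "beta_threat"],
            var_name="regressor", value_name="beta",
        )
        if long.groupby("group")["unit"].nunique().min() < 2:
            continue
        try:
            report[f"beta_anova_{pop}"] = _anova_to_dict(
                popstats.mixed_anova(
                    long, dv="beta", between="group",
                    within=["regressor", "interval"], subject="unit",
                )
            )
        except ValueError as e:
            report[f"beta_anova_{pop}"] = {"error": str(e)}

    # population tuning curves and peaks
    exc = tuning[tuning["label"] == "excited"]
    if not exc.empty:
        curves = exc.groupby(["group", "u"], as_index=False, observed=True)["mean_beta_threat"].mean()
        report["tuning"] = {
            grp: {
                "u": gsub["u"].tolist(),
                "mean_beta_threat": gsub["mean_beta_threat"].tolist(),
                "peak_u": float(gsub.loc[gsub["mean_beta_threat"].idxmax(), "u"]),
            }
            for grp, gsub in curves.groupby("group", observed=True)
        }
    return report
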