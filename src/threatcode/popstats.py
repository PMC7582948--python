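"""Population-level statistics.

Chi-square comparison of responsive proportions, mixed-design ANOVA with
partial eta squared, Bonferroni-corrected t tests, Pearson firing/signaling
coupling and the Fisher r-to-z comparison of two correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def chi_square_2x2(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    ss: float
    df_num: int
    df_den: int
    ms: float
    F: float
    p: float
    partial_eta_sq: float


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: list[str] | str,
    subject: str,
) -> dict[str, AnovaResult]:
    """Univariate mixed-design ANOVA with one between and 1-2 within factors.

    Each subject must be observed exactly once in every within-factor cell
    (aggregate replicates first). The between effect is tested against
    subjects-within-groups; each within effect and its group interaction
    against the effect x subjects-within-groups stratum; no sphericity
    correction is applied. Group means are observation-weighted, which for
    balanced designs coincides with the Type III decomposition; unbalanced
    group sizes are handled by the same formulas and documented as an
    approximation. Partial eta squared is SS_effect/(SS_effect+SS_error).
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors supported")
    cols = [subject, between, *within, dv]
    df = data[cols].dropna()
    # subject -> group map must be unique
    gmap = df.groupby(subject, observed=True)[between].nunique()
    if (gmap > 1).any():
        raise ValueError("a subject appears in more than one group")
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("missing within-factor cells for some subjects")
    levels = [df[w].drop_duplicates().tolist() for w in within]
    if len(within) == 1:
        wide = wide.reindex(columns=levels[0])
        shape = (len(wide), len(levels[0]))
    else:
        wide = wide.reindex(
            columns=pd.MultiIndex.from_product(levels, names=within)
        )
        shape = (len(wide), len(levels[0]), len(levels[1]))
    x = wide.to_numpy(dtype=float).reshape(shape)
    groups = df.drop_duplicates(subject).set_index(subject)[between].reindex(wide.index)
    glabels = groups.drop_duplicates().tolist()
    gidx = [np.flatnonzero((groups == g).to_numpy()) for g in glabels]
    n_sub, a = x.shape[0], len(glabels)
    J = int(np.prod(x.shape[1:]))
    if a < 2:
        raise ValueError("need >= 2 between-group levels")
    if n_sub <= a:
        raise ValueError("need more subjects than groups")

    gm = x.mean()
    ss_total = float(((x - gm) ** 2).sum())
    m_s = x.reshape(n_sub, J).mean(axis=1)
    m_g = np.array([m_s[idx].mean() for idx in gidx])
    n_g = np.array([len(idx) for idx in gidx])

    out: dict[str, AnovaResult] = {}

    def add(effect, ss, df_num, ss_err, df_den):
        ss, ss_err = float(ss), float(ss_err)
        ms, ms_err = ss / df_num, ss_err / df_den
        F = ms / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(F, df_num, df_den))
        out[effect] = AnovaResult(
            effect, ss, df_num, df_den, ms, F, p,
            partial_eta_sq=ss / (ss + ss_err) if ss + ss_err > 0 else 0.0,
        )

    # between-subjects stratum
    ss_a = J * float((n_g * (m_g - gm) ** 2).sum())
    ss_sa = J * float(
        sum(((m_s[idx] - m_g[i]) ** 2).sum() for i, idx in enumerate(gidx))
    )
    df_sa = n_sub - a
    add(between, ss_a, a - 1, ss_sa, df_sa)
    out["subjects"] = AnovaResult("subjects", ss_sa, df_sa, df_sa, ss_sa / df_sa,
                                  np.nan, np.nan, np.nan)

    accounted = ss_a + ss_sa
    # within-subject strata, one factor at a time
    for wi, w in enumerate(within):
        axis_other = tuple(
            ax for ax in range(1, x.ndim) if ax != wi + 1
        )
        L = x.shape[wi + 1]
        per_level = n_sub * J / L
        mu_w = x.mean(axis=(0, *axis_other))  # (L,)
        ss_w = per_level * float(((mu_w - gm) ** 2).sum())
        # group x level cell means of subject values
        mu_sw = x.mean(axis=axis_other) if axis_other else x  # (n_sub, L)
        mu_gw = np.array([mu_sw[idx].mean(axis=0) for idx in gidx])  # (a, L)
        ss_aw = (J / L) * float(
            (n_g[:, None] * (mu_gw - m_g[:, None] - mu_w[None, :] + gm) ** 2).sum()
        )
        g_of = np.concatenate([[i] * len(idx) for i, idx in enumerate(gidx)])
        order = np.concatenate(gidx)
        resid = (
            mu_sw[order]
            - m_s[order, None]
            - mu_gw[g_of]
            + m_g[g_of, None]
        )
        ss_wsa = (J / L) * float((resid ** 2).sum())
        df_wsa = (L - 1) * df_sa
        add(w, ss_w, L - 1, ss_wsa, df_wsa)
        add(f"{between}:{w}", ss_aw, (a - 1) * (L - 1), ss_wsa, df_wsa)
        accounted += ss_w + ss_aw + ss_wsa

    if len(within) == 2:
        b_lv, c_lv = x.shape[1], x.shape[2]
        mu_bc = x.mean(axis=0)  # (b, c)
        mu_b = mu_bc.mean(axis=1)
        mu_c = mu_bc.mean(axis=0)
        inter = mu_bc - mu_b[:, None] - mu_c[None, :] + gm
        ss_bc = n_sub * float((inter ** 2).sum())
        mu_gbc = np.stack([x[idx].mean(axis=0) for idx in gidx])  # (a, b, c)
        mu_gb = mu_gbc.mean(axis=2)
        mu_gc = mu_gbc.mean(axis=1)
        inter_g = (
            mu_gbc
            - mu_gb[:, :, None]
            - mu_gc[:, None, :]
            + m_g[:, None, None]
            - inter[None, :, :]
        )
        ss_abc = float((n_g[:, None, None] * inter_g ** 2).sum())
        df_bc = (b_lv - 1) * (c_lv - 1)
        ss_bcsa = ss_total - accounted - ss_bc - ss_abc
        df_bcsa = df_bc * df_sa
        add(f"{within[0]}:{within[1]}", ss_bc, df_bc, ss_bcsa, df_bcsa)
        add(f"{between}:{within[0]}:{within[1]}", ss_abc, (a - 1) * df_bc, ss_bcsa, df_bcsa)
    return out


@dataclass(frozen=True)
class TTestResult:
    label: str
    t: float
    df: float
    p: float
    significant: bool
    alpha_corrected: float


def bonferroni_t(
    contrasts: list[tuple[str, np.ndarray, np.ndarray]],
    m: int | None = None,
    paired: bool = False,
    alpha: float = 0.05,
) -> list[TTestResult]:
    """Two-tailed t tests judged at the Bonferroni-corrected level alpha/m.

    ``contrasts`` is a list of (label, sample_a, sample_b); ``m`` defaults
    to the number of contrasts. Independent-samples tests assume equal
    variances (classic Student t), matching conventional reporting of
    t(n1+n2-2).
    """
    m = len(contrasts) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    thr = alpha / m
    results = []
    for label, a, b in contrasts:
        a, b = np.asarray(a, float), np.asarray(b, float)
        if paired:
            t, p = stats.ttest_rel(a, b)
            df = a.size - 1
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            df = a.size + b.size - 2
        results.append(
            TTestResult(label, float(t), float(df), float(p), bool(p < thr), thr)
        )
    return results


@dataclass(frozen=True)
class CouplingResult:
    """Across-unit regression of a beta coefficient on normalized firing."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    n: int


def pearson_coupling(x: np.ndarray, y: np.ndarray) -> CouplingResult:
    """Least-squares trendline and Pearson correlation of y on x."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in coupling inputs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    fit = stats.linregress(x, y)
    return CouplingResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue), n=int(x.size),
    )


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via the Fisher transformation.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed p
    from the standard normal.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n < 4:
            raise ValueError("need n >= 4 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
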