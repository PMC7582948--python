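"""Population statistics: chi-square, mixed ANOVA, coupling, Fisher r-to-z."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import threatcode as tc
from threatcode.popstats import bonferroni_t, mixed_anova, pearson_coupling


class TestChiSquare:
    def test_equal_proportions_give_zero(self):
        chi2, p = tc.chi_square_2x2(np.array([[50, 50], [50, 50]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        """Pearson statistic equals sum (O-E)^2/E computed by hand."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            table = rng.integers(5, 200, size=(2, 2))
            chi2, _ = tc.chi_square_2x2(table)
            n = table.sum()
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
            oracle = ((table - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(oracle, abs=1e-10)

    def test_equals_squared_two_proportion_z(self):
        """Algebraic identity: chi-square = z^2 of the two-proportion test."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            table = rng.integers(5, 200, size=(2, 2))
            chi2, _ = tc.chi_square_2x2(table)
            n1, n2 = table.sum(axis=1)
            p1, p2 = table[0, 0] / n1, table[1, 0] / n2
            pp = (table[0, 0] + table[1, 0]) / (n1 + n2)
            z = (p1 - p2) / math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
            assert chi2 == pytest.approx(z**2, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            tc.chi_square_2x2(np.array([[0, 0], [5, 5]]))
        with pytest.raises(ValueError):
            tc.chi_square_2x2(np.array([[5, 0], [5, 0]]))


def _toy_mixed_dataset():
    """Deterministic 2-group x 3x4 within dataset shared with the R oracle."""
    rng = np.random.default_rng(7)
    rows = []
    for g, gname in enumerate(("con", "eaa")):
        for s in range(4):
            subj = f"{gname}{s}"
            for b in range(3):
                for c in range(4):
                    val = (1.0 + 0.5 * g + 0.3 * b - 0.2 * c + 0.15 * g * b
                           + 0.1 * b * c + rng.normal(0, 1))
                    rows.append((subj, gname, f"b{b}", f"c{c}", val))
    return pd.DataFrame(rows, columns=["subject", "group", "cue", "bin", "y"])


class TestMixedAnova:
    # Frozen from an independent R oracle:
    # aov(y ~ group*cue*bin + Error(subject/(cue*bin))) on _toy_mixed_dataset()
    R_ORACLE = {
        "group": (25.37467, 1, 6, 0.0023631),
        "cue": (14.60092, 2, 12, 0.00061036),
        "group:cue": (2.19745, 2, 12, 0.15375740),
        "bin": (0.15149, 3, 18, 0.92737),
        "group:bin": (1.92226, 3, 18, 0.16217),
        "cue:bin": (2.99093, 6, 36, 0.017854),
        "group:cue:bin": (1.01185, 6, 36, 0.433064),
    }

    def test_matches_r_aov_multistratum_oracle(self):
        res = mixed_anova(_toy_mixed_dataset(), dv="y", between="group",
                          within=["cue", "bin"], subject="subject")
        for effect, (F, df1, df2, p) in self.R_ORACLE.items():
            r = res[effect]
            assert r.F == pytest.approx(F, abs=5e-5), effect
            assert (r.df_num, r.df_den) == (df1, df2), effect
            assert r.p == pytest.approx(p, rel=1e-3), effect
            assert 0.0 <= r.partial_eta_sq <= 1.0

    def test_partial_eta_squared_identity(self):
        res = mixed_anova(_toy_mixed_dataset(), dv="y", between="group",
                          within=["cue", "bin"], subject="subject")
        for name, r in res.items():
            if name == "subjects":
                continue
            err_ss = r.ss * (1 / r.partial_eta_sq - 1) if r.partial_eta_sq else np.inf
            # pes = ss/(ss+ss_err) implies F = (ss/df1)/(ss_err/df2)
            assert r.F == pytest.approx((r.ss / r.df_num) / (err_ss / r.df_den), rel=1e-6)

    def test_matches_pingouin_single_within(self):
        pg = pytest.importorskip("pingouin")
        df = _toy_mixed_dataset()
        df1 = df.groupby(["subject", "group", "cue"], as_index=False)["y"].mean()
        ours = mixed_anova(df1, dv="y", between="group", within="cue",
                           subject="subject")
        theirs = pg.mixed_anova(data=df1, dv="y", between="group", within="cue",
                                subject="subject").set_index("Source")
        assert ours["group"].F == pytest.approx(theirs.loc["group", "F"], rel=1e-8)
        assert ours["cue"].F == pytest.approx(theirs.loc["cue", "F"], rel=1e-8)
        assert ours["group:cue"].F == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-8
        )
        pcol = "p_unc" if "p_unc" in theirs.columns else "p-unc"
        assert ours["group"].p == pytest.approx(theirs.loc["group", pcol], rel=1e-8)
        assert ours["group"].partial_eta_sq == pytest.approx(
            theirs.loc["group", "np2"], rel=1e-8
        )

    def test_null_group_effect_p_uniform(self):
        """With both groups drawn from one distribution, the group p value
        is uniform over repeated simulated datasets."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            rows = []
            for gname in ("a", "b"):
                for s in range(8):
                    subj = f"{gname}{s}"
                    subj_off = rng.normal(0, 1)
                    for c in range(3):
                        rows.append((subj, gname, c, subj_off + rng.normal(0, 1)))
            df = pd.DataFrame(rows, columns=["subject", "group", "cue", "y"])
            res = mixed_anova(df, dv="y", between="group", within="cue",
                              subject="subject")
            pvals.append(res["group"].p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_injected_three_way_interaction_detected(self):
        """A sizeable group x cue x bin interaction is detected reliably."""
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            rows = []
            for g, gname in enumerate(("a", "b")):
                for s in range(10):
                    subj = f"{gname}{s}"
                    off = rng.normal(0, 1)
                    for b in range(3):
                        for c in range(4):
                            # interaction pattern only in group b
                            inter = 1.2 * g * ((b - 1) * (c - 1.5) / 2)
                            rows.append(
                                (subj, gname, b, c, off + inter + rng.normal(0, 1))
                            )
            df = pd.DataFrame(rows, columns=["subject", "group", "cue", "bin", "y"])
            res = mixed_anova(df, dv="y", between="group", within=["cue", "bin"],
                              subject="subject")
            hits += res["group:cue:bin"].p < 0.05
        assert hits / n_sim >= 0.9

    def test_missing_cells_rejected(self):
        df = _toy_mixed_dataset().iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(df, dv="y", between="group", within=["cue", "bin"],
                        subject="subject")


class TestBonferroniT:
    def test_threshold_rule(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(1.0, 1.0, 40)
        (res,) = bonferroni_t([("ab", a, b)], m=3)
        assert res.alpha_corrected == pytest.approx(0.05 / 3)
        assert res.significant == (res.p < 0.05 / 3)
        t_ref, p_ref = stats.ttest_ind(a, b)
        assert res.t == pytest.approx(t_ref) and res.p == pytest.approx(p_ref)

    def test_moderate_p_fails_correction_but_not_uncorrected(self):
        # p ~ 0.02 is significant alone (m=1) but not under m=3
        rng = np.random.default_rng(12)
        for _ in range(200):
            a = rng.normal(0.0, 1.0, 25)
            b = rng.normal(0.6, 1.0, 25)
            (r1,) = bonferroni_t([("x", a, b)], m=1)
            if 0.017 < r1.p < 0.05:
                (r3,) = bonferroni_t([("x", a, b)], m=3)
                assert r1.significant and not r3.significant
                return
        pytest.fail("no sample with p in (0.017, 0.05) found")

    def test_paired_variant_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 16)
        b = a + rng.normal(0.5, 0.5, 16)
        (res,) = bonferroni_t([("pair", a, b)], paired=True)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(t_ref) and res.df == 15


class TestPearsonCoupling:
    def test_exact_line(self):
        x = np.linspace(-1, 2, 20)
        res = pearson_coupling(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_r_squared_is_r_squared(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson_coupling(x, y)
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref) and res.p == pytest.approx(p_ref)

    def test_null_false_positive_rate_calibrated(self):
        """Independent normals: p < 0.05 occurs at the nominal rate."""
        rng = np.random.default_rng(5)
        fp = 0
        n_rep = 1000
        for _ in range(n_rep):
            x, y = rng.normal(size=50), rng.normal(size=50)
            fp += pearson_coupling(x, y).p < 0.05
        assert 0.03 <= fp / n_rep <= 0.07

    def test_coupled_population_recovered(self):
        """Firing and betas sharing a latent gain give a positive slope."""
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            gain = rng.gamma(2.0, 1.0, size=40)
            firing = gain + rng.normal(0, 0.5, 40)
            beta = 0.8 * gain + rng.normal(0, 0.5, 40)
            res = pearson_coupling(firing, beta)
            hits += (res.slope > 0) and (res.p < 0.05)
        assert hits >= 95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_coupling(np.ones(10), np.arange(10.0))


class TestFisherRToZ:
    def test_equal_correlations_give_zero(self):
        z, p = tc.fisher_r_to_z(0.37, 40, 0.37, 25)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = tc.fisher_r_to_z(0.6, 30, 0.1, 45)
        z2, p2 = tc.fisher_r_to_z(0.1, 45, 0.6, 30)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_formula_oracle(self):
        z, p = tc.fisher_r_to_z(0.5, 30, 0.0, 30)
        z_oracle = (math.atanh(0.5) - math.atanh(0.0)) / math.sqrt(1 / 27 + 1 / 27)
        assert z == pytest.approx(z_oracle, abs=1e-10)
        assert p == pytest.approx(2 * (1 - stats.norm.cdf(abs(z_oracle))), abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tc.fisher_r_to_z(1.0, 30, 0.0, 30)
        with pytest.raises(ValueError):
            tc.fisher_r_to_z(0.5, 3, 0.0, 30)
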