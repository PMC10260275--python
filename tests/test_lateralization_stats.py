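import math

import numpy as np
import pandas as pd
import pytest

from spindlelat.lateralization_stats import (MODEL1_CONTROLS, followup_regression,
                                             lateralization_index,
                                             preliminary_screens, rm_anova_d,
                                             rm_anova_posthoc, rm_ancova_d)


class TestLateralizationIndex:
    def test_symmetric_is_zero(self):
        assert lateralization_index(3.0, 3.0) == 0.0

    def test_arithmetic(self):
        assert lateralization_index(3.0, 2.0) == pytest.approx(0.4)

    def test_antisymmetry(self, rng):
        for _ in range(20):
            r, l = rng.uniform(0.5, 5.0, size=2)
            assert lateralization_index(r, l) == pytest.approx(
                -lateralization_index(l, r))

    def test_scale_invariance(self, rng):
        for _ in range(20):
            r, l = rng.uniform(0.5, 5.0, size=2)
            k = rng.uniform(0.1, 10.0)
            assert lateralization_index(k * r, k * l) == pytest.approx(
                lateralization_index(r, l))

    def test_guard_returns_missing_not_inf(self):
        out = lateralization_index(1e-9, -1e-9, guard_eps=1e-6)
        assert math.isnan(out)


def brute_force_rm_anova(Y):
    """Independent oracle: explicit-loop sums-of-squares decomposition."""
    n, a, b = Y.shape
    grand = Y.sum() / (n * a * b)
    sub = [Y[i].sum() / (a * b) for i in range(n)]
    A = [Y[:, j, :].sum() / (n * b) for j in range(a)]
    B = [Y[:, :, k].sum() / (n * a) for k in range(b)]
    ss_a = ss_b = ss_ab = ss_as = ss_bs = ss_abs = 0.0
    for j in range(a):
        ss_a += n * b * (A[j] - grand) ** 2
    for k in range(b):
        ss_b += n * a * (B[k] - grand) ** 2
    for j in range(a):
        for k in range(b):
            ab = Y[:, j, k].sum() / n
            ss_ab += n * (ab - A[j] - B[k] + grand) ** 2
    for i in range(n):
        for j in range(a):
            cell = Y[i, j, :].sum() / b
            ss_as += b * (cell - A[j] - sub[i] + grand) ** 2
        for k in range(b):
            cell = Y[i, :, k].sum() / a
            ss_bs += a * (cell - B[k] - sub[i] + grand) ** 2
        for j in range(a):
            for k in range(b):
                fit = (sub[i] + A[j] + B[k] - 2 * grand
                       + (Y[:, j, k].sum() / n - A[j] - B[k] + grand)
                       + (Y[i, j, :].sum() / b - A[j] - sub[i] + grand)
                       + (Y[i, :, k].sum() / a - B[k] - sub[i] + grand))
                ss_abs += (Y[i, j, k] - fit) ** 2
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab


class TestRmAnova:
    def test_constant_data_gives_zero_f(self):
        Y = np.full((6, 3, 2), 2.0)
        res = rm_anova_d(Y)
        assert all(e.F == 0.0 for e in res)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            Y = rng.normal(2.0, 0.6, size=(4, 3, 2))
            res = {e.effect: e.F for e in rm_anova_d(Y)}
            f_a, f_b, f_ab = brute_force_rm_anova(Y)
            assert res["time"] == pytest.approx(f_a, abs=1e-8)
            assert res["emotion"] == pytest.approx(f_b, abs=1e-8)
            assert res["time x emotion"] == pytest.approx(f_ab, abs=1e-8)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        Y = rng.normal(2.0, 0.5, size=(10, 3, 2))
        rows = [{"s": i, "time": j, "emo": k, "y": Y[i, j, k]}
                for i in range(10) for j in range(3) for k in range(2)]
        aov = pg.rm_anova(dv="y", within=["time", "emo"], subject="s",
                          data=pd.DataFrame(rows), detailed=True)
        res = {e.effect: e for e in rm_anova_d(Y)}
        assert res["time"].F == pytest.approx(aov.loc[0, "F"], rel=1e-9)
        assert res["emotion"].F == pytest.approx(aov.loc[1, "F"], rel=1e-9)
        assert res["time x emotion"].F == pytest.approx(aov.loc[2, "F"], rel=1e-9)
        assert res["time"].p == pytest.approx(aov.loc[0, "p_unc"], rel=1e-9)

    def test_greenhouse_geisser_matches_pingouin(self, rng):
        import pingouin as pg

        Y = rng.normal(2.0, 0.5, size=(12, 3, 2))
        rows = [{"s": i, "time": j, "emo": k, "y": Y[i, j, k]}
                for i in range(12) for j in range(3) for k in range(2)]
        aov = pg.rm_anova(dv="y", within=["time", "emo"], subject="s",
                          data=pd.DataFrame(rows), detailed=True)
        res = {e.effect: e for e in rm_anova_d(Y, sphericity="gg")}
        assert res["time"].p == pytest.approx(aov.loc[0, "p_GG_corr"], rel=1e-6)

    def test_declining_pattern_detected(self, rng):
        # population pattern: d' declines over retrievals, neutral benefit at 24h
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            base = np.array([[2.6, 2.55], [2.1, 2.0], [2.05, 1.55]])
            Y = base[None] + r.normal(0, 0.4, (32, 1, 1)) + r.normal(0, 0.3, (32, 3, 2))
            res = {e.effect: e for e in rm_anova_d(Y)}
            hits += (res["time"].p < 0.05)
        assert hits >= 18  # ≥ 90% of seeds

    def test_insufficient_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_d(np.zeros((2, 3, 2)))

    def test_posthoc_bonferroni_bounds(self, rng):
        Y = rng.normal(2.0, 0.5, size=(12, 3, 2))
        ph = rm_anova_posthoc(Y)
        assert len(ph) == 6
        assert np.all(ph["p_bonferroni"] <= 1.0)
        assert np.all(ph["p_bonferroni"] >= ph["p_uncorrected"] - 1e-12)


def controls_frame(rng, n):
    return pd.DataFrame({
        "sex": rng.choice(["F", "M"], size=n),
        "location": rng.choice(["home", "lab"], size=n),
        "sleep_duration": rng.normal(6.7, 0.7, size=n),
    })


class TestRmAncova:
    def test_t_squared_equals_f_for_single_df(self, rng):
        import statsmodels.api as sm

        n = 16
        Y = rng.normal(2.0, 0.5, size=(n, 3, 2))
        cov = rng.normal(size=n)
        controls = controls_frame(rng, n)
        res = {e.effect: e for e in rm_ancova_d(Y, cov, controls)}
        # manual regression of the emotion contrast on the same design
        c = (Y[:, :, 0] - Y[:, :, 1]).mean(axis=1) / np.sqrt(2)
        X = pd.get_dummies(controls, drop_first=True, dtype=float)
        X.insert(0, "cov", cov - cov.mean())
        for col in X.columns[1:]:
            X[col] -= X[col].mean()
        fit = sm.OLS(c, sm.add_constant(X)).fit()
        assert fit.tvalues["cov"] ** 2 == pytest.approx(res["x emotion"].F, rel=1e-9)
        assert res["x emotion"].df1 == 1

    def test_dfs_match_design(self, rng):
        n = 32
        Y = rng.normal(2.0, 0.5, size=(n, 3, 2))
        res = {e.effect: e for e in rm_ancova_d(Y, rng.normal(size=n),
                                                controls_frame(rng, n))}
        # p = intercept + covariate + 3 controls = 5 -> error df n − 5 = 27
        assert (res["main"].df1, res["main"].df2) == (1, 27)
        assert (res["x time"].df1, res["x time"].df2) == (2, 54)
        assert (res["x emotion"].df1, res["x emotion"].df2) == (1, 27)
        assert (res["x time x emotion"].df1, res["x time x emotion"].df2) == (2, 54)

    def test_null_covariate_type_one_error(self):
        # independent covariate: p-values uniform, so ~5% below 0.05
        from spindlelat.synthetic_data import SimulationSpec, simulate_cohort_scores

        spec = SimulationSpec(wiring_coupling_emotion=0.0)
        hits = 0
        n_seeds = 300
        for s in range(n_seeds):
            scores, covs, truth = simulate_cohort_scores(spec, seed=s)
            res = rm_ancova_d(scores, truth["coupling_lat"].to_numpy(),
                              covs[list(MODEL1_CONTROLS)])
            hits += [e.p for e in res if e.effect == "x emotion"][0] < 0.05
        assert 0.02 <= hits / n_seeds <= 0.08

    def test_missing_bdi_mean_imputed(self, rng):
        n = 16
        Y = rng.normal(2.0, 0.5, size=(n, 3, 2))
        controls = controls_frame(rng, n)
        controls["bdi_ln"] = rng.normal(2.0, 0.8, size=n)
        controls.loc[0, "bdi_ln"] = np.nan
        res = rm_ancova_d(Y, rng.normal(size=n), controls)
        # all subjects retained (mean imputation), so df2 = n − 6 = 10
        assert res[0].df2 == 10


class TestFollowupRegression:
    def test_perfect_linear_relation(self, rng):
        x = rng.normal(size=30)
        t, p, coef = followup_regression(2.0 * x, x)
        assert coef == pytest.approx(2.0)
        assert p < 1e-12

    def test_null_predictor_mostly_nonsignificant(self):
        # P(|t| < 2) ≈ 0.945 at df = 30 under the null
        n_seeds = 500
        hits = 0
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            y = r.normal(size=32)
            x = r.normal(size=32)
            t, p, _ = followup_regression(y, x)
            hits += abs(t) < 2
        assert hits / n_seeds >= 0.93

    def test_prior_delta_absorbs_confound(self, rng):
        # delta fully explained by prior delta; predictor correlated with
        # prior delta only -> its t collapses once prior delta is controlled
        prior = rng.normal(size=200)
        delta = 1.5 * prior + 0.1 * rng.normal(size=200)
        predictor = prior + 0.1 * rng.normal(size=200)
        t_without, _, _ = followup_regression(delta, predictor)
        t_with, _, _ = followup_regression(delta, predictor, prior_delta=prior)
        assert abs(t_without) > 10
        assert abs(t_with) < 2.5

    def test_rank_deficiency_detected(self, rng):
        x = rng.normal(size=20)
        controls = pd.DataFrame({"dup": x})
        with pytest.raises(ValueError, match="rank"):
            followup_regression(rng.normal(size=20), x, controls)


class TestPreliminaryScreens:
    def test_equal_groups_large_p(self, rng):
        n = 200
        df = pd.DataFrame({
            "grp": ["a"] * (n // 2) + ["b"] * (n // 2),
            "v": np.concatenate([rng.normal(0, 1, n // 2),
                                 rng.normal(0, 1, n // 2)]),
        })
        rep = preliminary_screens(df, group="grp")
        assert rep["anova"]["v"]["p"] > 0.05

    def test_perfect_correlation(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"grp": ["a"] * 30, "x": x, "y": x})
        rep = preliminary_screens(df, group="grp", correlate_pairs=[("x", "y")])
        assert rep["pearson"][("x", "y")]["r"] == pytest.approx(1.0)

    def test_outlier_threshold(self):
        # one extreme value lands beyond 3 SD of the full sample -> flagged
        v = np.append(np.linspace(-1.2, 1.2, 30), 10.0)
        df = pd.DataFrame({"grp": ["a"] * 31, "v": v})
        z_extreme = (10.0 - v.mean()) / v.std(ddof=1)
        assert z_extreme > 3
        rep = preliminary_screens(df, group="grp")
        assert rep["outliers"]["v"] == [30]
        # a tight sample has no |z| > 3 -> nothing flagged
        df2 = pd.DataFrame({"grp": ["a"] * 31,
                            "v": np.append(np.linspace(-1.2, 1.2, 30), 2.0)})
        rep2 = preliminary_screens(df2, group="grp")
        assert "v" not in rep2["outliers"]

    def test_constant_variable_correlation_missing(self):
        df = pd.DataFrame({"grp": ["a"] * 10, "x": np.ones(10),
                           "y": np.arange(10.0)})
        rep = preliminary_screens(df, group="grp", correlate_pairs=[("x", "y")])
        assert math.isnan(rep["pearson"][("x", "y")]["r"])
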