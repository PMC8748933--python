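"""Screening, stepwise selection, overdispersion, effect sizes, dominance,
diagnostics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

from antiherbiome import assoc_models as am


def correlated_pair(n, r, rng):
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r**2) * rng.standard_normal(n)
    return x, y


class TestCorrelationScreen:
    def test_mar_ph_branching(self):
        rng = np.random.default_rng(0)
        mar, ph = correlated_pair(400, -0.78, rng)
        X = pd.DataFrame({"MAR": mar, "pH": ph, "MAT": rng.standard_normal(400)})
        res = am.correlation_screen(X)
        assert len(res.branches) == 2
        assert any("MAR" in b and "pH" not in b for b in res.branches)
        assert any("pH" in b and "MAR" not in b for b in res.branches)

    def test_uncorrelated_single_branch(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((300, 4)), columns=["MAR", "pH", "a", "b"])
        res = am.correlation_screen(X)
        assert len(res.branches) == 1

    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)})
        res = am.correlation_screen(X, branch_pair=None)
        assert any({p, q} == {"a", "b"} for p, q, _ in res.flagged)

    def test_constant_dropped(self, caplog):
        import logging

        X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with caplog.at_level(logging.WARNING):
            res = am.correlation_screen(X, branch_pair=None)
        assert res.dropped_constant == ["a"]


class TestStepwise:
    def make_data(self, seed=0, n=150, beta=(0.8, 0.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        y = X.to_numpy() @ np.array(beta) + rng.standard_normal(n)
        return pd.Series(y, index=X.index), X

    def test_single_planted_predictor_selected(self):
        y, X = self.make_data()
        fit = am.stepwise_select(y, X, branch_pair=None)
        assert fit.predictors == ["a"]
        assert (fit.pvalues.drop("const") <= 0.05).all()

    def test_quadratic_kept_only_with_linear(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=["a", "b"])
        z = (X["a"] - X["a"].mean()) / X["a"].std(ddof=0)
        y = 1.5 * z**2 + 0.05 * X["a"] + rng.standard_normal(200)
        fit = am.stepwise_select(y, X, forced_quadratics=("a",), branch_pair=None)
        if "a^2" in fit.predictors:
            assert "a" in fit.predictors  # hierarchy rule

    def test_unknown_quadratic_base_rejected(self):
        y, X = self.make_data()
        with pytest.raises(ValueError, match="unknown predictor"):
            am.stepwise_select(y, X, forced_quadratics=("zz",), branch_pair=None)

    def test_empty_model_flagged(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        y = pd.Series(rng.standard_normal(100))
        fit = am.stepwise_select(y, X, branch_pair=None)
        if fit.empty:
            assert "no_significant_predictors" in fit.flags

    def test_branch_winner_and_delta_aic(self):
        rng = np.random.default_rng(5)
        mar, ph = correlated_pair(300, -0.78, rng)
        X = pd.DataFrame({"MAR": mar, "pH": ph, "a": rng.standard_normal(300)})
        y = pd.Series(1.0 * ph + rng.standard_normal(300) * 0.5)
        fit = am.stepwise_select(y, X)
        assert fit.branch == "pH"
        assert fit.delta_aic is not None and fit.delta_aic > 2

    def test_sign_discard_rule(self):
        # a "herbivory" predictor whose significant sign contradicts a
        # defence response is dropped and selection re-run
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=["H_rich", "a"])
        y = pd.Series(-0.8 * X["H_rich"] + 0.5 * X["a"] + rng.standard_normal(200) * 0.5)
        fit = am.stepwise_select(y, X, branch_pair=None, expected_signs={"H_rich": 1})
        assert "H_rich" not in fit.predictors
        assert "a" in fit.predictors


class TestOverdispersedBinomial:
    def simulate(self, rho, seed=0, n_obs=80, n_tr=40):
        rng = np.random.default_rng(seed)
        M = np.column_stack([np.ones(n_obs), rng.standard_normal(n_obs)])
        mu = 1 / (1 + np.exp(-(M @ np.array([-0.2, 0.7]))))
        if rho > 0:
            p = rng.beta(mu * (1 - rho) / rho, (1 - mu) * (1 - rho) / rho)
        else:
            p = mu
        y = rng.binomial(n_tr, p)
        return y, n_tr - y, M

    def test_reduction_to_plain_logit(self):
        y, f, M = self.simulate(0.0)
        od = am.overdispersed_binomial_fit(y, f, M)
        plain = am._binomial_glm(y.astype(float), f.astype(float), M)
        assert np.abs(np.asarray(od.result.params) - np.asarray(plain.params)).max() < 1e-6

    @pytest.mark.parametrize("rho", [0.05, 0.1, 0.2])
    def test_deviance_below_df(self, rho):
        y, f, M = self.simulate(rho, seed=1)
        od = am.overdispersed_binomial_fit(y, f, M)
        assert od.converged
        assert od.deviance < od.df_resid
        assert od.phi > 0
        assert np.all(od.weights <= 1.0)

    def test_degenerate_single_observation(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            am.overdispersed_binomial_fit([3], [2], np.ones((1, 1)))


class TestEffectSizes:
    def fit(self, y, X, terms):
        return am.fit_model(pd.Series(y), X, terms)

    def test_zero_t_gives_zero_r(self):
        n = 64
        x = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        y = np.tile([1.0, -1.0], n // 2)  # exactly orthogonal to x
        X = pd.DataFrame({"x": x})
        eff = am.effect_sizes(self.fit(y, X, ["x"]))
        assert eff.loc["x", "r"] == pytest.approx(0.0, abs=1e-12)

    def test_simple_regression_equals_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        y = 0.6 * x + rng.standard_normal(60)
        eff = am.effect_sizes(self.fit(y, pd.DataFrame({"x": x}), ["x"]))
        assert eff.loc["x", "r"] == pytest.approx(st.pearsonr(x, y)[0], abs=1e-10)

    def test_multipredictor_equals_partial_correlation(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((120, 3)), columns=list("abc"))
        y = X @ np.array([0.5, -0.3, 0.0]) + rng.standard_normal(120)
        eff = am.effect_sizes(self.fit(y, X, list("abc")))
        # oracle: partial correlation via double residualization
        for t in "abc":
            others = [u for u in "abc" if u != t]
            Mo = np.column_stack([np.ones(120)] + [X[u] for u in others])
            ry = y - Mo @ np.linalg.lstsq(Mo, y, rcond=None)[0]
            rx = X[t] - Mo @ np.linalg.lstsq(Mo, X[t], rcond=None)[0]
            assert eff.loc[t, "r"] == pytest.approx(st.pearsonr(rx, ry)[0], abs=1e-8)

    def test_ci_sign_and_ordering(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(80)
        y = x + 0.3 * rng.standard_normal(80)
        eff = am.effect_sizes(self.fit(y, pd.DataFrame({"x": x}), ["x"]))
        assert eff.loc["x", "ci_low"] < eff.loc["x", "r"] < eff.loc["x", "ci_high"]
        assert eff.loc["x", "ci_low"] > 0  # strong positive effect


class TestDominance:
    def test_two_predictor_hand_enumeration(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        X["b"] += 0.5 * X["a"]  # correlated on purpose
        y = X["a"] + 0.5 * X["b"] + rng.standard_normal(100)

        def r2(cols):
            if not cols:
                return 0.0
            M = np.column_stack([np.ones(100)] + [X[c] for c in cols])
            res = sm.OLS(y, M).fit()
            return res.rsquared

        want_a = 0.5 * (r2(["a"]) - r2([])) + 0.5 * (r2(["a", "b"]) - r2(["b"]))
        want_b = 0.5 * (r2(["b"]) - r2([])) + 0.5 * (r2(["a", "b"]) - r2(["a"]))
        got = am.dominance_contributions(y, X, ["a", "b"])
        assert got["a"] == pytest.approx(want_a, abs=1e-12)
        assert got["b"] == pytest.approx(want_b, abs=1e-12)

    def test_orthonormal_contributions_sum_to_r2(self):
        rng = np.random.default_rng(1)
        M = np.linalg.qr(rng.standard_normal((90, 3)))[0]  # orthonormal columns
        X = pd.DataFrame(M, columns=list("abc"))
        y = M @ np.array([1.0, 0.5, -0.7]) + rng.standard_normal(90)
        got = am.dominance_contributions(y, X, list("abc"))
        full = sm.OLS(y, np.column_stack([np.ones(90), M])).fit().rsquared
        assert got.sum() == pytest.approx(full, abs=1e-10)

    def test_single_predictor_is_model_r2(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.standard_normal(50)})
        y = X["a"] + rng.standard_normal(50)
        got = am.dominance_contributions(y, X, ["a"])
        assert got["a"] == pytest.approx(
            sm.OLS(y, sm.add_constant(X)).fit().rsquared, abs=1e-12
        )

    def test_too_many_predictors_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((40, 13)),
                         columns=[f"p{i}" for i in range(13)])
        with pytest.raises(ValueError, match="capped at 12"):
            am.dominance_contributions(X.iloc[:, 0], X, list(X.columns))

    def test_mcfadden_for_binomial(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.standard_normal(80)})
        p = 1 / (1 + np.exp(-1.2 * X["a"]))
        y = rng.binomial(30, p)
        resp = (pd.Series(y, index=X.index), pd.Series(30 - y, index=X.index))
        got = am.dominance_contributions(resp, X, ["a"], family="binomial_counts")
        assert 0 < got["a"] < 1


class TestDiagnostics:
    def lattice_adjacency(self, n):
        return {i: {j for j in (i - 1, i + 1) if 0 <= j < n} for i in range(n)}

    def test_hc_refit_on_heteroscedastic_data(self):
        rng = np.random.default_rng(0)
        n = 200
        X = pd.DataFrame({"x": rng.uniform(1, 5, n)})
        y = pd.Series(X["x"] + rng.standard_normal(n) * X["x"] ** 1.5 * 0.5)
        fit = am.fit_model(y, X, ["x"])
        fit2, rec = am.diagnostics(fit, X, y, adjacency=self.lattice_adjacency(n),
                                   index=pd.RangeIndex(n))
        assert rec.bp_p <= 0.05
        assert rec.hc_used
        assert fit2.cov_type == "HC3"

    def test_clean_data_reports_pvalues(self):
        rng = np.random.default_rng(1)
        n = 150
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = pd.Series(X["x"] + rng.standard_normal(n))
        fit = am.fit_model(y, X, ["x"])
        _, rec = am.diagnostics(fit, X, y, adjacency=self.lattice_adjacency(n),
                                index=pd.RangeIndex(n))
        assert 0 <= rec.ks_p <= 1 and 0 <= rec.bp_p <= 1 and 0 <= rec.moran_p <= 1
        assert rec.max_vif == pytest.approx(1.0)

    def test_duplicated_predictor_raises_collinearity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": x})
        y = pd.Series(x + rng.standard_normal(50))
        fit = am.fit_model(y, X, ["a", "b"])
        with pytest.raises(am.CollinearityError):
            am.diagnostics(fit, X, y)


class TestMoransI:
    def brute(self, values, adjacency):
        ids = list(values.index)
        e = values.to_numpy() - values.mean()
        pos = {u: i for i, u in enumerate(ids)}
        num = s0 = 0.0
        for u in ids:
            for v in adjacency[u]:
                num += e[pos[u]] * e[pos[v]]
                s0 += 1
        return (len(ids) / s0) * num / (e**2).sum()

    def test_value_matches_brute_force(self):
        rng = np.random.default_rng(0)
        n = 30
        adjacency = {i: {j for j in (i - 1, i + 1) if 0 <= j < n} for i in range(n)}
        vals = pd.Series(rng.standard_normal(n))
        got, p, flagged = am.morans_i(vals, adjacency)
        assert got == pytest.approx(self.brute(vals, adjacency), abs=1e-12)
        assert not flagged

    def test_autocorrelated_field_detected(self):
        n = 60
        adjacency = {i: {j for j in (i - 1, i + 1) if 0 <= j < n} for i in range(n)}
        vals = pd.Series(np.sin(np.arange(n) / 4.0))  # smooth spatial signal
        got, p, _ = am.morans_i(vals, adjacency)
        assert got > 0.5 and p < 1e-6

    def test_disconnected_graph_flagged(self):
        adjacency = {0: {1}, 1: {0}, 2: {3}, 3: {2}, 4: set()}
        vals = pd.Series(np.random.default_rng(1).standard_normal(5))
        _, _, flagged = am.morans_i(vals, adjacency)
        assert flagged
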