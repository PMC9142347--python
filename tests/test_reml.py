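"""REML engine: closed forms, GLS oracle, invariances, boundary handling."""

import numpy as np
import pandas as pd
import pytest

import metstab as ms
from metstab.reml import ModelSpec, RemlError, reml_fit


def one_way(g, r, sd_group, sd_e, seed):
    rng = np.random.default_rng(seed)
    eff = rng.normal(0, sd_group, g)
    y = np.repeat(eff, r) + rng.normal(0, sd_e, g * r)
    return pd.DataFrame({"group": np.repeat([f"t{i:02d}" for i in range(g)], r), "y": y})


def anova_one_way(df, g, r):
    ym = df.groupby("group")["y"].mean()
    grand = df["y"].mean()
    msb = r * float(((ym - grand) ** 2).sum()) / (g - 1)
    mse = float(((df["y"] - df["group"].map(ym)) ** 2).sum()) / (g * (r - 1))
    return msb, mse


class TestClosedForms:
    def test_fixed_only_model_matches_ols(self):
        df = one_way(6, 4, 1.0, 1.0, seed=0)
        fit = reml_fit(df, ModelSpec("y", ("group",), ()))
        resid = df["y"] - df["group"].map(df.groupby("group")["y"].mean())
        assert fit.sigma2_e == pytest.approx(float(resid @ resid) / (24 - 6), rel=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_balanced_one_way_equals_anova(self, seed):
        g, r = 10, 5
        df = one_way(g, r, 2.0, 1.0, seed)
        msb, mse = anova_one_way(df, g, r)
        assert msb > mse
        fit = reml_fit(df, ModelSpec("y", (), ("group",)))
        assert fit.variances["group"] == pytest.approx((msb - mse) / r, rel=1e-6)
        assert fit.sigma2_e == pytest.approx(mse, rel=1e-6)

    def test_group_variance_clamped_at_zero(self):
        # draw with between MS well below within MS: boundary estimate
        df = one_way(6, 8, 0.0, 1.0, seed=2)
        msb, mse = anova_one_way(df, 6, 8)
        assert msb < mse
        fit = reml_fit(df, ModelSpec("y", (), ("group",)))
        assert fit.variances["group"] == 0.0
        assert "group" in fit.clamped


class TestGlsOracle:
    def _dense_oracle(self, df, spec, fit):
        """Explicit dense GLS at the fitted variances."""
        y = df[spec.response].to_numpy(float)
        n = len(df)
        X_cols = [np.ones(n)]
        levels = sorted(df[spec.fixed_terms[0]].unique())
        for lev in levels[1:]:
            X_cols.append((df[spec.fixed_terms[0]] == lev).to_numpy(float))
        X = np.column_stack(X_cols)
        V = fit.sigma2_e * np.eye(n)
        for term in spec.random_terms:
            Z = pd.get_dummies(df[term]).to_numpy(float)
            V += fit.variances[term] * Z @ Z.T
        Vi = np.linalg.inv(V)
        cov = np.linalg.inv(X.T @ Vi @ X)
        return cov @ X.T @ Vi @ y

    def test_fixed_effects_equal_dense_gls(self, rcbd_env):
        df = rcbd_env.df
        spec = ModelSpec("value", ("genotype",), ("block",))
        fit = reml_fit(df, spec)
        beta_oracle = self._dense_oracle(df, spec, fit)
        assert np.allclose(fit.beta.to_numpy(), beta_oracle, rtol=1e-8, atol=1e-8)


class TestInvariances:
    def test_row_order_permutation(self, rcbd_env):
        df = rcbd_env.df
        spec = ModelSpec("value", ("genotype",), ("block",))
        fit1 = reml_fit(df, spec)
        fit2 = reml_fit(df.sample(frac=1.0, random_state=4), spec)
        # float summation order perturbs the optimum by ~sqrt(eps): 1e-5 rel
        assert np.allclose(fit1.beta, fit2.beta, rtol=1e-7, atol=1e-7)
        assert fit1.variances["block"] == pytest.approx(fit2.variances["block"], rel=1e-5)

    def test_response_shift_moves_blues_not_variances(self, rcbd_env):
        df = rcbd_env.df
        spec = ModelSpec("value", ("genotype",), ("block",))
        fit1 = reml_fit(df, spec)
        df2 = df.assign(value=df["value"] + 17.5)
        fit2 = reml_fit(df2, spec)
        em1, em2 = fit1.emmeans("genotype"), fit2.emmeans("genotype")
        assert np.allclose(em2["estimate"] - em1["estimate"], 17.5, atol=1e-8)
        assert fit1.sigma2_e == pytest.approx(fit2.sigma2_e, rel=1e-8)
        assert fit1.variances["block"] == pytest.approx(fit2.variances["block"], rel=1e-7, abs=1e-10)

    def test_restricted_loglik_nondecreasing_along_trace(self, small_met):
        _, plots, _ = small_met
        df = plots.df.copy()
        df["env_block"] = df["location"] + df["year"].astype(str) + df["block"]
        fit = reml_fit(df, ModelSpec(
            "value", (), ("genotype", "env_block", "genotype:location")))
        tr = np.array(fit.trace)
        if len(tr) > 1:  # -2 loglik must not increase across accepted iterates
            assert (np.diff(tr) <= 1e-6).all()


class TestErrors:
    def test_overlapping_fixed_and_random_rejected(self):
        with pytest.raises(RemlError):
            ModelSpec("y", ("a",), ("a",))

    def test_aliased_fixed_design_named(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "a": ["u", "u", "v", "v"],
                           "b": ["p", "p", "q", "q"]})  # b aliases a
        with pytest.raises(RemlError, match="aliased"):
            reml_fit(df, ModelSpec("y", ("a", "b"), ()))

    def test_missing_response_column(self):
        with pytest.raises(RemlError):
            reml_fit(pd.DataFrame({"y": [1.0]}), ModelSpec("z", (), ()))

    def test_constant_response_warns(self):
        df = pd.DataFrame({"y": np.ones(8), "g": list("aabbccdd")})
        with pytest.warns(UserWarning, match="degenerate"):
            reml_fit(df, ModelSpec("y", (), ("g",)))


class TestCrossedModelAgainstLme4:
    """Frozen reference fit from R lme4 (same data regenerated by seed).

    The dataset is a balanced 6 x 2 x 3 x 2 MET (seed 20250924); the lme4
    REML estimates and restricted log-likelihood below were computed
    independently and frozen.
    """

    LME4 = {
        "genotype": 1.9635744381, "location": 0.1159280303, "year": 1.5154268400,
        "location:year": 0.0, "env_block": 1.5644384654,
        "genotype:location": 1.0733139380, "genotype:year": 1.1323975289,
        "genotype:location:year": 0.1786378728, "residual": 3.2495406699,
    }
    LOGLIK = -168.069667889

    @staticmethod
    @pytest.fixture(scope="class")
    def fixture_plots():
        cfg = ms.SimulationConfig(
            n_genotypes=6, n_locations=2, n_years=3, n_replicates=2,
            mu=50.0, sigma2_g=4, sigma2_l=2, sigma2_a=3, sigma2_la=2,
            sigma2_block=1, sigma2_gl=1, sigma2_ga=1.5, sigma2_gla=2,
            sigma2_e=3, seed=20250924)
        plots, _ = ms.simulate_met(cfg)
        return plots

    @pytest.mark.parametrize("fast", [True, False])
    def test_variances_and_loglik_match(self, fixture_plots, fast):
        vc = ms.estimate_variance_components(
            fixture_plots, "yield_kg_ha", use_fast_path=fast)
        got = {
            "genotype": vc.sigma2_g, "location": vc.sigma2_l, "year": vc.sigma2_a,
            "location:year": vc.sigma2_la, "env_block": vc.sigma2_block,
            "genotype:location": vc.sigma2_gl, "genotype:year": vc.sigma2_ga,
            "genotype:location:year": vc.sigma2_gla, "residual": vc.sigma2_e,
        }
        for term, ref in self.LME4.items():
            assert got[term] == pytest.approx(ref, abs=2e-4), term
        assert vc.loglik == pytest.approx(self.LOGLIK, abs=1e-4)

    def test_fast_and_general_paths_agree(self, fixture_plots):
        vc_f = ms.estimate_variance_components(fixture_plots, "yield_kg_ha")
        vc_g = ms.estimate_variance_components(fixture_plots, "yield_kg_ha",
                                               use_fast_path=False)
        assert vc_f.method == "strata" and vc_g.method == "general"
        for a, b in zip(vc_f.as_dict().values(), vc_g.as_dict().values()):
            assert a == pytest.approx(b, abs=2e-4)
        assert vc_f.loglik == pytest.approx(vc_g.loglik, abs=1e-5)
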