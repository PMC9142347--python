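"""BLUEs, spatial-term selection, variance components and score models."""

import numpy as np
import pandas as pd
import pytest

import metstab as ms
from metstab.mixed_models import select_spatial_terms
from metstab.reml import RemlError


class TestEstimateBlues:
    def test_balanced_rcbd_blues_are_genotype_means(self, rcbd_env):
        env = rcbd_env.environments[0]
        res = ms.estimate_blues(rcbd_env, "yield_kg_ha", env, spatial="none")
        means = rcbd_env.df.groupby("genotype")["value"].mean()
        got = res.table.set_index("genotype")["blue"]
        assert np.allclose(got, means.loc[got.index], atol=1e-10)

    def test_single_plot_per_genotype_blue_is_observation(self):
        cfg = ms.SimulationConfig(n_genotypes=6, n_locations=1, n_years=1,
                                  n_replicates=1, mu=10, sigma2_g=4,
                                  sigma2_l=0, sigma2_a=0, sigma2_la=0,
                                  sigma2_block=0, sigma2_gl=0, sigma2_ga=0,
                                  sigma2_gla=0, sigma2_e=1, seed=2)
        plots, _ = ms.simulate_met(cfg)
        res = ms.estimate_blues(plots, "yield_kg_ha", plots.environments[0])
        obs = plots.df.set_index("genotype")["value"]
        got = res.table.set_index("genotype")["blue"]
        assert np.allclose(got, obs.loc[got.index], atol=1e-10)

    def test_absent_genotype_excluded_and_listed(self, rcbd_env):
        df = rcbd_env.df[rcbd_env.df["genotype"] != "g003"]
        plots = ms.PlotTable(pd.concat([
            df, rcbd_env.df.head(0)]))  # keep schema
        # g003 known to the full genotype list via a second (empty-valued) env
        extra = rcbd_env.df.head(1).copy()
        extra["genotype"] = "g003"
        extra["location"] = "elsewhere"
        extra["row"] = 99
        plots = ms.PlotTable(pd.concat([df, extra], ignore_index=True))
        env = rcbd_env.environments[0]
        res = ms.estimate_blues(plots, "yield_kg_ha", env, spatial="none")
        assert "g003" not in set(res.table["genotype"])
        assert res.excluded == ["g003"]

    def test_augmented_entries_adjusted_by_block_effect(self):
        # 12-plot augmented toy: 2 replicated checks + 8 unreplicated entries,
        # pure additive block effect, tiny noise
        rng = np.random.default_rng(3)
        geno_eff = {"chkA": 0.0, "chkB": 2.0, **{f"e{i}": float(i) for i in range(8)}}
        rows = []
        block_eff = {"b1": 0.0, "b2": 5.0}
        layout = {"b1": ["chkA", "chkB", "e0", "e1", "e2", "e3"],
                  "b2": ["chkA", "chkB", "e4", "e5", "e6", "e7"]}
        r = 1
        for b, members in layout.items():
            for c, g in enumerate(members):
                rows.append(dict(genotype=g, location="X", year=2020, block=b,
                                 row=r, column=c + 1, trait="yield_kg_ha",
                                 value=10 + geno_eff[g] + block_eff[b]
                                 + rng.normal(0, 1e-4)))
            r += 1
        plots = ms.PlotTable(pd.DataFrame(rows))
        res = ms.estimate_blues(plots, "yield_kg_ha", ms.EnvironmentKey("X", 2020),
                                spatial="none")
        fit = res.fit
        # dense GLS oracle at the fitted variances
        df = plots.df
        X = np.column_stack([np.ones(12)] + [
            (df["genotype"] == g).to_numpy(float)
            for g in sorted(geno_eff)[1:]])
        Z = pd.get_dummies(df["block"]).to_numpy(float)
        V = fit.sigma2_e * np.eye(12) + fit.variances["block"] * Z @ Z.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["value"].to_numpy())
        assert np.allclose(fit.beta.to_numpy(), beta, rtol=1e-7, atol=1e-7)
        # unreplicated entry BLUE = raw value minus its block's estimated effect
        resid = df["value"].to_numpy() - X @ beta
        blup = fit.variances["block"] * Z.T @ Vi @ resid
        blues = res.table.set_index("genotype")["blue"]
        for i, rec in df.iterrows():
            if rec["genotype"].startswith("e"):
                b_idx = 0 if rec["block"] == "b1" else 1
                assert blues[rec["genotype"]] == pytest.approx(
                    rec["value"] - blup[b_idx], abs=1e-6)


class TestSelectSpatialTerms:
    @staticmethod
    def _env_df(sigma2_row, sigma2_col, seed, n_genotypes=12):
        cfg = ms.SimulationConfig(n_genotypes=n_genotypes, n_locations=1, n_years=1,
                                  n_replicates=3, mu=0, sigma2_g=1.0,
                                  sigma2_l=0, sigma2_a=0, sigma2_la=0,
                                  sigma2_block=0.5, sigma2_row=sigma2_row,
                                  sigma2_col=sigma2_col, sigma2_gl=0,
                                  sigma2_ga=0, sigma2_gla=0, sigma2_e=1.0,
                                  seed=seed)
        plots, _ = ms.simulate_met(cfg)
        return plots.df

    def test_null_spatial_rarely_selected(self):
        # AIC admits a boundary variance term with ~8% probability per
        # candidate under the null, so the base model is expected in ~86%
        # of trials; assert a bound consistent with that rate at n=60
        picks = 0
        n = 60
        for s in range(n):
            chosen, _ = select_spatial_terms(self._env_df(0.0, 0.0, 300 + s),
                                             base_random=("block",))
            picks += chosen == ("block",)
        assert picks >= 0.78 * n

    def test_strong_row_effect_selected(self):
        picks = 0
        n = 60
        for s in range(n):
            chosen, _ = select_spatial_terms(
                self._env_df(1.0, 0.0, 600 + s, n_genotypes=20),
                base_random=("block",))
            picks += "row" in chosen
        assert picks >= 0.85 * n

    def test_tie_prefers_smaller_model_deterministically(self):
        # row and column made identical factors: equal likelihoods, the
        # selection must be deterministic and never pick the redundant pair
        df = self._env_df(1.0, 0.0, 11).copy()
        df["column"] = df["row"]
        c1, t1 = select_spatial_terms(df, base_random=("block",))
        c2, _ = select_spatial_terms(df.sample(frac=1, random_state=5),
                                     base_random=("block",))
        assert c1 == c2
        assert len(c1) <= 2  # block + at most one of the two identical terms

    def test_lrt_mode(self):
        df = self._env_df(1.0, 0.0, 12)
        chosen, table = select_spatial_terms(df, base_random=("block",),
                                             criterion="lrt")
        assert "row" in chosen
        assert set(table.columns) >= {"extra_terms", "minus2_reml", "aic", "chosen"}


class TestVarianceComponents:
    def test_full_model_requires_two_locations(self):
        cfg = ms.SimulationConfig(n_genotypes=5, n_locations=1, n_years=3,
                                  n_replicates=2, sigma2_e=1.0, seed=1)
        plots, _ = ms.simulate_met(cfg)
        with pytest.raises(RemlError, match="per_location"):
            ms.estimate_variance_components(plots, "yield_kg_ha")

    def test_reduced_scopes(self, small_met):
        _, plots, _ = small_met
        vl = ms.estimate_variance_components(plots, "yield_kg_ha",
                                             scope="per_location", location="L1")
        assert vl.sigma2_l is None and vl.sigma2_ga is not None
        env = plots.environments[0]
        ve = ms.estimate_variance_components(plots, "yield_kg_ha",
                                             scope="per_environment", environment=env)
        assert ve.sigma2_ga is None and ve.sigma2_g >= 0

    def test_pure_noise_drives_structural_components_to_boundary(self):
        # under sigma2 = 0 truth the nonnegativity bound is active for most
        # components; sampling noise can leave small positive remnants, so
        # assert near-zero magnitudes plus a non-empty clamped set
        cfg = ms.SimulationConfig(n_genotypes=12, n_locations=2, n_years=2,
                                  n_replicates=2, mu=0, sigma2_g=0, sigma2_l=0,
                                  sigma2_a=0, sigma2_la=0, sigma2_block=0,
                                  sigma2_gl=0, sigma2_ga=0, sigma2_gla=0,
                                  sigma2_e=1.0, seed=23)
        plots, _ = ms.simulate_met(cfg)
        vc = ms.estimate_variance_components(plots, "yield_kg_ha")
        for k, v in vc.as_dict().items():
            if k == "residual":
                assert v > 0.5
            else:
                assert v <= 0.12, (k, v)  # at or near the zero bound
        assert len(vc.clamped) >= 2

    def test_gla_zero_recovery(self):
        # truth sigma2_GLA = 0: its estimate sits at/near the boundary in
        # the 50 x 2 x 5 x 3 network (<= 5% of total genetic variance)
        hits = 0
        n = 60
        for s in range(n):
            cfg = ms.SimulationConfig(n_genotypes=50, n_locations=2, n_years=5,
                                      n_replicates=3, mu=0, sigma2_g=2,
                                      sigma2_l=1, sigma2_a=1, sigma2_la=1,
                                      sigma2_block=0.5, sigma2_gl=1,
                                      sigma2_ga=1, sigma2_gla=0.0,
                                      sigma2_e=2, seed=900 + s)
            plots, _ = ms.simulate_met(cfg)
            vc = ms.estimate_variance_components(plots, "yield_kg_ha")
            hits += (vc.sigma2_gla <= 0.05 * vc.total_genetic())
        assert hits >= 0.9 * n


class TestScoreModel:
    def test_single_evaluator_blues_are_means(self):
        recs, _ = ms.simulate_scores(1, 5, None, np.arange(5) * 0.3, 0.0, 0.0,
                                     0.25, scale=(1, 10), seed=6)
        with pytest.warns(UserWarning, match="single evaluator"):
            res = ms.fit_score_model(recs)
        df = pd.DataFrame([(r.genotype_id, r.score) for r in recs],
                          columns=["g", "s"])
        means = df.groupby("g")["s"].mean()
        got = res.table.set_index("genotype")["blue"]
        assert np.allclose(got, means.loc[got.index], atol=1e-10)
        assert res.evaluator_variance is None

    def test_additive_evaluator_shifts_cancel_in_differences(self):
        # evaluator effects injected additively with no noise: BLUE
        # differences equal the true genotype-effect differences exactly
        geno = np.array([0.0, 0.8, -0.5, 1.2])
        recs, truth = ms.simulate_scores(4, 4, None, geno, 1.0, 0.0, 0.0,
                                         scale=(-100, 100), mu=0.0, seed=9)
        res = ms.fit_score_model(recs)
        got = res.table.set_index("genotype")["blue"]
        g_sorted = sorted(truth["genotype_effects"])
        diffs = np.diff([got[g] for g in g_sorted])
        true_diffs = np.diff([truth["genotype_effects"][g] for g in g_sorted])
        assert np.allclose(diffs, true_diffs, atol=1e-8)

    def test_stage_variance_estimated_when_requested(self):
        recs, _ = ms.simulate_scores(5, 4, ["mix", "proof", "bake"],
                                     np.zeros(4), 0.5, 1.0, 0.3,
                                     scale=(1, 10), seed=10)
        res = ms.fit_score_model(recs, include_stage=True)
        assert res.stage_variance is not None and res.stage_variance >= 0
        assert res.evaluator_variance is not None

    def test_include_stage_without_stage_info_errors(self):
        recs, _ = ms.simulate_scores(3, 3, None, np.zeros(3), 0.1, 0.0, 0.1,
                                     scale=(1, 10), seed=11)
        with pytest.raises(RemlError):
            ms.fit_score_model(recs, include_stage=True)
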