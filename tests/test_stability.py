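"""Finlay-Wilkinson regression and Wricke ecovalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metstab as ms
from metstab.data import MetDataError


def matrix_of(rows, genotypes=None, years=None):
    Y = np.asarray(rows, dtype=float)
    genotypes = genotypes or [f"g{i}" for i in range(Y.shape[0])]
    envs = [ms.EnvironmentKey("E", 2000 + j) for j in range(Y.shape[1])]
    return ms.BlueMatrix(pd.DataFrame(Y, index=genotypes, columns=envs))


def anova_interaction_ss(Y):
    """Independent two-way ANOVA oracle for the interaction sum of squares."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    g, e = Y.shape
    df = pd.DataFrame({
        "y": Y.ravel(),
        "g": np.repeat([f"g{i}" for i in range(g)], e),
        "e": np.tile([f"e{j}" for j in range(e)], g),
    })
    model = smf.ols("y ~ C(g) + C(e)", data=df).fit()
    return float(model.ssr)  # residual SS of the additive model = GEI SS


class TestFinlayWilkinson:
    def test_hand_example(self):
        fw = ms.finlay_wilkinson(matrix_of([[10, 20, 30], [30, 40, 50]]))
        assert np.allclose(fw.env_index, [-10, 0, 10])
        assert np.allclose(fw.table["beta"], 1.0, atol=1e-12)
        assert np.allclose(fw.table["r2"], 1.0, atol=1e-12)

    def test_noise_free_recovery(self):
        slopes = np.linspace(0.6, 1.4, 8)
        blues, truth = ms.simulate_fw(8, 10, slopes, noise_sd=0.0, seed=4, env_sd=3.0)
        fw = ms.finlay_wilkinson(blues)
        got = fw.table.set_index("genotype")["beta"]
        for g, b in truth["slopes"].items():
            assert got[g] == pytest.approx(b, abs=1e-10)
        assert np.allclose(fw.table["r2"], 1.0, atol=1e-12)

    def test_constant_genotype_has_zero_slope(self):
        rows = [[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0], [0.0, 2.0, 4.0, 6.0]]
        fw = ms.finlay_wilkinson(matrix_of(rows))
        assert fw.table.set_index("genotype").loc["g0", "beta"] == pytest.approx(0.0, abs=1e-12)
        assert fw.table.set_index("genotype").loc["g0", "label"] == "static"

    def test_mean_slope_is_one_on_complete_tables(self, rng, blue_matrix_factory):
        bm = blue_matrix_factory(rng, 9, 6)
        fw = ms.finlay_wilkinson(bm)
        assert fw.table["beta"].mean() == pytest.approx(1.0, abs=1e-10)
        assert (fw.table["beta"] - 1.0).sum() == pytest.approx(0.0, abs=1e-9)

    def test_residuals_orthogonal_to_index(self, rng, blue_matrix_factory):
        bm = blue_matrix_factory(rng, 5, 7)
        fw = ms.finlay_wilkinson(bm)
        x = fw.env_index.to_numpy()
        for g, row in bm.values.iterrows():
            rec = fw.table.set_index("genotype").loc[g]
            resid = row.to_numpy() - rec["intercept"] - rec["beta"] * x
            assert abs(resid @ x) < 1e-8

    def test_sparse_genotype_excluded(self, rng, blue_matrix_factory):
        bm = blue_matrix_factory(rng, 6, 5)
        bm.values.iloc[0, :3] = np.nan  # g00 observed in only 2 environments
        fw = ms.finlay_wilkinson(bm)
        assert fw.excluded == ["g00"]
        assert "g00" not in set(fw.table["genotype"])

    def test_too_few_environments(self):
        with pytest.raises(MetDataError):
            ms.finlay_wilkinson(matrix_of([[1, 2], [2, 3]]))

    def test_zero_index_variance(self):
        with pytest.raises(MetDataError, match="zero variance"):
            ms.finlay_wilkinson(matrix_of([[1, 1, 1], [2, 2, 2]]))


class TestClassifySensitivity:
    @pytest.mark.parametrize("beta,label", [
        (0.79, "sub-sensitive"),  # just below the dynamic band
        (1.0, "dynamic"),
        (2.0, "hypersensitive"),
        (0.3, "static"),
        (1.20, "dynamic"),
    ])
    def test_bands(self, beta, label):
        assert ms.classify_sensitivity(beta) == label

    def test_invalid_bands(self):
        with pytest.raises(ValueError):
            ms.classify_sensitivity(1.0, bands=(0.9, 0.5, 1.2))


class TestWrickeEcovalence:
    def test_additive_table_gives_zero(self):
        g = np.array([1.0, 2.0, 4.0])
        e = np.array([10.0, 20.0, 25.0, 5.0])
        w = ms.wricke_ecovalence(matrix_of(g[:, None] + e[None, :]))
        assert np.allclose(w.table["W"], 0.0, atol=1e-18)

    def test_two_by_two_checkerboard(self):
        # double-centered residuals are +-0.5, so W_i = 2 * 0.25 = 0.5
        w = ms.wricke_ecovalence(matrix_of([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(w.table["W"], 0.5, atol=1e-14)
        assert w.total == pytest.approx(1.0, abs=1e-14)

    def test_total_equals_anova_interaction_ss(self, rng):
        Y = rng.normal(10, 3, (5, 6))
        w = ms.wricke_ecovalence(matrix_of(Y))
        assert w.total == pytest.approx(anova_interaction_ss(Y), rel=1e-8)

    def test_duplicated_genotype_rows_get_identical_w(self):
        Y = np.array([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0], [4.0, 0.0, 3.0]])
        w = ms.wricke_ecovalence(matrix_of(Y)).table.set_index("genotype")
        assert w.loc["g0", "W"] == pytest.approx(w.loc["g1", "W"], rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_row_and_column_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(0, 2, (4, 5))
        base = ms.wricke_ecovalence(matrix_of(Y)).table["W"].to_numpy()
        shifted = (Y + rng.normal(0, 5, (4, 1)) + rng.normal(0, 5, (1, 5)))
        got = ms.wricke_ecovalence(matrix_of(shifted)).table["W"].to_numpy()
        assert np.allclose(base, got, atol=1e-8)

    def test_scale_equivariance(self, rng):
        Y = rng.normal(0, 1, (4, 5))
        w1 = ms.wricke_ecovalence(matrix_of(Y)).table["W"].to_numpy()
        w2 = ms.wricke_ecovalence(matrix_of(3.0 * Y)).table["W"].to_numpy()
        assert np.allclose(9.0 * w1, w2, rtol=1e-12)
        fw1 = ms.finlay_wilkinson(matrix_of(Y)).table
        fw2 = ms.finlay_wilkinson(matrix_of(3.0 * Y)).table
        assert np.allclose(fw1["beta"], fw2["beta"], atol=1e-10)
        assert np.allclose(fw1["r2"], fw2["r2"], atol=1e-10)

    def test_fw_agreement_in_degenerate_case(self):
        # all slopes one with zero FW residual variance implies W = 0
        blues, _ = ms.simulate_fw(5, 6, np.ones(5), noise_sd=0.0, seed=8)
        w = ms.wricke_ecovalence(blues)
        assert np.allclose(w.table["W"], 0.0, atol=1e-16)

    def test_missing_cells(self, rng, blue_matrix_factory):
        bm = blue_matrix_factory(rng, 4, 5)
        bm.values.iloc[1, 2] = np.nan
        with pytest.raises(MetDataError):
            ms.wricke_ecovalence(bm)
        w = ms.wricke_ecovalence(bm, on_missing="drop")
        assert len(w.environments) == 4

    def test_too_small(self):
        with pytest.raises(MetDataError):
            ms.wricke_ecovalence(matrix_of([[1.0, 2.0]]))


class TestDropEnvironments:
    def test_identity_and_reduction(self, rng, blue_matrix_factory):
        bm = blue_matrix_factory(rng, 5, 10)
        same = ms.drop_environments(bm, [])
        pd.testing.assert_frame_equal(same.values, bm.values)
        red = ms.drop_environments(bm, bm.environments[:2])
        assert len(red.environments) == 8
        assert list(red.values.index) == list(bm.values.index)

    def test_cannot_drop_below_three(self, rng, blue_matrix_factory):
        bm = blue_matrix_factory(rng, 5, 4)
        with pytest.raises(MetDataError):
            ms.drop_environments(bm, bm.environments[:2])

    def test_extreme_environment_sensitivity_harness(self):
        # inflate two environments and report the slope rank correlation
        # between the full and reduced analyses (no fixed value expected)
        from scipy import stats
        blues, _ = ms.simulate_fw(10, 10, np.linspace(0.7, 1.3, 10),
                                  noise_sd=0.3, seed=12, env_sd=2.0)
        inflated = blues.values.copy()
        inflated.iloc[:, :2] = inflated.iloc[:, :2] * 3.0 + 40.0
        bm = ms.BlueMatrix(inflated)
        full = ms.finlay_wilkinson(bm).table.set_index("genotype")["beta"]
        red = ms.finlay_wilkinson(
            ms.drop_environments(bm, bm.environments[:2])).table.set_index("genotype")["beta"]
        rho = stats.spearmanr(full, red.loc[full.index]).statistic
        assert -1.0 <= rho <= 1.0
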