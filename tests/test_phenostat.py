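import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypwas.phenostat import (
    PlotTable,
    VarianceComponents,
    _RemlProblem,
    correlate,
    fit_blup,
    heritability,
    restricted_loglik,
)
from hypwas.simulate import SimConfig, simulate_genotypes, simulate_trial


def brute_force_neg2_reml(df, g1, g2, with_gxe=True):
    """Dense-matrix restricted likelihood oracle (profiled over var_e)."""
    gen = sorted(df["genotype"].unique())
    env = sorted(df["environment"].unique())
    gi = df["genotype"].map({g: i for i, g in enumerate(gen)}).to_numpy()
    ei = df["environment"].map({e: i for i, e in enumerate(env)}).to_numpy()
    n, ng, ne = len(df), len(gen), len(env)
    X = np.zeros((n, ne))
    X[np.arange(n), ei] = 1.0
    Z1 = np.zeros((n, ng))
    Z1[np.arange(n), gi] = 1.0
    H = np.eye(n) + g1 * Z1 @ Z1.T
    if with_gxe:
        Z2 = np.zeros((n, ng * ne))
        Z2[np.arange(n), gi * ne + ei] = 1.0
        H += g2 * Z2 @ Z2.T
    Hi = np.linalg.inv(H)
    y = df["value"].to_numpy(float)
    XtHiX = X.T @ Hi @ X
    beta = np.linalg.solve(XtHiX, X.T @ Hi @ y)
    ypy = float(y @ Hi @ y - (X.T @ Hi @ y) @ beta)
    return (
        np.linalg.slogdet(H)[1]
        + np.linalg.slogdet(XtHiX)[1]
        + (n - ne) * np.log(ypy)
    )


@pytest.fixture()
def unbalanced_df(rng):
    rows = []
    for g in range(8):
        for e in range(3):
            for r in range(2):
                if rng.random() < 0.2:
                    continue
                rows.append(
                    dict(genotype=f"g{g}", environment=f"e{e}",
                         replicate=f"r{r}", trait="t", value=rng.normal())
                )
    return pd.DataFrame(rows)


class TestRemlCore:
    @pytest.mark.parametrize("g1,g2", [(0.5, 0.3), (2.0, 0.01), (1e-5, 1.5), (3.0, 3.0)])
    def test_matches_dense_oracle(self, unbalanced_df, g1, g2):
        prob = _RemlProblem(unbalanced_df, with_gxe=True)
        fast = prob._core(g1, g2)[0]
        slow = brute_force_neg2_reml(unbalanced_df, g1, g2)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_single_env_matches_oracle(self, unbalanced_df):
        df = unbalanced_df[unbalanced_df["environment"] == "e0"]
        prob = _RemlProblem(df, with_gxe=False)
        fast = prob._core(0.7, 0.0)[0]
        slow = brute_force_neg2_reml(df, 0.7, 0.0, with_gxe=False)
        assert fast == pytest.approx(slow, abs=1e-8)


class TestFitBlup:
    def test_parameter_recovery(self):
        cfg = SimConfig(n_genotypes=300, n_markers=20, var_g=1.0, var_int=0.5,
                        var_e=1.0, n_env=4, n_rep=2, seed=3)
        tbl, _ = simulate_trial(cfg, simulate_genotypes(cfg))
        fit = fit_blup(tbl, "yield")
        assert fit.vc.var_g == pytest.approx(1.0, rel=0.15)
        assert fit.vc.var_int == pytest.approx(0.5, rel=0.15)
        assert fit.vc.var_e == pytest.approx(1.0, rel=0.15)

    def test_constant_trait_all_zero(self):
        rows = [
            dict(genotype=g, environment=e, replicate=r, trait="t", value=5.0)
            for g in "ab" for e in "xy" for r in "12"
        ]
        fit = fit_blup(PlotTable(pd.DataFrame(rows)), "t")
        assert fit.vc.var_g == 0 and fit.vc.var_e == 0
        assert (fit.genotype_effects == 0).all()

    def test_var_e_zero_limit_blups_equal_mean_deviations(self):
        cfg = SimConfig(n_genotypes=40, n_markers=10, var_g=1.0, var_int=0.0,
                        var_e=1e-8, n_env=2, n_rep=2, seed=5)
        tbl, _ = simulate_trial(cfg, simulate_genotypes(cfg))
        fit = fit_blup(tbl, "yield")
        df = tbl.data.copy()
        df["dev"] = df["value"] - df.groupby("environment")["value"].transform("mean")
        means = df.groupby("genotype")["dev"].mean()
        np.testing.assert_allclose(
            fit.genotype_effects.loc[means.index], means, atol=1e-3
        )

    def test_no_replication_multi_env_errors(self):
        rows = [
            dict(genotype=g, environment=e, replicate="r1", trait="t", value=float(hash((g, e)) % 7))
            for g in "abcd" for e in "xyz"
        ]
        with pytest.raises(ValueError, match="confounded"):
            fit_blup(PlotTable(pd.DataFrame(rows)), "t")

    def test_single_env_single_rep_degrades_gracefully(self, rng):
        rows = [
            dict(genotype=f"g{i}", environment="e1", replicate="r1",
                 trait="t", value=rng.normal())
            for i in range(30)
        ]
        fit = fit_blup(PlotTable(pd.DataFrame(rows)), "t")
        assert fit.vc.var_int == 0.0
        assert np.isfinite(fit.log_restricted_likelihood)

    def test_blup_mean_near_zero(self):
        cfg = SimConfig(n_genotypes=100, n_markers=10, seed=7)
        tbl, _ = simulate_trial(cfg, simulate_genotypes(cfg))
        fit = fit_blup(tbl, "yield")
        assert abs(fit.genotype_effects.mean()) < 1e-6

    def test_optimum_beats_perturbations(self, rng):
        cfg = SimConfig(n_genotypes=60, n_markers=10, var_g=0.8, var_int=0.3,
                        var_e=1.2, seed=9)
        tbl, _ = simulate_trial(cfg, simulate_genotypes(cfg))
        fit = fit_blup(tbl, "yield")
        best = restricted_loglik(tbl, "yield", fit.vc)
        assert best == pytest.approx(fit.log_restricted_likelihood, abs=1e-4)
        for _ in range(20):
            factors = np.exp(rng.uniform(-0.7, 0.7, size=3))
            vc = VarianceComponents(
                max(fit.vc.var_g, 1e-4) * factors[0],
                max(fit.vc.var_int, 1e-4) * factors[1],
                fit.vc.var_e * factors[2],
            )
            assert restricted_loglik(tbl, "yield", vc) <= best + 1e-6

    def test_missing_values_excluded(self, rng):
        cfg = SimConfig(n_genotypes=30, n_markers=10, seed=13)
        tbl, _ = simulate_trial(cfg, simulate_genotypes(cfg))
        data = tbl.data.copy()
        data.loc[data.index[:5], "value"] = np.nan
        fit = fit_blup(PlotTable(data), "yield")
        assert np.isfinite(fit.vc.var_e)


class TestHeritability:
    def test_pure_genetic(self):
        assert heritability(VarianceComponents(1, 0, 0), 3, 2) == 1.0

    def test_no_genetic(self):
        assert heritability(VarianceComponents(0, 1, 1), 3, 2) == 0.0

    def test_hand_computed(self):
        # 2 / (2 + 1/4 + 4/8)
        h2 = heritability(VarianceComponents(2, 1, 4), 4, 2)
        assert h2 == pytest.approx(2 / 2.75, abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            heritability(VarianceComponents(0, 0, 0), 2, 2)

    @settings(max_examples=30, deadline=None)
    @given(
        vg=st.floats(0.01, 10), vi=st.floats(0, 10), ve=st.floats(0.01, 10),
        n=st.integers(1, 8), r=st.integers(1, 8),
    )
    def test_monotone_in_var_g_and_reps(self, vg, vi, ve, n, r):
        h = heritability(VarianceComponents(vg, vi, ve), n, r)
        assert 0 <= h <= 1
        assert heritability(VarianceComponents(vg * 2, vi, ve), n, r) >= h
        assert heritability(VarianceComponents(vg, vi, ve), n, r + 1) >= h


class TestCorrelate:
    def _bands(self, cols):
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))])

    def test_identity_r_one(self):
        t = pd.Series([1.0, 2, 3, 4], index=["g0", "g1", "g2", "g3"])
        bands = self._bands({"b1": [1.0, 2, 3, 4]})
        assert correlate(bands, t)["b1"] == pytest.approx(1.0)

    def test_negation_r_minus_one(self):
        t = pd.Series([1.0, 2, 3, 4], index=["g0", "g1", "g2", "g3"])
        bands = self._bands({"b1": [-1.0, -2, -3, -4]})
        assert correlate(bands, t)["b1"] == pytest.approx(-1.0)

    def test_hand_computed_point_six(self):
        t = pd.Series([2.0, 1, 4, 3], index=["g0", "g1", "g2", "g3"])
        bands = self._bands({"b1": [1.0, 2, 3, 4]})
        assert correlate(bands, t)["b1"] == pytest.approx(0.6)

    def test_zero_variance_warns_nan(self):
        t = pd.Series([1.0, 2, 3, 4], index=["g0", "g1", "g2", "g3"])
        bands = self._bands({"b1": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning, match="undefined"):
            r = correlate(bands, t)
        assert np.isnan(r["b1"])


class TestPlotTable:
    def test_duplicate_key_rejected(self):
        rows = [
            dict(genotype="a", environment="e", replicate="r", trait="t", value=1.0),
            dict(genotype="a", environment="e", replicate="r", trait="t", value=2.0),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            PlotTable(pd.DataFrame(rows))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            PlotTable(pd.DataFrame({"genotype": ["a"]}))
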