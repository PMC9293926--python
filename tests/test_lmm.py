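import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dense_loglik
from streamtemp import lmm
from streamtemp.exceptions import ConvergenceError, DataError
from streamtemp.lmm import ModelSpec, build_design, car_correlation, marginal_loglik
from streamtemp.synthetic import TruthParams, simulate_paired_dataset


def small_design(seed, n_sites=5, n_obs=9, env=("elevation",), phi_truth=0.8):
    truth = TruthParams.daily(phi=phi_truth, sigma=1.2)
    sites, paired = simulate_paired_dataset(n_sites, n_obs, truth, seed=seed, n_catchments=2)
    return build_design(paired, sites, ModelSpec(env_covariates=env)), paired, sites


class TestCarCorrelation:
    def test_zero_gap_is_one_even_at_phi_zero(self):
        assert car_correlation(0.0, 0.0) == 1.0
        assert car_correlation(0.8, 0.0) == 1.0

    def test_closed_form(self):
        assert car_correlation(0.5, 2.0) == pytest.approx(0.25)
        assert car_correlation(0.962, 1.0) == pytest.approx(0.962)

    def test_fractional_gaps_supported(self):
        assert car_correlation(0.64, 0.5) == pytest.approx(0.8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            car_correlation(1.0, 1.0)
        with pytest.raises(ValueError):
            car_correlation(0.5, -1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        phi=st.floats(min_value=0.01, max_value=0.99),
        dt=st.floats(min_value=0.01, max_value=50),
        step=st.floats(min_value=0.01, max_value=10),
    )
    def test_strictly_decreasing_in_gap(self, phi, dt, step):
        assert car_correlation(phi, dt + step) < car_correlation(phi, dt)


class TestBuildDesign:
    def test_four_catchments_give_three_contrasts_with_alphabetic_reference(self):
        truth = TruthParams.daily()
        sites, paired = simulate_paired_dataset(12, 6, truth, seed=0, n_catchments=4)
        dm = build_design(paired, sites, ModelSpec())
        assert [c for c in dm.columns if c.startswith("catchment")] == [
            "catchment[Kiso]",
            "catchment[Sorachi]",
            "catchment[Teshio]",
        ]  # Hiji is the (alphabetically first) reference

    def test_full_model_has_ten_columns(self):
        truth = TruthParams.daily()
        sites, paired = simulate_paired_dataset(12, 6, truth, seed=0, n_catchments=4)
        dm = build_design(paired, sites, ModelSpec())
        assert dm.X.shape[1] == 10  # intercept + air + 3 contrasts + 5 covariates

    def test_single_catchment_drops_factor_with_warning(self):
        truth = TruthParams.daily()
        sites, paired = simulate_paired_dataset(6, 6, truth, seed=0, n_catchments=1)
        with pytest.warns(UserWarning, match="catchment"):
            dm = build_design(paired, sites, ModelSpec(env_covariates=()))
        assert dm.columns == ["intercept", "ta"]

    def test_duplicated_covariate_column_is_data_error(self):
        truth = TruthParams.daily()
        sites, paired = simulate_paired_dataset(8, 6, truth, seed=0, n_catchments=2)
        sites["elevation_copy"] = sites["elevation"]
        with pytest.raises(DataError, match="collinear"):
            build_design(paired, sites, ModelSpec(env_covariates=("elevation", "elevation_copy")))

    def test_site_without_covariates_is_data_error(self):
        truth = TruthParams.daily()
        sites, paired = simulate_paired_dataset(6, 6, truth, seed=0, n_catchments=2)
        with pytest.raises(DataError, match="covariate"):
            build_design(paired, sites.drop(index=sites.index[0]), ModelSpec())

    def test_air_centering_shifts_intercept_only(self):
        truth = TruthParams.monthly()
        sites, paired = simulate_paired_dataset(20, 8, truth, seed=6)
        spec_raw = ModelSpec(correlation="none", env_covariates=())
        spec_centered = ModelSpec(correlation="none", env_covariates=(), center_air=True)
        raw = lmm.fit(paired, sites, spec_raw)
        cen = lmm.fit(paired, sites, spec_centered)
        assert cen.beta["ta"] == pytest.approx(raw.beta["ta"], abs=1e-4)
        shift = paired["ta"].mean() * raw.beta["ta"]
        assert cen.beta["intercept"] == pytest.approx(raw.beta["intercept"] + shift, abs=1e-2)

    def test_duplicate_period_is_data_error(self):
        truth = TruthParams.daily()
        sites, paired = simulate_paired_dataset(6, 6, truth, seed=0, n_catchments=2)
        dup = pd.concat([paired, paired.iloc[[0]]], ignore_index=True)
        with pytest.raises(DataError, match="duplicate"):
            build_design(dup, sites, ModelSpec())


class TestMarginalLoglik:
    def test_standard_normal_point_mass(self):
        # D = 0, phi = 0, sigma = 1, two residual-free observations:
        # the ML density of two exact zeros is -log(2 pi).
        paired = pd.DataFrame(
            {"site_id": ["a", "a"], "time": [0.0, 1.0], "ta": [0.0, 1.0], "tw": [0.0, 0.0]}
        )
        sites = pd.DataFrame(index=pd.Index(["a"], name="site_id"))
        dm = build_design(paired, sites, ModelSpec(env_covariates=(), include_catchment=False))
        ll = marginal_loglik(dm, np.zeros((2, 2)), 1.0, 0.0, "ML")
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-10)

    @pytest.mark.parametrize("method", ["ML", "REML"])
    @pytest.mark.parametrize("phi", [0.0, 0.5, 0.962])
    def test_blockwise_equals_dense_oracle(self, method, phi):
        D = np.array([[1.3, 0.06], [0.06, 0.02]])
        for seed in range(6):
            dm, _, _ = small_design(seed)
            a = marginal_loglik(dm, D, 1.2, phi, method)
            b = dense_loglik(dm, D, 1.2, phi, method)
            assert a == pytest.approx(b, abs=1e-8)

    def test_phi_zero_equals_independent_error_model(self):
        dm, _, _ = small_design(3)
        D = np.diag([0.5, 0.01])
        with_car = marginal_loglik(dm, D, 1.0, 0.0, "ML")
        # build the same likelihood through the no-correlation path
        without = dense_loglik(dm, D, 1.0, 0.0, "ML")
        assert with_car == pytest.approx(without, abs=1e-10)

    def test_invalid_parameters(self):
        dm, _, _ = small_design(0)
        with pytest.raises(ValueError):
            marginal_loglik(dm, np.eye(2), -1.0, 0.0, "ML")
        with pytest.raises(ValueError):
            marginal_loglik(dm, np.eye(2), 1.0, 1.0, "ML")
        with pytest.raises(ValueError):
            marginal_loglik(dm, np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0, 0.0, "ML")


class TestFit:
    def test_reduces_to_ols_when_variances_vanish(self):
        # At D = 0, phi = 0 the profiled GLS solution is exactly OLS
        dm, paired, sites = small_design(2, n_sites=6, n_obs=10)
        from streamtemp.lmm import _gls_from_sums, _site_sums

        S, _ = _site_sums(dm, np.zeros((2, 2)), 0.0)
        beta, rss, _, _ = _gls_from_sums(S)
        ols_beta, *_ = np.linalg.lstsq(dm.X, dm.y, rcond=None)
        assert np.allclose(beta, ols_beta, atol=1e-6)
        ols_rss = float(((dm.y - dm.X @ ols_beta) ** 2).sum())
        assert rss == pytest.approx(ols_rss, rel=1e-8)

    def test_permuting_rows_leaves_fit_invariant(self):
        truth = TruthParams.monthly()
        sites, paired = simulate_paired_dataset(20, 8, truth, seed=5)
        spec = ModelSpec(correlation="none")
        f1 = lmm.fit(paired, sites, spec)
        shuffled = paired.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f2 = lmm.fit(shuffled, sites, spec)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)

    def test_near_zero_variance_truth_recovers_small_D(self):
        truth = TruthParams.monthly(tau00=0.0, tau11=0.0)
        spec = ModelSpec(correlation="none", method="ML")
        biases, tau00s, tau11s = [], [], []
        for rep in range(5):
            sites, paired = simulate_paired_dataset(40, 12, truth, seed=100 + rep)
            f = lmm.fit(paired, sites, spec)
            se = np.sqrt(f.beta_cov.loc["ta", "ta"])
            biases.append((f.beta["ta"] - truth.beta_air) / se)
            tau00s.append(f.tau00)
            tau11s.append(f.tau11)
        assert np.all(np.abs(biases) < 3.5)
        # boundary MLEs fluctuate above zero; on average the estimated
        # between-site variances are an order of magnitude below the
        # residual variance (sigma^2 = 0.68) and far below the realistic
        # regime (tau00^2 = 1.75)
        assert np.mean(np.square(tau00s)) < 0.25
        assert np.mean(np.square(tau11s)) < 0.005

    def test_matches_statsmodels_mixedlm_without_car(self):
        # independent cross-check of the phi = 0 sub-model
        sm = pytest.importorskip("statsmodels.api")
        truth = TruthParams.monthly()
        sites, paired = simulate_paired_dataset(40, 10, truth, seed=21)
        spec = ModelSpec(correlation="none", method="ML", env_covariates=("elevation",))
        ours = lmm.fit(paired, sites, spec)

        data = paired.join(sites, on="site_id")
        model = sm.MixedLM.from_formula(
            "tw ~ ta + C(catchment) + elevation",
            groups="site_id",
            re_formula="~ta",
            data=data,
        )
        theirs = model.fit(reml=False, method="lbfgs")
        assert ours.loglik == pytest.approx(theirs.llf, abs=1e-2)
        assert ours.beta["ta"] == pytest.approx(theirs.params["ta"], abs=1e-3)
        assert ours.sigma**2 == pytest.approx(theirs.scale, rel=2e-2)

    def test_fewer_than_two_sites_rejected(self):
        truth = TruthParams.monthly()
        sites, paired = simulate_paired_dataset(2, 8, truth, seed=1, n_catchments=1)
        one = paired[paired["site_id"] == paired["site_id"].iloc[0]]
        with pytest.raises(DataError):
            lmm.fit(one, sites, ModelSpec(env_covariates=(), include_catchment=False))


class TestFixedInference:
    def test_t_is_coef_over_se_and_df_rule(self, monthly_fit):
        fitted, _, _ = monthly_fit
        table = lmm.fixed_inference(fitted)
        assert np.allclose(table["t"], table["coef"] / table["se"])
        n_sites, n_obs = fitted.n_sites, fitted.n_obs
        # 8 site-level terms: 3 catchment contrasts + 5 covariates
        assert table.loc["elevation", "df"] == n_sites - 8 - 1
        assert table.loc["catchment[Kiso]", "df"] == n_sites - 8 - 1
        # observation-level: intercept and air temperature
        assert table.loc["ta", "df"] == n_obs - n_sites - 1
        assert table.loc["intercept", "df"] == n_obs - n_sites - 1

    def test_large_df_matches_normal_approximation(self, monthly_fit):
        fitted, _, _ = monthly_fit
        from scipy import stats

        table = lmm.fixed_inference(fitted)
        z = table.loc["ta", "t"]
        p_norm = 2 * stats.norm.sf(abs(z))
        assert table.loc["ta", "p"] == pytest.approx(p_norm, abs=1e-3)

    def test_nonconverged_fit_is_refused(self, monthly_fit):
        fitted, _, _ = monthly_fit
        import dataclasses

        broken = dataclasses.replace(fitted, converged=False)
        with pytest.raises(ConvergenceError):
            lmm.fixed_inference(broken)


class TestLRT:
    def test_identical_specs_give_null_result(self, monthly_fit):
        fitted, paired, sites = monthly_fit
        chi2, df, p = lmm.lrt_compare(fitted, fitted, paired, sites)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert df == 0 and p == 1.0

    def test_baseline_vs_full_has_df_five_and_tiny_p(self, monthly_fit):
        fitted, paired, sites = monthly_fit
        base = lmm.fit(paired, sites, ModelSpec(env_covariates=(), correlation="none"))
        chi2, df, p = lmm.lrt_compare(base, fitted, paired, sites)
        assert df == 5
        assert chi2 > 0
        assert p < 1e-4  # simulated environmental effects are strong

    def test_non_nested_specs_rejected(self, monthly_fit):
        fitted, paired, sites = monthly_fit
        other = lmm.fit(paired, sites, ModelSpec(env_covariates=("cultivated",), correlation="none"))
        reduced = lmm.fit(paired, sites, ModelSpec(env_covariates=("elevation",), correlation="none"))
        with pytest.raises(ValueError, match="nested"):
            lmm.lrt_compare(reduced, other, paired, sites)
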