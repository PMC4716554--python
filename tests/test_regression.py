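"""Design assembly and the negative binomial fit."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermolag as tl
from thermolag.regression import (DesignInfo, FitError, _nb2_loglik, assemble_design,
                                  diagnostics, fit_negbin)


def _daily_frame(n, seed=0, counts=None):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2009-01-01", periods=n, freq="D")
    return pd.DataFrame({
        "date": dates,
        "tavg": rng.normal(25.7, 4.1, n),
        "tmax": rng.normal(29.9, 5.5, n),
        "tmin": rng.normal(21.7, 3.1, n),
        "humidity": rng.uniform(40, 100, n),
        "dewpoint": rng.normal(22, 2.7, n),
        "deaths_all": counts if counts is not None else rng.poisson(3.4, n),
    })


class TestAssembleDesign:
    def test_final_model_block_sizes(self):
        data = _daily_frame(1826)
        design = assemble_design(data, tl.ModelSpec())
        # 1 intercept + 4x5 cross-basis + 6 dow + 25 time + 3 humidity + 3 dewpoint
        assert design.X.shape[1] == 1 + 20 + 6 + 25 + 3 + 3
        assert len(design.blocks["time"]) == 25
        assert len(design.blocks["crossbasis"]) == 20
        assert len(design.blocks["dow"]) == 6

    def test_five_years_time_spline_25_columns(self):
        design = assemble_design(_daily_frame(1826), tl.ModelSpec(time_df_per_year=5))
        assert len(design.blocks["time"]) == 25

    def test_minimal_model(self):
        data = _daily_frame(400)
        spec = tl.ModelSpec(var_df=2, lag_df=2, max_lag=7, dow=False,
                            humidity_df=0, dewpoint_df=0, time_df_per_year=1 / 400)
        design = assemble_design(data, spec)
        # intercept + cross-basis + the 1-df floor of the time spline
        assert design.X.shape[1] == 1 + 4 + 1

    def test_mask_excludes_lag_incomplete_rows(self):
        design = assemble_design(_daily_frame(400), tl.ModelSpec(max_lag=28))
        assert not design.mask[:28].any()
        assert design.n_used == 400 - 28

    def test_missing_column_and_bad_counts(self):
        data = _daily_frame(100)
        with pytest.raises(ValueError, match="missing required"):
            assemble_design(data.drop(columns=["humidity"]), tl.ModelSpec())
        bad = data.assign(deaths_all=data["deaths_all"] + 0.5)
        with pytest.raises(ValueError, match="integer"):
            assemble_design(bad, tl.ModelSpec(max_lag=7))


class TestFit:
    def test_constant_counts_poisson_limit(self):
        data = _daily_frame(200, counts=np.full(200, 3))
        spec = tl.ModelSpec(var_df=1, lag_df=1, max_lag=0, dow=False,
                            humidity_df=0, dewpoint_df=0, time_df_per_year=1 / 200)
        design = assemble_design(data, spec)
        # intercept-only comparison: strip covariates
        design = dataclasses.replace(design, X=design.X[:, :1], column_names=["intercept"],
                                     blocks={"intercept": np.array([0]),
                                             "crossbasis": np.array([], dtype=int)})
        model = fit_negbin(design)
        assert np.exp(model.coefficients["intercept"]) == pytest.approx(3.0, abs=1e-8)
        assert np.isinf(model.dispersion)

    def test_all_zero_response_errors(self):
        data = _daily_frame(100, counts=np.zeros(100, dtype=int))
        with pytest.raises(FitError, match="zero"):
            tl.fit_model(data, tl.ModelSpec(max_lag=7, var_df=2, lag_df=2,
                                            time_df_per_year=2))

    def test_coefficient_recovery_across_replicates(self):
        """Known linear predictor, theta=10, n=3000: truth within 3 SE >= 95%."""
        n, theta = 3000, 10.0
        beta = np.array([np.log(3.0), 0.25, -0.15, 0.1])
        hits = []
        for seed in range(1, 101):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, 3))])
            mu = np.exp(X @ beta)
            y = rng.negative_binomial(theta, theta / (theta + mu))
            design = DesignInfo(X, y.astype(float), np.ones(n, bool),
                                ["intercept", "x1", "x2", "x3"],
                                {"intercept": np.array([0]),
                                 "crossbasis": np.array([], dtype=int)},
                                None, None, {})
            m = fit_negbin(design)
            se = np.sqrt(np.diag(m.vcov.to_numpy()))
            hits.append(bool(np.all(np.abs(m.coefficients.to_numpy() - beta) <= 3 * se)))
        assert np.mean(hits) >= 0.95

    def test_aic_matches_pmf_summation_oracle(self, small_model):
        theta = small_model.dispersion
        mu = small_model.fitted_mean
        y = small_model.response
        # independent oracle: scipy nbinom pmf term by term
        llf = stats.nbinom.logpmf(y, theta, theta / (theta + mu)).sum()
        k = len(small_model.coefficients) + 1
        assert small_model.aic == pytest.approx(-2 * llf + 2 * k, abs=1e-6)

    def test_parameterization_invariance(self, sim_data, small_spec, small_model):
        """An invertible affine recombination of a spline block leaves the fit alone."""
        design = assemble_design(sim_data, small_spec)
        X2 = design.X.copy()
        idx = design.blocks["time"]
        rng = np.random.default_rng(9)
        A = rng.normal(size=(len(idx), len(idx))) + 3 * np.eye(len(idx))
        X2[:, idx] = X2[:, idx] @ A
        m2 = fit_negbin(dataclasses.replace(design, X=X2))
        assert m2.aic == pytest.approx(small_model.aic, abs=1e-4)
        assert np.max(np.abs(m2.fitted_mean - small_model.fitted_mean)) < 1e-4

    def test_poisson_data_approaches_poisson_coefficients(self):
        rng = np.random.default_rng(12)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, 2))])
        beta = np.array([1.0, 0.3, -0.2])
        y = rng.poisson(np.exp(X @ beta))
        design = DesignInfo(X, y.astype(float), np.ones(n, bool), ["b0", "b1", "b2"],
                            {"intercept": np.array([0]),
                             "crossbasis": np.array([], dtype=int)}, None, None, {})
        m = fit_negbin(design)
        import statsmodels.api as sm
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.max(np.abs(m.coefficients.to_numpy() - pois.params)) < 1e-3

    def test_aic_prefers_true_term(self):
        """Adding the data-generating covariate lowers the AIC in >= 90% of runs."""
        n = 3000
        wins = []
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, n)
            mu = np.exp(1.0 + 0.3 * x)
            theta = 8.0
            y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
            blocks = {"intercept": np.array([0]), "crossbasis": np.array([], dtype=int)}
            d0 = DesignInfo(np.ones((n, 1)), y, np.ones(n, bool), ["b0"], blocks,
                            None, None, {})
            d1 = DesignInfo(np.column_stack([np.ones(n), x]), y, np.ones(n, bool),
                            ["b0", "b1"], blocks, None, None, {})
            wins.append(fit_negbin(d1).aic <= fit_negbin(d0).aic)
        assert np.mean(wins) >= 0.9


class TestDiagnostics:
    def test_self_consistency_dispersion_ratio(self):
        rng = np.random.default_rng(21)
        n, theta = 3000, 6.0
        X = np.column_stack([np.ones(n), rng.normal(0, 0.5, n)])
        mu = np.exp(X @ np.array([1.2, 0.3]))
        y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
        design = DesignInfo(X, y, np.ones(n, bool), ["b0", "b1"],
                            {"intercept": np.array([0]),
                             "crossbasis": np.array([], dtype=int)}, None, None, {})
        report = diagnostics(fit_negbin(design))
        assert 0.8 <= report.dispersion_ratio <= 1.2

    def test_white_noise_acf_within_bands(self):
        """Structureless counts: >= 28 of 30 autocorrelations inside +/-2/sqrt(n),
        required for the majority of independent datasets."""
        n = 2000
        good = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.poisson(3.0, n).astype(float)
            design = DesignInfo(np.ones((n, 1)), y, np.ones(n, bool), ["b0"],
                                {"intercept": np.array([0]),
                                 "crossbasis": np.array([], dtype=int)}, None, None, {})
            report = diagnostics(fit_negbin(design))
            assert len(report.pearson_residuals) == n
            good += (np.abs(report.residual_acf) > 2 / np.sqrt(n)).sum() <= 2
        assert good >= 6

    def test_residual_count_is_n_used(self, small_model):
        report = diagnostics(small_model)
        assert len(report.pearson_residuals) == small_model.n_used
        assert len(report.deviance_residuals) == small_model.n_used


class TestEstimator:
    def test_sklearn_interface(self, sim_data):
        est = tl.NegativeBinomialDLNM(var_df=3, lag_df=3, max_lag=10,
                                      time_df_per_year=4, humidity_df=2, dewpoint_df=2)
        est.fit(sim_data)
        assert est.aic_ == est.result_.aic
        assert est.n_used_ == len(sim_data) - 10
        fitted = est.predict()
        assert np.isnan(fitted[:10]).all()
        assert np.nanmax(fitted) < 50
        params = est.get_params()
        assert params["var_df"] == 3
        clone_pred = est.predict(sim_data)
        # rebuilt design with stored knots reproduces in-sample fitted means
        assert np.allclose(fitted[10:], clone_pred[10:], rtol=1e-10)

    def test_nb2_loglik_poisson_branch(self):
        y = np.array([0, 1, 2, 3])
        mu = np.full(4, 1.5)
        expected = stats.poisson.logpmf(y, mu).sum()
        assert _nb2_loglik(y, mu, np.inf) == pytest.approx(expected, abs=1e-10)
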