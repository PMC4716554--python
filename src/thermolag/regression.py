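"""Negative binomial regression for daily death counts with a DLNM cross-basis.

The model for the daily count Y_t is

    Y_t ~ NegBin2(mu_t, theta),   Var(Y_t) = mu_t + mu_t^2 / theta
    log mu_t = alpha + crossbasis(temp)_t . beta_cb + dow_t . beta_dow
               + NCS(t; time_df) . beta_time + NCS(RH_t; 3) . beta_rh
               + NCS(dewpoint_t; 3) . beta_dp

i.e. a log-linear count regression where the temperature term is the
cross-basis of a distributed lag non-linear model, day-of-week indicators
absorb weekly structure, a natural cubic spline in the day index absorbs
seasonality and long-term trend, and humidity / dew point splines absorb
weather confounding.  The NB2 dispersion theta is estimated jointly with
the coefficients by maximum likelihood; as theta -> infinity the model
approaches the Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special
from sklearn.base import BaseEstimator

from .crossbasis import CrossBasis, CrossBasisSpec, LagStructure, build_crossbasis
from .splines import KnotSpec, _basis_values, place_knots, place_knots_even

__all__ = ["ModelSpec", "FittedModel", "DesignInfo", "assemble_design", "fit_negbin",
           "fit_model", "diagnostics", "NegativeBinomialDLNM", "INDICATOR_COLUMNS"]

INDICATOR_COLUMNS = {"maximum": "tmax", "average": "tavg", "minimum": "tmin"}

_DOW_LEVELS = ["Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]  # reference: Monday


@dataclass(frozen=True)
class ModelSpec:
    """Full specification of one temperature-mortality model.

    Defaults reproduce the final all-cause configuration of the Hue analysis:
    average temperature, a 4 df (temperature) x 5 df (lag) NCS-NCS cross-basis
    with maximum lag 28, 5 df per year of time spline, and 3 df splines for
    relative humidity and dew point.
    """

    temperature_indicator: str = "average"
    var_df: int = 4
    lag_df: int = 5
    max_lag: int = 28
    time_df_per_year: float = 5.0
    humidity_df: int = 3
    dewpoint_df: int = 3
    dow: bool = True
    lag_intercept: bool = True
    var_knots: KnotSpec | None = None
    lag_knots: KnotSpec | None = None

    def __post_init__(self):
        if self.temperature_indicator not in INDICATOR_COLUMNS:
            raise ValueError(f"temperature_indicator must be one of {sorted(INDICATOR_COLUMNS)}")
        if self.var_df < 1 or self.lag_df < 1:
            raise ValueError("cross-basis dfs must be >= 1")
        if self.humidity_df < 0 or self.dewpoint_df < 0:
            raise ValueError("confounder dfs must be >= 0 (0 disables the term)")
        if self.time_df_per_year <= 0:
            raise ValueError("time_df_per_year must be positive")

    def time_df(self, n_days: int) -> int:
        """Total time-spline df: time_df_per_year x length of the series in years."""
        return max(1, round(self.time_df_per_year * n_days / 365.25))


def hue2016() -> ModelSpec:
    """The final all-cause model configuration selected in the Hue study."""
    return ModelSpec()


@dataclass
class DesignInfo:
    """Assembled design: matrix, response, complete-case mask and column bookkeeping."""

    X: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    column_names: list[str]
    blocks: dict[str, np.ndarray]
    crossbasis: CrossBasis
    spec: ModelSpec
    resolved: dict[str, object]

    @property
    def n_used(self) -> int:
        return int(self.mask.sum())


@dataclass
class FittedModel:
    """One fitted negative binomial DLNM."""

    coefficients: pd.Series
    vcov: pd.DataFrame
    dispersion: float          # NB2 theta; inf marks the Poisson limit
    loglik: float
    aic: float
    n_used: int
    spec: ModelSpec
    crossbasis: CrossBasis
    blocks: dict[str, np.ndarray]
    fitted_mean: np.ndarray    # on used rows, in series order
    response: np.ndarray       # used response values
    exposure_used: np.ndarray  # temperature series on used rows (percentile basis)
    converged: bool = True

    @property
    def cb_coefficients(self) -> np.ndarray:
        return self.coefficients.to_numpy()[self.blocks["crossbasis"]]

    @property
    def cb_vcov(self) -> np.ndarray:
        idx = self.blocks["crossbasis"]
        return self.vcov.to_numpy()[np.ix_(idx, idx)]


def _require_columns(data: pd.DataFrame, cols):
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")


def assemble_design(data: pd.DataFrame, spec: ModelSpec, outcome: str = "deaths_all") -> DesignInfo:
    """Build the regression design for a daily series.

    The mask excludes rows whose lag window is incomplete and rows with any
    missing covariate or count; rows are flagged, never dropped, so that the
    design stays aligned with the input series.
    """
    temp_col = INDICATOR_COLUMNS[spec.temperature_indicator]
    needed = ["date", temp_col, outcome]
    if spec.humidity_df:
        needed.append("humidity")
    if spec.dewpoint_df:
        needed.append("dewpoint")
    _require_columns(data, needed)

    y_raw = pd.to_numeric(data[outcome], errors="coerce").to_numpy(dtype=float)
    finite_y = np.isfinite(y_raw)
    vals = y_raw[finite_y]
    if ((vals < 0) | (vals != np.round(vals))).any():
        raise ValueError(f"outcome '{outcome}' must contain non-negative integer counts")

    temps = data[temp_col].to_numpy(dtype=float)
    n = len(data)
    dates = pd.DatetimeIndex(pd.to_datetime(data["date"]))

    finite_temp = temps[np.isfinite(temps)]
    var_knots = spec.var_knots or place_knots(finite_temp, spec.var_df)
    if spec.lag_knots is not None:
        lag_knots = spec.lag_knots
    else:
        spline_df = spec.lag_df - 1 if spec.lag_intercept else spec.lag_df
        lag_knots = place_knots_even(0, spec.max_lag, spline_df) if spline_df >= 1 else None
    cb_spec = CrossBasisSpec(var_knots, LagStructure(spec.max_lag), lag_knots, spec.lag_intercept)
    cb = build_crossbasis(temps, cb_spec, dates)

    names = ["intercept"]
    cols = [np.ones(n)]
    blocks: dict[str, np.ndarray] = {"intercept": np.array([0])}
    start = 1

    J, K = cb_spec.var_df, cb_spec.lag_df
    names += [f"cb_v{j + 1}l{k + 1}" for j in range(J) for k in range(K)]
    cols.append(cb.matrix)
    blocks["crossbasis"] = np.arange(start, start + J * K)
    start += J * K

    if spec.dow:
        wd = dates.dayofweek.to_numpy()  # Monday = 0
        dow_mat = np.column_stack([(wd == i + 1).astype(float) for i in range(6)])
        names += [f"dow_{d}" for d in _DOW_LEVELS]
        cols.append(dow_mat)
        blocks["dow"] = np.arange(start, start + 6)
        start += 6

    time_index = np.arange(1, n + 1, dtype=float)
    tdf = spec.time_df(n)
    time_knots = place_knots(time_index, tdf)
    time_mat = _basis_values(time_index, time_knots)
    names += [f"time_{i + 1}" for i in range(tdf)]
    cols.append(time_mat)
    blocks["time"] = np.arange(start, start + tdf)
    start += tdf

    resolved = {"var_knots": var_knots, "lag_knots": lag_knots, "time_knots": time_knots,
                "time_df": tdf}
    covariate_ok = np.ones(n, dtype=bool)
    for label, df_ in (("humidity", spec.humidity_df), ("dewpoint", spec.dewpoint_df)):
        if not df_:
            continue
        v = data[label].to_numpy(dtype=float)
        ok = np.isfinite(v)
        covariate_ok &= ok
        knots = place_knots(v[ok], df_)
        mat = _basis_values(v, knots)
        names += [f"{label}_{i + 1}" for i in range(df_)]
        cols.append(mat)
        blocks[label] = np.arange(start, start + df_)
        start += df_
        resolved[f"{label}_knots"] = knots

    X = np.column_stack(cols)
    mask = cb.complete & covariate_ok & finite_y
    return DesignInfo(X, y_raw, mask, names, blocks, cb, spec, resolved)


class FitError(RuntimeError):
    """Raised when the likelihood optimization fails; carries the trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


def fit_negbin(design: DesignInfo, theta_floor: float = 1e-6) -> FittedModel:
    """Maximize the NB2 likelihood jointly over coefficients and dispersion.

    A Poisson GLM supplies starting values; when the estimated overdispersion
    collapses to zero (alpha below ``theta_floor``) the fit degrades
    gracefully to the Poisson limit with ``dispersion = inf``.  The AIC is
    -2 loglik + 2 (n_coefficients + 1), the +1 counting the dispersion
    parameter in every model so that comparisons are consistent.
    """
    mask = design.mask
    X = design.X[mask]
    y = design.y[mask].astype(int)
    if y.size == 0:
        raise FitError("no complete rows to fit")
    if (y == 0).all():
        raise FitError("degenerate response: all counts are zero")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(f"design is rank deficient ({rank} < {X.shape[1]}); "
                      "estimates of aliased coefficients are not unique")

    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu0 = np.clip(pois.fittedvalues, 1e-10, None)
    alpha0 = float(((y - mu0) ** 2 - mu0).sum() / (mu0 ** 2).sum())
    trace.append(("poisson_start", float(pois.llf)))

    res = None
    if alpha0 > theta_floor:
        start = np.r_[pois.params, max(alpha0, 1e-3)]
        for method in ("newton", "bfgs", "lbfgs"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cand = sm.NegativeBinomial(y, X).fit(
                        start_params=start, method=method, maxiter=300, disp=0)
                trace.append((method, float(cand.llf)))
                if cand.mle_retvals.get("converged", False) and np.isfinite(cand.llf):
                    res = cand
                    break
            except Exception as exc:  # singular hessian, line-search failure, ...
                trace.append((method, f"failed: {exc}"))
    if res is not None and res.params[-1] > theta_floor:
        params = res.params[:-1]
        theta = 1.0 / float(res.params[-1])
        llf = float(res.llf)
        vcov_full = np.asarray(res.cov_params())
        vcov = vcov_full[:-1, :-1]
        converged = True
    else:
        # Poisson limit: no evidence of overdispersion (or boundary estimate)
        params = np.asarray(pois.params)
        theta = np.inf
        llf = float(pois.llf)
        vcov = np.asarray(pois.cov_params())
        converged = True
        if res is None and alpha0 > theta_floor:
            raise FitError("negative binomial optimization did not converge", trace)

    k = len(params) + 1  # + dispersion
    aic = -2.0 * llf + 2.0 * k
    names = design.column_names
    coef = pd.Series(params, index=names)
    vcov_df = pd.DataFrame(vcov, index=names, columns=names)
    mu = np.exp(X @ params)
    exposure_used = (design.crossbasis.exposure[mask] if design.crossbasis is not None
                     else np.array([]))
    return FittedModel(coef, vcov_df, theta, llf, aic, int(mask.sum()), design.spec,
                       design.crossbasis, design.blocks, mu, y, exposure_used, converged)


def fit_model(data: pd.DataFrame, spec: ModelSpec | None = None,
              outcome: str = "deaths_all") -> FittedModel:
    """Assemble the design for ``spec`` (default: the Hue final model) and fit."""
    return fit_negbin(assemble_design(data, spec or ModelSpec(), outcome))


def _nb2_loglik(y, mu, theta) -> float:
    """NB2 log-likelihood summed term by term (Poisson when theta is inf)."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if not np.isfinite(theta):
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu)) + y * np.log(mu / (theta + mu))))


@dataclass
class DiagnosticReport:
    pearson_residuals: np.ndarray
    deviance_residuals: np.ndarray
    residual_acf: np.ndarray        # lags 1..30
    dispersion_ratio: float         # sum r_P^2 / (n - p)

    def summary(self) -> str:
        bands = 2 / np.sqrt(len(self.pearson_residuals))
        n_out = int((np.abs(self.residual_acf) > bands).sum())
        return (f"dispersion ratio {self.dispersion_ratio:.3f}; "
                f"{n_out}/30 residual autocorrelations outside +/-{bands:.3f}")


def diagnostics(model: FittedModel, max_acf_lag: int = 30) -> DiagnosticReport:
    """Residual diagnostics of a fitted model.

    Pearson residuals use the NB2 variance mu + mu^2/theta; the dispersion
    ratio should sit near 1 for a well specified model.
    """
    from statsmodels.tsa.stattools import acf

    y, mu, theta = model.response.astype(float), model.fitted_mean, model.dispersion
    var = mu + (0.0 if not np.isfinite(theta) else mu ** 2 / theta)
    pearson = (y - mu) / np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        if np.isfinite(theta):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
            term2 = (y + theta) * np.log((y + theta) / (mu + theta))
            dev2 = 2 * (term - term2)
        else:
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
            dev2 = 2 * (term - (y - mu))
    deviance = np.sign(y - mu) * np.sqrt(np.clip(dev2, 0, None))
    rho = acf(pearson, nlags=max_acf_lag, fft=True)[1:]
    p = len(model.coefficients)
    ratio = float((pearson ** 2).sum() / max(model.n_used - p, 1))
    return DiagnosticReport(pearson, deviance, rho, ratio)


class NegativeBinomialDLNM(BaseEstimator):
    """scikit-learn style estimator wrapping the full DLNM count regression.

    Parameters mirror :class:`ModelSpec`; ``fit`` takes the daily series
    DataFrame (date, temperature indicators, humidity, dewpoint and count
    columns) and estimates coefficients and NB2 dispersion by maximum
    likelihood.

    Attributes
    ----------
    result_ : FittedModel
    coef_ : pd.Series
    aic_, dispersion_, n_used_ : floats / int
    """

    def __init__(self, temperature_indicator: str = "average", var_df: int = 4,
                 lag_df: int = 5, max_lag: int = 28, time_df_per_year: float = 5.0,
                 humidity_df: int = 3, dewpoint_df: int = 3, dow: bool = True,
                 lag_intercept: bool = True, outcome: str = "deaths_all"):
        self.temperature_indicator = temperature_indicator
        self.var_df = var_df
        self.lag_df = lag_df
        self.max_lag = max_lag
        self.time_df_per_year = time_df_per_year
        self.humidity_df = humidity_df
        self.dewpoint_df = dewpoint_df
        self.dow = dow
        self.lag_intercept = lag_intercept
        self.outcome = outcome

    def _spec(self) -> ModelSpec:
        return ModelSpec(self.temperature_indicator, self.var_df, self.lag_df,
                         self.max_lag, self.time_df_per_year, self.humidity_df,
                         self.dewpoint_df, self.dow, self.lag_intercept)

    def fit(self, X: pd.DataFrame, y=None):
        design = assemble_design(X, self._spec(), self.outcome)
        self.result_ = fit_negbin(design)
        self.design_ = design
        self.coef_ = self.result_.coefficients
        self.vcov_ = self.result_.vcov
        self.dispersion_ = self.result_.dispersion
        self.aic_ = self.result_.aic
        self.n_used_ = self.result_.n_used
        return self

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        """Expected daily counts; NaN on rows excluded from the fit.

        With ``X=None`` returns in-sample fitted means aligned to the
        training series.
        """
        if not hasattr(self, "result_"):
            raise ValueError("NegativeBinomialDLNM is not fitted")
        if X is None:
            design = self.design_
            out = np.full(len(design.mask), np.nan)
            out[design.mask] = self.result_.fitted_mean
            return out
        spec = replace(self._spec(), var_knots=self.design_.resolved["var_knots"],
                       lag_knots=self.design_.resolved["lag_knots"])
        design = assemble_design(X, spec, self.outcome)
        params = self.coef_.to_numpy()
        out = np.full(len(design.mask), np.nan)
        out[design.mask] = np.exp(design.X[design.mask] @ params)
        return out

    def score(self, X: pd.DataFrame, y=None) -> float:
        """NB2 log-likelihood of the fitted parameters on the design of ``X``."""
        mu = self.predict(X)
        yv = pd.to_numeric(X[self.outcome], errors="coerce").to_numpy(float)
        ok = np.isfinite(mu) & np.isfinite(yv)
        return _nb2_loglik(yv[ok], mu[ok], self.dispersion_)
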