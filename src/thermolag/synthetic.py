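"""Synthetic daily weather and mortality series with a known true surface.

The generator is a data-generating analogue of the regression model: daily
average temperature follows an annual sinusoid plus AR(1) noise (calibrated
so the marginal mean/SD match the observed Hue climate: mean 25.7 degC, SD
4.1), maximum / minimum temperatures and dew point are derived with positive
seeded offsets, relative humidity follows from the dew-point depression via
the Magnus approximation, and daily death counts are NB2 draws around a log
mean driven by a known exposure-lag-response surface f(x, l), day-of-week
effects and a long-term trend.  Because f is known in closed form, every
downstream estimate has an exact truth to be compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossbasis import CrossBasisSpec
from .splines import KnotSpec

__all__ = ["TrueSurface", "CrossBasisSurface", "SimConfig", "simulate_weather",
           "simulate_mortality", "simulate_dataset", "true_cumulative_rr"]

# Magnus saturation vapour pressure constants (over water)
_MAGNUS_A, _MAGNUS_B = 17.625, 243.04

# Stratum proportions emulating the Hue death composition
STRATUM_PROPORTIONS = {
    "cause": {"external": 0.059, "cvd": 0.3564, "resp": 0.029, "cancer": 0.1728},
    "male": 0.5349,
    "age65plus": 0.655,
}


@dataclass(frozen=True)
class TrueSurface:
    """Closed-form exposure-lag-response surface f(x, l), with f(ref, l) = 0.

    ``hot_logrr`` / ``cold_logrr`` anchor the cumulative (lag 0..max_lag)
    log-RR of the hot / cold anchor temperature against the reference.
    Temperature responses are quadratic ramps above / below the reference;
    lag profiles are an exponential decay (hot), a delayed Gaussian bump
    (cold), and for the ``displacement`` shape an acute positive pulse on
    lags 0-2 followed by a compensating negative lobe on lags 3-10 of
    relative depth ``displacement_depth`` (<= 0).
    """

    shape: str = "J"
    hot_logrr: float = math.log(1.4)
    cold_logrr: float = math.log(1.8)
    hot_lag_decay: float = 4.5
    cold_lag_onset: float = 5.0
    cold_lag_decay: float = 7.0
    displacement_depth: float = -0.6
    ref_temp: float = 26.3
    hot_anchor: float = 32.4
    cold_anchor: float = 15.8
    max_lag: int = 28

    _SHAPES = ("null", "linear", "J", "U", "L", "displacement")

    def __post_init__(self):
        if self.shape not in self._SHAPES:
            raise ValueError(f"shape must be one of {self._SHAPES}")
        if self.displacement_depth > 0:
            raise ValueError("displacement_depth must be <= 0")

    # -- lag profiles, each normalized to sum 1 over lags 0..max_lag --
    def _w_hot(self) -> np.ndarray:
        l = np.arange(self.max_lag + 1, dtype=float)
        w = np.exp(-l / self.hot_lag_decay)
        return w / w.sum()

    def _w_cold(self) -> np.ndarray:
        l = np.arange(self.max_lag + 1, dtype=float)
        w = np.exp(-0.5 * ((l - self.cold_lag_onset) / self.cold_lag_decay) ** 2)
        return w / w.sum()

    def _w_displacement(self) -> np.ndarray:
        l = np.arange(self.max_lag + 1, dtype=float)
        acute = np.where(l <= 2, np.exp(-l / self.hot_lag_decay), 0.0)
        acute /= acute.sum()
        rebound = np.where((l >= 3) & (l <= 10), np.exp(-0.5 * ((l - 6.0) / 2.0) ** 2), 0.0)
        rebound /= rebound.sum()
        return acute + self.displacement_depth * rebound

    # -- temperature responses, 0 at the reference, 1 at the anchor --
    def _g_hot(self, x) -> np.ndarray:
        u = np.maximum(np.asarray(x, float) - self.ref_temp, 0.0)
        return (u / (self.hot_anchor - self.ref_temp)) ** 2

    def _g_cold(self, x) -> np.ndarray:
        u = np.maximum(self.ref_temp - np.asarray(x, float), 0.0)
        return (u / (self.ref_temp - self.cold_anchor)) ** 2

    def loglag(self, x, l) -> np.ndarray:
        """f(x, l): contribution of exposure x at lag l to the daily log-rate."""
        x = np.asarray(x, dtype=float)
        l = np.asarray(l)
        if self.shape == "null":
            return np.zeros(np.broadcast(x, l).shape)
        hot = np.zeros(np.broadcast(x, l).shape)
        cold = np.zeros_like(hot)
        if self.shape == "linear":
            ramp = (x - self.ref_temp) / (self.hot_anchor - self.ref_temp)
            return self.hot_logrr * ramp * self._w_hot()[l]
        if self.shape == "displacement":
            hot = self.hot_logrr * self._g_hot(x) * self._w_displacement()[l]
            return hot
        if self.shape in ("J", "U"):
            hot = self.hot_logrr * self._g_hot(x) * self._w_hot()[l]
        if self.shape in ("L", "U"):
            cold = self.cold_logrr * self._g_cold(x) * self._w_cold()[l]
        return hot + cold

    def lag_contributions(self, x) -> np.ndarray:
        """Matrix f(x_i, l) for all lags, shape (len(x), max_lag + 1)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lags = np.arange(self.max_lag + 1)
        return np.stack([self.loglag(x, np.full(x.shape, l, int)) for l in lags], axis=1)


@dataclass(frozen=True)
class CrossBasisSurface:
    """True surface lying exactly in the span of an NCS-NCS cross-basis.

    f(x, l) = sum_{j,k} coef[j, k] VarBasis(x)_j LagBasis(l)_k, shifted so
    f(ref_temp, l) = 0 for every lag.  Used to study how model selection
    recovers the dimensionality of the generating basis.
    """

    spec: CrossBasisSpec
    coef: tuple  # (var_df, lag_df) nested tuples
    ref_temp: float = 26.3

    @property
    def max_lag(self) -> int:
        return self.spec.lag.max_lag

    def _coef(self) -> np.ndarray:
        c = np.asarray(self.coef, dtype=float)
        if c.shape != (self.spec.var_df, self.spec.lag_df):
            raise ValueError(f"coef shape {c.shape} != {(self.spec.var_df, self.spec.lag_df)}")
        return c

    def loglag(self, x, l) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        l = np.atleast_1d(np.asarray(l, dtype=int))
        vb = self.spec.var_basis_matrix(x) - self.spec.var_basis_matrix([self.ref_temp])
        lb = self.spec.lag_basis_matrix()[l]
        out = np.einsum("nj,jk,nk->n", vb, self._coef(), lb)
        return out if out.shape else float(out)

    def lag_contributions(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        vb = self.spec.var_basis_matrix(x) - self.spec.var_basis_matrix([self.ref_temp])
        return vb @ self._coef() @ self.spec.lag_basis_matrix().T


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the simulator (Hue 2009-2013 structure).

    The AR(1) innovation variance is derived from ``temp_sd`` and
    ``seasonal_amplitude`` so the marginal temperature SD matches ``temp_sd``
    by construction; ``seasonal_amplitude`` must satisfy A^2/2 < temp_sd^2.
    """

    n_years: float = 5.0
    start_date: str = "2009-01-01"
    temp_mean: float = 25.7
    temp_sd: float = 4.1
    seasonal_amplitude: float = 4.6
    ar1: float = 0.7
    peak_doy: float = 190.0           # warmest around early July
    tmax_offset_mean: float = 4.2     # Table-1 style spreads of the indicators
    tmax_offset_sd: float = 1.5
    tmin_offset_mean: float = 4.0
    tmin_offset_sd: float = 1.2
    dewpoint_depression_mean: float = 3.6
    dewpoint_depression_sd: float = 1.5
    baseline_daily_deaths: float = 3.4
    nb_theta: float = 8.0
    dow_effects: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.03, 0.03)  # Monday-first log effects
    trend_slope: float = 0.0          # per-year change in the log rate
    seed: int | None = None

    def __post_init__(self):
        if self.seasonal_amplitude ** 2 / 2 > self.temp_sd ** 2:
            raise ValueError("seasonal_amplitude too large for the requested marginal SD")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must be in [0, 1)")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Monday first)")

    @property
    def n_days(self) -> int:
        return round(365.25 * self.n_years)


def _rng(config: SimConfig, seed) -> np.random.Generator:
    if seed is None:
        seed = config.seed
    return np.random.default_rng(seed)


def simulate_weather(config: SimConfig = SimConfig(), seed: int | None = None) -> pd.DataFrame:
    """Daily weather series: date, tmax, tavg, tmin, dewpoint, humidity."""
    rng = _rng(config, seed)
    n = config.n_days
    dates = pd.date_range(config.start_date, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    seasonal = config.seasonal_amplitude * np.cos(2 * np.pi * (doy - config.peak_doy) / 365.25)
    noise_var = config.temp_sd ** 2 - config.seasonal_amplitude ** 2 / 2
    innov_sd = math.sqrt(noise_var * (1 - config.ar1 ** 2))
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, math.sqrt(noise_var))
    shocks = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        eps[t] = config.ar1 * eps[t - 1] + shocks[t]
    tavg = config.temp_mean + seasonal + eps

    def _gamma(mean, sd):
        shape = (mean / sd) ** 2
        return rng.gamma(shape, mean / shape, size=n)

    tmax = tavg + _gamma(config.tmax_offset_mean, config.tmax_offset_sd)
    tmin = tavg - _gamma(config.tmin_offset_mean, config.tmin_offset_sd)

    # dew-point depression larger in the dry season (Mar-Aug), smaller Sep-Jan
    season_factor = 1 + 0.35 * np.cos(2 * np.pi * (doy - 150.0) / 365.25)
    depression = np.maximum(_gamma(config.dewpoint_depression_mean,
                                   config.dewpoint_depression_sd) * season_factor, 0.05)
    dewpoint = tavg - depression

    def _sat(t):
        return np.exp(_MAGNUS_A * t / (_MAGNUS_B + t))

    humidity = np.clip(100.0 * _sat(dewpoint) / _sat(tavg), 1e-6, 100.0)
    return pd.DataFrame({"date": dates, "tmax": tmax, "tavg": tavg, "tmin": tmin,
                         "dewpoint": dewpoint, "humidity": humidity})


def _surface_linpred(tavg: np.ndarray, surface) -> np.ndarray:
    """sum_l f(x_{t-l}, l); unavailable leading lags contribute 0 (reference level)."""
    n = len(tavg)
    contrib = surface.lag_contributions(tavg)  # (n, L+1)
    L = contrib.shape[1] - 1
    lin = np.zeros(n)
    for l in range(L + 1):
        lin[l:] += contrib[: n - l, l]
    return lin


def simulate_mortality(weather: pd.DataFrame, surface, config: SimConfig = SimConfig(),
                       seed: int | None = None, stratify: bool = False) -> pd.DataFrame:
    """Append NB2 death counts driven by ``surface`` to a weather frame.

    With ``stratify=True`` each day's count is split by multinomial thinning
    into cause, sex and age strata (each partition sums to the all-cause
    count by construction).
    """
    rng = _rng(config, seed)
    tavg = weather["tavg"].to_numpy(dtype=float)
    n = len(tavg)
    dates = pd.DatetimeIndex(weather["date"])
    lin = _surface_linpred(tavg, surface)
    dow = np.asarray(config.dow_effects, dtype=float)[dates.dayofweek.to_numpy()]
    years = np.arange(n) / 365.25
    log_mu = math.log(config.baseline_daily_deaths) + lin + dow + config.trend_slope * years
    if (log_mu > 20).any():
        raise ValueError("surface produces overflowing expected counts")
    mu = np.exp(log_mu)
    theta = config.nb_theta
    y = rng.negative_binomial(theta, theta / (theta + mu), size=n)

    out = weather.copy()
    out["deaths_all"] = y
    if stratify:
        p = STRATUM_PROPORTIONS["cause"]
        other = 1.0 - sum(p.values())
        probs = np.array([p["external"], p["cvd"], p["resp"], p["cancer"], other])
        cause = np.stack([rng.multinomial(k, probs) for k in y])
        out["deaths_external"] = cause[:, 0]
        out["deaths_cvd"] = cause[:, 1]
        out["deaths_resp"] = cause[:, 2]
        out["deaths_cancer"] = cause[:, 3]
        out["deaths_nonext"] = y - cause[:, 0]
        male = rng.binomial(y, STRATUM_PROPORTIONS["male"])
        out["deaths_male"] = male
        out["deaths_female"] = y - male
        old = rng.binomial(y, STRATUM_PROPORTIONS["age65plus"])
        out["deaths_65plus"] = old
        out["deaths_0_64"] = y - old
    return out


def simulate_dataset(surface=None, config: SimConfig = SimConfig(),
                     seed: int | None = None, stratify: bool = False) -> pd.DataFrame:
    """Weather plus mortality in one call (``surface=None`` means no temperature effect)."""
    if surface is None:
        surface = TrueSurface(shape="null")
    rng = _rng(config, seed)
    w_seed, m_seed = rng.integers(0, 2 ** 31 - 1, size=2)
    weather = simulate_weather(config, seed=int(w_seed))
    return simulate_mortality(weather, surface, config, seed=int(m_seed), stratify=stratify)


def true_cumulative_rr(surface, at_temp: float, ref_temp: float,
                       lag_window: tuple[int, int]) -> float:
    """Exact cumulative RR of the surface: exp(sum_{l in window} [f(at,l) - f(ref,l)])."""
    l0, l1 = int(lag_window[0]), int(lag_window[1])
    if not (0 <= l0 <= l1 <= surface.max_lag):
        raise ValueError(f"lag window {lag_window} outside [0, {surface.max_lag}]")
    lags = np.arange(l0, l1 + 1)
    at = surface.loglag(np.full(lags.shape, at_temp), lags)
    ref = surface.loglag(np.full(lags.shape, ref_temp), lags)
    return float(np.exp(np.sum(at) - np.sum(ref)))
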