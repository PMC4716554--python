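"""Relative risks from a fitted DLNM.

All effects are contrasts of the fitted exposure-lag-response surface
f(x, l) = sum_{j,k} beta_jk VarBasis(x)_j LagBasis(l)_k against a reference
temperature, exponentiated to the relative risk (RR) scale:

    log RR(at vs ref; window) = sum_{l in window} [f(at, l) - f(ref, l)]

The log-RR is a linear form c'beta in the cross-basis coefficients, so its
variance is c' V c by the delta method and 95% confidence intervals are
Wald intervals on the log scale.

Conventions follow the source analysis: the reference is the median of the
analyzed temperature series, the "high temperature effect" contrasts the
99th percentile against the median cumulated over lags 0-2, and the "low
temperature effect" the 1st percentile against the median over lags 0-28.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossbasis import CrossBasis
from .regression import FittedModel

__all__ = ["TemperatureContrast", "EffectCurve", "LagCurve", "contrast_vector",
           "cumulative_rr", "overall_curve", "lag_structure", "percentile_effects"]


@dataclass(frozen=True)
class TemperatureContrast:
    """A pair of temperatures whose fitted risks are compared (RR = at vs ref)."""

    at_temp: float
    ref_temp: float


@dataclass
class EffectCurve:
    """Cumulative RR over a lag window across a temperature grid."""

    temps: np.ndarray
    rr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    lag_window: tuple[int, int]
    ref_temp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temp": self.temps, "rr": self.rr,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


@dataclass
class LagCurve:
    """Single-lag RRs at a fixed temperature contrast."""

    lags: np.ndarray
    rr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    contrast: TemperatureContrast

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "rr": self.rr,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def _check_window(window, max_lag):
    l0, l1 = int(window[0]), int(window[1])
    if not (0 <= l0 <= l1 <= max_lag):
        raise ValueError(f"lag window {window} outside [0, {max_lag}]")
    return l0, l1


def contrast_vector(crossbasis: CrossBasis, contrast: TemperatureContrast,
                    lag_window: tuple[int, int]) -> np.ndarray:
    """Vector c with c'beta_cb = log RR of ``contrast`` cumulated over ``lag_window``."""
    spec = crossbasis.spec
    l0, l1 = _check_window(lag_window, spec.lag.max_lag)
    vb = spec.var_basis_matrix(np.array([contrast.at_temp, contrast.ref_temp]))
    dv = vb[0] - vb[1]                               # (var_df,)
    w = spec.lag_basis_matrix()[l0:l1 + 1].sum(axis=0)  # (lag_df,)
    return np.outer(dv, w).ravel()                   # column order j * lag_df + k


def _rr_from_contrasts(model: FittedModel, C: np.ndarray, alpha: float):
    """RR and Wald CI for each row of the contrast matrix C."""
    beta = model.cb_coefficients
    V = model.cb_vcov
    est = C @ beta
    var = np.einsum("ij,jk,ik->i", C, V, C)
    if (var < -1e-8).any():
        raise ValueError("cross-basis covariance block is not positive semi-definite")
    se = np.sqrt(np.clip(var, 0, None))
    z = stats.norm.ppf(1 - alpha / 2)
    return np.exp(est), np.exp(est - z * se), np.exp(est + z * se)


def cumulative_rr(model: FittedModel, contrast: TemperatureContrast,
                  lag_window: tuple[int, int], alpha: float = 0.05):
    """Cumulative RR over a lag window with a delta-method CI.

    Returns ``(rr, ci_low, ci_high)``.
    """
    c = contrast_vector(model.crossbasis, contrast, lag_window)
    rr, lo, hi = _rr_from_contrasts(model, c[None, :], alpha)
    return float(rr[0]), float(lo[0]), float(hi[0])


def overall_curve(model: FittedModel, temp_grid=None, ref_temp: float | None = None,
                  lag_window: tuple[int, int] | None = None,
                  alpha: float = 0.05) -> EffectCurve:
    """Cumulative overall RR curve over a temperature grid.

    Defaults: grid of 50 points spanning the analyzed temperatures, reference
    at their median, and the full lag window 0..max_lag.
    """
    spec = model.crossbasis.spec
    if lag_window is None:
        lag_window = (0, spec.lag.max_lag)
    if ref_temp is None:
        ref_temp = float(np.quantile(model.exposure_used, 0.5))
    if temp_grid is None:
        temp_grid = np.linspace(model.exposure_used.min(), model.exposure_used.max(), 50)
    temp_grid = np.asarray(temp_grid, dtype=float)
    C = np.stack([contrast_vector(model.crossbasis, TemperatureContrast(t, ref_temp),
                                  lag_window) for t in temp_grid])
    rr, lo, hi = _rr_from_contrasts(model, C, alpha)
    return EffectCurve(temp_grid, rr, lo, hi, tuple(lag_window), float(ref_temp))


def lag_structure(model: FittedModel, contrast: TemperatureContrast,
                  alpha: float = 0.05) -> LagCurve:
    """Single-lag RRs at ``contrast`` for every lag 0..max_lag."""
    max_lag = model.crossbasis.spec.lag.max_lag
    lags = np.arange(max_lag + 1)
    C = np.stack([contrast_vector(model.crossbasis, contrast, (l, l)) for l in lags])
    rr, lo, hi = _rr_from_contrasts(model, C, alpha)
    return LagCurve(lags, rr, lo, hi, contrast)


def percentile_effects(model: FittedModel, p_cold: float = 1, p_ref: float = 50,
                       p_hot: float = 99, hot_window: tuple[int, int] = (0, 2),
                       cold_window: tuple[int, int] = (0, 28),
                       alpha: float = 0.05) -> pd.DataFrame:
    """High and low temperature effects at percentile contrasts.

    Percentiles are empirical quantiles (linear interpolation) of the
    temperature series actually entering the fit.  Returns one row per
    effect with the contrast temperatures, lag window, RR and CI.
    """
    temps = np.asarray(model.exposure_used, dtype=float)
    t_cold, t_ref, t_hot = np.percentile(temps, [p_cold, p_ref, p_hot])
    rows = []
    for name, at, window, pct in (("hot", t_hot, hot_window, p_hot),
                                  ("cold", t_cold, cold_window, p_cold)):
        rr, lo, hi = cumulative_rr(model, TemperatureContrast(float(at), float(t_ref)),
                                   window, alpha)
        rows.append({"effect": name, "percentile": pct, "at_temp": float(at),
                     "ref_temp": float(t_ref), "lag_low": window[0], "lag_high": window[1],
                     "rr": rr, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
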