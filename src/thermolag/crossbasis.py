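"""Cross-basis construction for distributed lag non-linear models.

The cross-basis is the design block that lets a regression estimate a smooth
exposure-lag-response surface f(x, l): column (j, k) on day t is

    sum_{l=0..L} VarBasis(x_{t-l})_j * LagBasis(l)_k

where VarBasis spans the exposure (temperature) dimension and LagBasis spans
the lag dimension, evaluated at the integer lags 0..L.  The coefficient on
column (j, k) is the weight of the tensor-product term VarBasis_j x
LagBasis_k in the fitted surface.

By default the lag basis carries an explicit intercept column, and the
quoted lag df counts it: a 1-df lag basis is the plain intercept, under
which the cross-basis collapses to moving sums of the exposure basis.  Set
``lag_intercept=False`` for the alternative convention where all lag df go
to the spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import KnotSpec, _basis_values, place_knots, place_knots_even

__all__ = ["LagStructure", "CrossBasisSpec", "CrossBasis", "build_lag_matrix",
           "build_crossbasis", "CrossBasisTransformer"]


@dataclass(frozen=True)
class LagStructure:
    """Lag window 0..max_lag in days."""

    max_lag: int

    def __post_init__(self):
        if int(self.max_lag) != self.max_lag or self.max_lag < 0:
            raise ValueError("max_lag must be a non-negative integer")
        object.__setattr__(self, "max_lag", int(self.max_lag))

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.max_lag + 1)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Layout of a cross-basis: exposure knots, lag knots and lag window.

    ``lag_knots=None`` together with ``lag_intercept=True`` gives a pure
    intercept lag basis (a constant-in-lag, i.e. moving-sum, effect).
    ``lag_stratified=True`` replaces the lag spline by one indicator per
    integer lag (an unconstrained distributed lag model).
    """

    var_knots: KnotSpec
    lag: LagStructure
    lag_knots: KnotSpec | None = None
    lag_intercept: bool = True
    lag_stratified: bool = False

    def __post_init__(self):
        if self.lag_stratified:
            return
        if self.lag_knots is None and not self.lag_intercept:
            raise ValueError("lag basis needs either knots or an intercept")
        if self.lag_knots is not None:
            lo, hi = self.lag_knots.boundary
            if not (lo == 0 and hi == self.lag.max_lag):
                raise ValueError("lag_knots boundary must be (0, max_lag)")

    @property
    def var_df(self) -> int:
        return self.var_knots.df

    @property
    def lag_df(self) -> int:
        if self.lag_stratified:
            return self.lag.max_lag + 1
        spline = self.lag_knots.df if self.lag_knots is not None else 0
        return spline + (1 if self.lag_intercept else 0)

    @property
    def n_columns(self) -> int:
        return self.var_df * self.lag_df

    @classmethod
    def from_dfs(cls, temperatures, var_df: int = 4, lag_df: int = 5, max_lag: int = 28,
                 lag_intercept: bool = True) -> "CrossBasisSpec":
        """Place exposure knots at equally spaced quantiles of ``temperatures``
        and lag knots at equally spaced values on [0, max_lag]."""
        var_knots = place_knots(np.asarray(temperatures, float), var_df)
        lag = LagStructure(max_lag)
        spline_df = lag_df - 1 if lag_intercept else lag_df
        if spline_df < 0 or (spline_df == 0 and not lag_intercept):
            raise ValueError("lag_df must be >= 1")
        lag_knots = place_knots_even(0, max_lag, spline_df) if spline_df >= 1 else None
        return cls(var_knots, lag, lag_knots, lag_intercept)

    def lag_basis_matrix(self) -> np.ndarray:
        """Lag basis evaluated at integer lags 0..max_lag, shape (max_lag+1, lag_df)."""
        if self.lag_stratified:
            return np.eye(self.lag.max_lag + 1)
        lags = self.lag.lags.astype(float)
        cols = []
        if self.lag_intercept:
            cols.append(np.ones_like(lags))
        if self.lag_knots is not None:
            cols.append(_basis_values(lags, self.lag_knots))
        return np.column_stack(cols)

    def var_basis_matrix(self, x) -> np.ndarray:
        """Exposure basis at values ``x`` (NaN rows propagate), shape (n, var_df)."""
        return _basis_values(np.asarray(x, dtype=float).ravel(), self.var_knots)


@dataclass
class CrossBasis:
    """An evaluated cross-basis.

    ``matrix`` has one row per day and ``var_df * lag_df`` columns ordered
    with the exposure index j major: column ``j * lag_df + k``.  Rows whose
    lag window reaches before the series start, or spans a missing exposure
    day, are NaN and marked in ``complete``; they are flagged rather than
    dropped so that row alignment with the outcome series is preserved.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    series_dates: pd.DatetimeIndex | None
    complete: np.ndarray
    exposure: np.ndarray

    @property
    def column_index(self) -> dict[tuple[int, int], int]:
        """(j, k) -> flat column, j over exposure basis, k over lag basis."""
        L = self.spec.lag_df
        return {(j, k): j * L + k for j in range(self.spec.var_df) for k in range(L)}


def build_lag_matrix(series, lag: LagStructure) -> np.ndarray:
    """Matrix Q with Q[t, l] = series[t - l]; unavailable lags are NaN."""
    x = np.asarray(series, dtype=float).ravel()
    L = lag.max_lag
    if x.size <= L:
        raise ValueError(f"series of length {x.size} is shorter than max_lag+1={L + 1}")
    n = x.size
    Q = np.full((n, L + 1), np.nan)
    for l in range(L + 1):
        Q[l:, l] = x[: n - l]
    return Q


def build_crossbasis(series, spec: CrossBasisSpec, dates=None) -> CrossBasis:
    """Evaluate the cross-basis of an exposure series.

    Missing exposure values (NaN) are allowed: any row whose lag window
    covers a missing day is flagged incomplete, never bridged.
    """
    x = np.asarray(series, dtype=float).ravel()
    if dates is not None:
        dates = pd.DatetimeIndex(dates)
        if len(dates) != x.size:
            raise ValueError("dates and series lengths differ")
    L = spec.lag.max_lag
    if x.size <= L:
        raise ValueError(f"series of length {x.size} is shorter than max_lag+1={L + 1}")
    vb = spec.var_basis_matrix(x)                       # (n, J); NaN rows for missing days
    lb = spec.lag_basis_matrix()                        # (L+1, K)
    n, J, K = x.size, spec.var_df, spec.lag_df
    M = np.zeros((n, J * K))
    for l in range(L + 1):
        shifted = np.full((n, J), np.nan)
        shifted[l:, :] = vb[: n - l, :]
        M += np.einsum("nj,k->njk", shifted, lb[l]).reshape(n, J * K)
    complete = np.isfinite(M).all(axis=1)
    M[~complete, :] = np.nan
    return CrossBasis(M, spec, dates, complete, x)


class CrossBasisTransformer:
    """scikit-learn style transformer building a DLNM cross-basis.

    ``fit`` places exposure knots from the training series (equally spaced
    quantiles) and lag knots at equally spaced values on [0, max_lag];
    ``transform`` evaluates the cross-basis, returning a matrix with NaN in
    incomplete rows (inspect ``complete_`` after transform, or mask NaN).
    """

    def __init__(self, var_df: int = 4, lag_df: int = 5, max_lag: int = 28,
                 var_knots: KnotSpec | None = None, lag_knots: KnotSpec | None = None,
                 lag_intercept: bool = True):
        self.var_df = var_df
        self.lag_df = lag_df
        self.max_lag = max_lag
        self.var_knots = var_knots
        self.lag_knots = lag_knots
        self.lag_intercept = lag_intercept

    def get_params(self, deep: bool = True):
        return {k: getattr(self, k) for k in
                ("var_df", "lag_df", "max_lag", "var_knots", "lag_knots", "lag_intercept")}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if self.var_knots is not None and self.lag_knots is not None:
            spec = CrossBasisSpec(self.var_knots, LagStructure(self.max_lag),
                                  self.lag_knots, self.lag_intercept)
        else:
            spec = CrossBasisSpec.from_dfs(x[np.isfinite(x)], self.var_df, self.lag_df,
                                           self.max_lag, self.lag_intercept)
            if self.var_knots is not None:
                spec = CrossBasisSpec(self.var_knots, spec.lag, spec.lag_knots,
                                      self.lag_intercept)
        self.spec_ = spec
        return self

    def transform(self, X):
        if not hasattr(self, "spec_"):
            raise ValueError("CrossBasisTransformer is not fitted")
        cb = build_crossbasis(np.asarray(X, dtype=float).ravel(), self.spec_)
        self.complete_ = cb.complete
        return cb.matrix

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
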