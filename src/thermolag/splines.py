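"""Natural cubic spline (NCS) bases.

A natural cubic spline with interior knots xi_1 < ... < xi_m inside boundary
knots (b0, b1) is a cubic spline that is linear beyond the boundaries.  The
function space (including the constant) has dimension m + 2, so a basis that
excludes the intercept has ``df = m + 1`` columns.

The basis returned here is the *cardinal* parameterization: writing the full
knot sequence k_1 < ... < k_K (boundaries plus interiors, K = m + 2), column
j is the unique natural cubic spline taking the value 1 at knot k_{j+1} and 0
at every other knot.  Dropping the cardinal function of the first knot
removes the intercept direction while preserving the span together with the
constant.  This parameterization is translation-equivariant and makes fitted
coefficients readable as values at knots; all downstream quantities (fitted
means, relative risks, AIC) are invariant to the choice.

Outside the boundary knots every basis function continues linearly (the
natural condition), so evaluation on prediction grids slightly wider than
the data is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotSpec", "BasisMatrix", "place_knots", "place_knots_even", "ncs_basis",
           "NaturalSplineFeatures"]


@dataclass(frozen=True)
class KnotSpec:
    """Knot layout of one NCS dimension.

    Parameters
    ----------
    interior : tuple of float
        Strictly increasing knots strictly inside the boundary pair.
    boundary : (float, float)
        Boundary knots bracketing the interior knots.
    """

    interior: tuple[float, ...]
    boundary: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.boundary
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ValueError(f"boundary knots must be finite and increasing, got {self.boundary}")
        interior = tuple(float(k) for k in self.interior)
        if any(not np.isfinite(k) for k in interior):
            raise ValueError("interior knots must be finite")
        if any(k2 <= k1 for k1, k2 in zip(interior, interior[1:])):
            raise ValueError("interior knots must be strictly increasing")
        if interior and (interior[0] <= lo or interior[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        object.__setattr__(self, "interior", interior)
        object.__setattr__(self, "boundary", (float(lo), float(hi)))

    @property
    def df(self) -> int:
        """Number of basis columns (intercept excluded)."""
        return len(self.interior) + 1

    @property
    def all_knots(self) -> np.ndarray:
        """Full increasing knot sequence: lower boundary, interiors, upper boundary."""
        return np.array([self.boundary[0], *self.interior, self.boundary[1]])


@dataclass
class BasisMatrix:
    """An evaluated spline basis: rows are evaluation points, columns basis functions."""

    values: np.ndarray
    knots: KnotSpec
    variable_name: str = ""

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != self.knots.df:
            raise ValueError("basis matrix column count must equal knots.df")


def place_knots(values, df: int) -> KnotSpec:
    """Place knots for a ``df``-column NCS from the data distribution.

    Boundary knots sit at the min and max of ``values``; the ``df - 1``
    interior knots sit at equally spaced quantiles (levels k/df).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(values)
    if df > distinct.size - 1:
        raise ValueError(
            f"insufficient distinct values: df={df} needs at least {df + 1} distinct values, "
            f"got {distinct.size}")
    boundary = (float(values.min()), float(values.max()))
    levels = np.arange(1, df) / df
    interior = np.quantile(values, levels)  # linear interpolation between order stats
    if np.unique(interior).size != interior.size or (
        interior.size and (interior[0] <= boundary[0] or interior[-1] >= boundary[1])
    ):
        raise ValueError("insufficient distinct values: quantile knots collide")
    return KnotSpec(tuple(interior), boundary)


def place_knots_even(lo: float, hi: float, df: int) -> KnotSpec:
    """Knots at equally spaced *values* on [lo, hi] (used for the lag dimension)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    grid = np.linspace(lo, hi, df + 1)
    return KnotSpec(tuple(grid[1:-1]), (float(lo), float(hi)))


def _cardinal_coefs(knots: KnotSpec) -> np.ndarray:
    """Coefficients mapping the raw NCS basis to cardinal form, one column per knot."""
    k = knots.all_knots
    A = _raw_ncs(k, k)
    return np.linalg.solve(A, np.eye(len(k)))


def _raw_ncs(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Raw K-dimensional NCS basis (with intercept) on knot sequence ``knots``.

    Columns: 1, x, and K-2 differences of scaled truncated cubics, each
    constructed to be linear outside the boundary knots.
    """
    K = len(knots)
    cols = [np.ones_like(x), x]
    if K > 2:
        def d(j):
            num = np.maximum(x - knots[j], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
            return num / (knots[K - 1] - knots[j])
        last = d(K - 2)
        cols.extend(d(j) - last for j in range(K - 2))
    return np.column_stack(cols)


def _basis_values(x: np.ndarray, knots: KnotSpec) -> np.ndarray:
    """Cardinal NCS basis without validation; NaN inputs propagate to NaN rows."""
    C = _cardinal_coefs(knots)
    full = _raw_ncs(x, knots.all_knots) @ C
    out = full[:, 1:]  # drop the first knot's cardinal function (intercept direction)
    bad = ~np.isfinite(x)
    if bad.any():
        out[bad, :] = np.nan
    return out


def ncs_basis(x, knots: KnotSpec, variable_name: str = "") -> BasisMatrix:
    """Evaluate the ``knots.df``-column natural cubic spline basis at ``x``.

    Points beyond the boundary knots are extrapolated linearly (the natural
    condition makes this the unique C2 continuation).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    bad = ~np.isfinite(x)
    if bad.any():
        rows = np.flatnonzero(bad)
        raise ValueError(f"non-finite values of '{variable_name or 'x'}' at rows {rows[:10].tolist()}")
    return BasisMatrix(_basis_values(x, knots), knots, variable_name)


class NaturalSplineFeatures:
    """scikit-learn style transformer producing an NCS basis.

    Parameters
    ----------
    df : int
        Number of basis columns (intercept excluded).
    knots : KnotSpec, optional
        Explicit knots; when given, ``df`` is ignored and no placement occurs.
    strategy : {"quantile", "even"}
        Automatic knot placement rule used during :meth:`fit`.
    """

    def __init__(self, df: int = 3, knots: KnotSpec | None = None, strategy: str = "quantile"):
        self.df = df
        self.knots = knots
        self.strategy = strategy

    def get_params(self, deep: bool = True):
        return {"df": self.df, "knots": self.knots, "strategy": self.strategy}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if self.knots is not None:
            self.knots_ = self.knots
        elif self.strategy == "quantile":
            self.knots_ = place_knots(x, self.df)
        elif self.strategy == "even":
            self.knots_ = place_knots_even(x.min(), x.max(), self.df)
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        if not hasattr(self, "knots_"):
            raise ValueError("NaturalSplineFeatures is not fitted")
        x = np.asarray(X, dtype=float).ravel()
        return ncs_basis(x, self.knots_).values

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
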