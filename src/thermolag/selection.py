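"""AIC-driven model selection.

The selection decides four model components: the time-spline smoothness
(df per year), the temperature indicator (maximum / average / minimum), the
cross-basis temperature df, and the cross-basis lag df.  Two strategies are
provided:

* ``sequential`` fixes the four choices one step at a time, each step
  minimizing the AIC over its candidates while the not-yet-selected
  components sit at the midpoints of their candidate lists;
* ``exhaustive`` fits the full Cartesian grid.

Ties break toward the smaller df (parsimony) and then toward the average
temperature indicator.  Every attempted fit is logged in the trace with its
AIC, or the failure reason, so the search is fully auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .regression import FitError, ModelSpec, fit_model, hue2016

__all__ = ["SelectionGrid", "SelectionResult", "select_model", "AICGridSearch", "hue2016"]

_INDICATOR_ORDER = {"average": 0, "maximum": 1, "minimum": 2}  # tie-break preference


@dataclass(frozen=True)
class SelectionGrid:
    """Candidate lists for the four selection steps."""

    time_df_per_year_candidates: tuple = tuple(range(3, 11))
    indicator_candidates: tuple = ("maximum", "average", "minimum")
    var_df_candidates: tuple = tuple(range(2, 7))
    lag_df_candidates: tuple = tuple(range(2, 7))
    max_lag: int = 28

    def __post_init__(self):
        for name in ("time_df_per_year_candidates", "indicator_candidates",
                     "var_df_candidates", "lag_df_candidates"):
            if not len(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty")

    def _midpoint(self, values):
        values = sorted(values)
        return values[(len(values) - 1) // 2]

    def default_spec(self) -> ModelSpec:
        """Provisional spec holding every component at its candidate midpoint."""
        ind = sorted(self.indicator_candidates, key=_INDICATOR_ORDER.get)[0]
        return ModelSpec(temperature_indicator=ind,
                         var_df=self._midpoint(self.var_df_candidates),
                         lag_df=self._midpoint(self.lag_df_candidates),
                         max_lag=self.max_lag,
                         time_df_per_year=self._midpoint(self.time_df_per_year_candidates))


@dataclass
class SelectionResult:
    chosen: ModelSpec
    trace: pd.DataFrame  # columns: step, parameter, candidate, aic, status
    aic: float

    def best_rows(self) -> pd.DataFrame:
        ok = self.trace[self.trace["status"] == "ok"]
        return ok.loc[ok.groupby("step")["aic"].idxmin()]


def _try_fit(data, spec, outcome, rows, step, parameter, candidate):
    try:
        model = fit_model(data, spec, outcome)
        rows.append({"step": step, "parameter": parameter, "candidate": candidate,
                     "aic": model.aic, "status": "ok"})
        return model.aic
    except (FitError, ValueError, np.linalg.LinAlgError) as exc:
        rows.append({"step": step, "parameter": parameter, "candidate": candidate,
                     "aic": np.nan, "status": f"failed: {exc}"})
        return np.nan


def _argmin(cands, aics, key=lambda c: c):
    """Index of the smallest AIC; ties prefer the smaller candidate under ``key``."""
    best, best_aic = None, np.inf
    order = sorted(range(len(cands)), key=lambda i: key(cands[i]))
    for i in order:
        if np.isfinite(aics[i]) and aics[i] < best_aic - 1e-9:
            best, best_aic = i, aics[i]
    return best, best_aic


def select_model(data: pd.DataFrame, grid: SelectionGrid | None = None,
                 strategy: str = "sequential", outcome: str = "deaths_all") -> SelectionResult:
    """Run the four-step AIC selection (or an exhaustive grid search)."""
    grid = grid or SelectionGrid()
    rows: list[dict] = []

    if strategy == "exhaustive":
        combos = list(itertools.product(grid.time_df_per_year_candidates,
                                        grid.indicator_candidates,
                                        grid.var_df_candidates,
                                        grid.lag_df_candidates))
        specs = [ModelSpec(temperature_indicator=ind, var_df=v, lag_df=l,
                           max_lag=grid.max_lag, time_df_per_year=tdf)
                 for tdf, ind, v, l in combos]
        aics = [_try_fit(data, s, outcome, rows, 0, "grid", str(c))
                for c, s in zip(combos, specs)]
        key = lambda c: (c[2], c[3], c[0], _INDICATOR_ORDER[c[1]])
        idx, best_aic = _argmin(combos, aics, key=lambda c: key(c))
        if idx is None:
            raise FitError("every candidate fit failed", rows)
        return SelectionResult(specs[idx], pd.DataFrame(rows), best_aic)

    if strategy != "sequential":
        raise ValueError("strategy must be 'sequential' or 'exhaustive'")

    spec = grid.default_spec()
    steps = [
        (1, "time_df_per_year", grid.time_df_per_year_candidates, lambda c: c),
        (2, "temperature_indicator", grid.indicator_candidates, _INDICATOR_ORDER.get),
        (3, "var_df", grid.var_df_candidates, lambda c: c),
        (4, "lag_df", grid.lag_df_candidates, lambda c: c),
    ]
    best_aic = np.nan
    for step, param, cands, key in steps:
        aics = [_try_fit(data, replace(spec, **{param: c}), outcome, rows, step, param, c)
                for c in cands]
        idx, best_aic = _argmin(list(cands), aics, key=key)
        if idx is None:
            raise FitError(f"every candidate fit failed at step {step} ({param})", rows)
        spec = replace(spec, **{param: cands[idx]})
    return SelectionResult(spec, pd.DataFrame(rows), best_aic)


class AICGridSearch(BaseEstimator):
    """scikit-learn style wrapper around :func:`select_model`.

    After ``fit``, ``best_spec_`` holds the chosen :class:`ModelSpec`,
    ``best_aic_`` its AIC and ``trace_`` the full search log.
    """

    def __init__(self, grid: SelectionGrid | None = None, strategy: str = "sequential",
                 outcome: str = "deaths_all"):
        self.grid = grid
        self.strategy = strategy
        self.outcome = outcome

    def fit(self, X: pd.DataFrame, y=None):
        result = select_model(X, self.grid, self.strategy, self.outcome)
        self.result_ = result
        self.best_spec_ = result.chosen
        self.best_aic_ = result.aic
        self.trace_ = result.trace
        return self
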