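"""End-to-end study orchestration.

`run_study` reproduces the analysis flow on any compliant daily series:
describe the data, choose the model (four-step AIC selection or the shipped
`hue2016` preset), fit the all-cause model, re-fit the same predictor
structure for each stratum outcome, and report percentile-contrast effects
(hot: 99th vs 50th percentile over lags 0-2; cold: 1st vs 50th over lags
0-28), cumulative overall curves across lag windows, and single-lag curves.
Line-listed death records can be aggregated to daily counts first.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import effects as eff
from .regression import FittedModel, ModelSpec, fit_model, hue2016
from .selection import SelectionGrid, SelectionResult, select_model

__all__ = ["WEATHER_COLUMNS", "STRATUM_COLUMNS", "validate_daily_series", "load_daily_csv",
           "aggregate_deaths", "describe", "StudyConfig", "StudyReport", "run_study"]

log = logging.getLogger("thermolag")

WEATHER_COLUMNS = ["tmax", "tavg", "tmin", "dewpoint", "humidity"]
STRATUM_COLUMNS = ["deaths_nonext", "deaths_cvd", "deaths_resp", "deaths_cancer",
                   "deaths_male", "deaths_female", "deaths_0_64", "deaths_65plus"]
DEFAULT_WINDOWS = ((0, 1), (0, 2), (0, 3), (0, 4), (0, 7), (0, 14), (0, 21), (0, 28))

_ICD_RE = re.compile(r"^([A-Z])(\d{2})")

# ICD-10 chapter ranges, both endpoints inclusive on the 3-character code
_CAUSE_RANGES = {
    "deaths_nonext": ("A00", "R99"),
    "deaths_cvd": ("I00", "I99"),
    "deaths_resp": ("J00", "J99"),
    "deaths_cancer": ("C00", "D48"),
}


def validate_daily_series(data: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a daily series.

    Dates are made contiguous: missing days are inserted with NaN weather
    and counts (a gap breaks every lag window covering it, and NaN counts
    drop those rows from fitting).  Count columns must be non-negative
    integers where present; humidity must lie in (0, 100].
    """
    if "date" not in data.columns:
        raise ValueError("daily series needs a 'date' column")
    out = data.copy()
    out["date"] = pd.to_datetime(out["date"])
    if out["date"].duplicated().any():
        raise ValueError("duplicate dates in daily series")
    out = out.sort_values("date").reset_index(drop=True)
    full = pd.date_range(out["date"].iloc[0], out["date"].iloc[-1], freq="D")
    if len(full) != len(out):
        log.warning("daily series has %d missing days; inserted as gaps",
                    len(full) - len(out))
        out = out.set_index("date").reindex(full).rename_axis("date").reset_index()

    for col in out.columns:
        if not col.startswith("deaths"):
            continue
        v = pd.to_numeric(out[col], errors="coerce")
        ok = v.dropna()
        if ((ok < 0) | (ok != ok.round())).any():
            raise ValueError(f"column '{col}' must hold non-negative integer counts")
        out[col] = v
    if "humidity" in out.columns:
        h = out["humidity"].dropna()
        if ((h <= 0) | (h > 100)).any():
            raise ValueError("humidity must lie in (0, 100]")
    trio = out[["tmin", "tavg", "tmax"]].dropna() if set(
        ["tmin", "tavg", "tmax"]).issubset(out.columns) else None
    if trio is not None and (((trio["tmin"] > trio["tavg"]) |
                              (trio["tavg"] > trio["tmax"])).any()):
        raise ValueError("require tmin <= tavg <= tmax on every complete day")
    return out


def load_daily_csv(path) -> pd.DataFrame:
    """Read and validate a daily series CSV (ISO-8601 dates)."""
    return validate_daily_series(pd.read_csv(path))


def aggregate_deaths(records: pd.DataFrame, date_range=None) -> pd.DataFrame:
    """Aggregate line-listed deaths to daily stratified counts.

    ``records`` needs columns date_of_death, sex ('male'/'female'), age
    (years) and icd10.  Cause classification compares the leading
    letter+two-digit code against the chapter ranges (non-external A00-R99,
    cardiovascular I00-I99, respiratory J00-J99, cancer C00-D48); records
    with unparseable codes count toward all-cause only and are logged.
    Days without deaths are zero-filled.
    """
    rec = records.copy()
    rec["date_of_death"] = pd.to_datetime(rec["date_of_death"])
    if date_range is None:
        idx = pd.date_range(rec["date_of_death"].min(), rec["date_of_death"].max(), freq="D")
    else:
        idx = pd.date_range(date_range[0], date_range[1], freq="D")
        rec = rec[(rec["date_of_death"] >= idx[0]) & (rec["date_of_death"] <= idx[-1])]

    codes = rec["icd10"].astype(str).str.upper().str.strip()
    parsed = codes.str.extract(_ICD_RE, expand=True)
    code3 = (parsed[0] + parsed[1]).where(parsed[0].notna())
    n_bad = int(code3.isna().sum())
    if n_bad:
        log.warning("%d records with unparseable ICD-10 codes counted in all-cause only", n_bad)

    out = pd.DataFrame({"date": idx})
    daily = rec.groupby("date_of_death").size()
    out["deaths_all"] = daily.reindex(idx, fill_value=0).to_numpy()

    for col, (lo, hi) in _CAUSE_RANGES.items():
        hit = code3.notna() & (code3 >= lo) & (code3 <= hi)
        counts = rec.loc[hit].groupby("date_of_death").size()
        out[col] = counts.reindex(idx, fill_value=0).to_numpy()

    sex = rec["sex"].astype(str).str.lower()
    for col, label in (("deaths_male", "male"), ("deaths_female", "female")):
        counts = rec.loc[sex == label].groupby("date_of_death").size()
        out[col] = counts.reindex(idx, fill_value=0).to_numpy()

    age = pd.to_numeric(rec["age"], errors="coerce")
    for col, hit in (("deaths_0_64", age < 65), ("deaths_65plus", age >= 65)):
        counts = rec.loc[hit.fillna(False)].groupby("date_of_death").size()
        out[col] = counts.reindex(idx, fill_value=0).to_numpy()
    return out


@dataclass
class DataSummary:
    table: pd.DataFrame
    weather_correlations: pd.DataFrame

    def __str__(self):
        return self.table.to_string(float_format=lambda v: f"{v:.1f}")


def describe(data: pd.DataFrame) -> DataSummary:
    """Summary statistics per numeric column plus the weather correlation matrix.

    Per column: mean, SD, minimum, 25/50/75 percentiles and maximum, with
    percentiles computed by linear interpolation between order statistics.
    """
    numeric = data.select_dtypes(include=[np.number])
    rows = {}
    for col in numeric.columns:
        v = numeric[col].dropna().to_numpy(dtype=float)
        if v.size == 0:
            continue
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        rows[col] = {"mean": v.mean(), "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                     "min": v.min(), "p25": q25, "p50": q50, "p75": q75, "max": v.max()}
    table = pd.DataFrame(rows).T
    weather = [c for c in WEATHER_COLUMNS if c in numeric.columns]
    corr = numeric[weather].corr() if weather else pd.DataFrame()
    return DataSummary(table, corr)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run."""

    preset: str | None = "hue2016"         # None runs model selection instead
    selection_grid: SelectionGrid | None = None
    selection_strategy: str = "sequential"
    outcome: str = "deaths_all"
    strata: tuple | None = None            # None: every deaths_* column present
    p_cold: float = 1.0
    p_ref: float = 50.0
    p_hot: float = 99.0
    hot_window: tuple[int, int] = (0, 2)
    cold_window: tuple[int, int] = (0, 28)
    curve_windows: tuple = DEFAULT_WINDOWS
    refit_per_window: bool = True          # re-fit with max_lag = window end for curves
    curves: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "selection_grid" in raw and raw["selection_grid"] is not None:
            raw["selection_grid"] = SelectionGrid(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["selection_grid"].items()})
        for key in ("hot_window", "cold_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "curve_windows" in raw:
            raw["curve_windows"] = tuple(tuple(w) for w in raw["curve_windows"])
        if "strata" in raw and raw["strata"] is not None:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)


@dataclass
class StudyReport:
    config: StudyConfig
    spec: ModelSpec
    selection: SelectionResult | None
    summary: DataSummary
    fits: dict[str, FittedModel]
    effects_table: pd.DataFrame
    curves: dict[tuple[int, int], eff.EffectCurve]
    lag_curves: dict[str, eff.LagCurve]
    skipped: list[str]

    def manifest(self) -> dict:
        spec = self.spec
        return {
            "model": {"temperature_indicator": spec.temperature_indicator,
                      "var_df": spec.var_df, "lag_df": spec.lag_df,
                      "max_lag": spec.max_lag, "time_df_per_year": spec.time_df_per_year,
                      "humidity_df": spec.humidity_df, "dewpoint_df": spec.dewpoint_df,
                      "dow": spec.dow},
            "selection": None if self.selection is None else {
                "strategy": self.config.selection_strategy,
                "n_fits": int(len(self.selection.trace)),
                "best_aic": float(self.selection.aic)},
            "fits": {name: {"aic": float(m.aic), "n_used": int(m.n_used),
                            "dispersion": (None if not np.isfinite(m.dispersion)
                                           else float(m.dispersion))}
                     for name, m in self.fits.items()},
            "skipped_strata": self.skipped,
        }

    def save(self, outdir, plots: bool = False):
        """Write effects / trace / curve CSVs and the JSON manifest to ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.effects_table.to_csv(outdir / "effects.csv", index=False)
        self.summary.table.to_csv(outdir / "summary.csv")
        if self.selection is not None:
            self.selection.trace.to_csv(outdir / "selection_trace.csv", index=False)
        frames = []
        for window, curve in self.curves.items():
            f = curve.to_frame()
            f.insert(0, "lag_high", window[1])
            f.insert(0, "lag_low", window[0])
            frames.append(f)
        if frames:
            pd.concat(frames).to_csv(outdir / "overall_curves.csv", index=False)
        lag_frames = []
        for name, curve in self.lag_curves.items():
            f = curve.to_frame()
            f.insert(0, "effect", name)
            lag_frames.append(f)
        if lag_frames:
            pd.concat(lag_frames).to_csv(outdir / "lag_curves.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
        if plots:
            self._plot(outdir)

    def _plot(self, outdir):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if self.curves:
            n = len(self.curves)
            fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
            for ax, (window, curve) in zip(axes.ravel(), sorted(self.curves.items())):
                ax.fill_between(curve.temps, curve.ci_low, curve.ci_high,
                                color="0.8", label="95% CI")
                ax.plot(curve.temps, curve.rr, color="crimson")
                ax.axhline(1.0, color="0.5", lw=0.5)
                ax.set_title(f"lag {window[0]}-{window[1]}")
                ax.set_xlabel("temperature (degC)")
            axes[0, 0].set_ylabel("cumulative RR")
            fig.tight_layout()
            fig.savefig(outdir / "overall_curves.png", dpi=150)
            plt.close(fig)
        if self.lag_curves:
            fig, axes = plt.subplots(1, len(self.lag_curves), figsize=(8, 3), squeeze=False)
            for ax, (name, curve) in zip(axes.ravel(), self.lag_curves.items()):
                ax.fill_between(curve.lags, curve.ci_low, curve.ci_high, color="0.8")
                ax.plot(curve.lags, curve.rr, color="crimson")
                ax.axhline(1.0, color="0.5", lw=0.5)
                ax.set_title(f"{name} effect")
                ax.set_xlabel("lag (days)")
            axes[0, 0].set_ylabel("RR at single lag")
            fig.tight_layout()
            fig.savefig(outdir / "lag_curves.png", dpi=150)
            plt.close(fig)


def _percentile_row(model, name, config) -> pd.DataFrame:
    table = eff.percentile_effects(model, config.p_cold, config.p_ref, config.p_hot,
                                   config.hot_window, config.cold_window)
    table.insert(0, "stratum", name)
    return table


def run_study(data: pd.DataFrame, config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the full analysis flow and collect every artifact into a report."""
    data = validate_daily_series(data)
    summary = describe(data)

    selection = None
    if config.preset == "hue2016":
        spec = hue2016()
    elif config.preset is None:
        selection = select_model(data, config.selection_grid, config.selection_strategy,
                                 config.outcome)
        spec = selection.chosen
    else:
        raise ValueError(f"unknown preset {config.preset!r}")

    fits: dict[str, FittedModel] = {}
    skipped: list[str] = []
    log.info("fitting all-cause model: %s", spec)
    fits[config.outcome] = fit_model(data, spec, config.outcome)

    strata = config.strata
    if strata is None:
        strata = tuple(c for c in STRATUM_COLUMNS if c in data.columns)
    for col in strata:
        counts = pd.to_numeric(data[col], errors="coerce")
        if counts.fillna(0).sum() == 0:
            log.warning("stratum %s has no deaths; skipped", col)
            skipped.append(col)
            continue
        try:
            fits[col] = fit_model(data, spec, col)
        except Exception as exc:
            log.warning("stratum %s failed to fit (%s); skipped", col, exc)
            skipped.append(col)

    effects_table = pd.concat([_percentile_row(m, name, config)
                               for name, m in fits.items()], ignore_index=True)

    curves: dict[tuple[int, int], eff.EffectCurve] = {}
    lag_curves: dict[str, eff.LagCurve] = {}
    main = fits[config.outcome]
    if config.curves:
        temps = main.exposure_used
        grid = np.linspace(temps.min(), temps.max(), 50)
        ref = float(np.percentile(temps, config.p_ref))
        for window in config.curve_windows:
            window = (int(window[0]), int(window[1]))
            if config.refit_per_window and window[1] != spec.max_lag:
                # the lag spline df cannot exceed the window length
                lag_df = min(spec.lag_df, window[1] - window[0] + 1)
                wspec = replace(spec, max_lag=window[1], lag_df=lag_df)
                wmodel = fit_model(data, wspec, config.outcome)
            else:
                wmodel = main
            curves[window] = eff.overall_curve(wmodel, grid, ref, window)
        t_cold, t_hot = np.percentile(temps, [config.p_cold, config.p_hot])
        lag_curves["hot"] = eff.lag_structure(main, eff.TemperatureContrast(float(t_hot), ref))
        lag_curves["cold"] = eff.lag_structure(main, eff.TemperatureContrast(float(t_cold), ref))

    return StudyReport(config, spec, selection, summary, fits, effects_table,
                       curves, lag_curves, skipped)
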