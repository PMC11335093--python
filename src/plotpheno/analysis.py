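"""Statistical analysis of extracted phenotype tables.

Five-family curve fitting with best-fit selection, correlation screening
against ground truth, per-date trait dynamics, box-plot distribution
statistics, and prediction-accuracy metrics. All functions are pure: the
same table in, the same numbers out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CorrelationMatrix",
    "FIT_FAMILIES",
    "FitResult",
    "SeriesSummary",
    "accuracy_report",
    "correlation_matrix",
    "distribution_stats",
    "dynamic_curve",
    "fit_curves",
]

logger = logging.getLogger(__name__)

FIT_FAMILIES = ("linear", "quadratic", "exponential", "power", "logarithmic")

#: families tied for best when RMSE agrees at this many decimals
RMSE_TIE_DECIMALS = 4


@dataclass
class FitResult:
    """One fitted family: coefficients, fit quality, formula rendering."""

    family: str
    coefficients: list[float]
    rmse: float
    r_squared: float | None
    n: int
    note: str | None = None

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c[0] + c[1] * x
        if self.family == "quadratic":
            return c[0] + c[1] * x + c[2] * x**2
        if self.family == "exponential":
            return c[0] * np.exp(c[1] * x)
        if self.family == "power":
            return c[0] * np.power(x, c[1])
        if self.family == "logarithmic":
            return c[0] + c[1] * np.log(x)
        raise ValueError(f"unknown family {self.family!r}")

    def equation(self) -> str:
        c = [f"{v:.6g}" for v in self.coefficients]
        if self.family == "linear":
            return f"y = {c[0]} + {c[1]}*x"
        if self.family == "quadratic":
            return f"y = {c[0]} + {c[1]}*x + {c[2]}*x^2"
        if self.family == "exponential":
            return f"y = {c[0]}*exp({c[1]}*x)"
        if self.family == "power":
            return f"y = {c[0]}*x^{c[1]}"
        return f"y = {c[0]} + {c[1]}*ln(x)"


def _metrics(y: np.ndarray, predicted: np.ndarray) -> tuple[float, float | None]:
    residual = y - predicted
    rmse = float(np.sqrt(np.mean(residual**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum(residual**2)) / ss_tot
    return rmse, r2


def _fit_family(family: str, x: np.ndarray, y: np.ndarray) -> FitResult:
    n = len(x)
    if family == "linear":
        b, a = np.polyfit(x, y, 1)
        coefficients = [float(a), float(b)]
    elif family == "quadratic":
        c2, c1, c0 = np.polyfit(x, y, 2)
        coefficients = [float(c0), float(c1), float(c2)]
    elif family == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic fit requires x > 0")
        b, a = np.polyfit(np.log(x), y, 1)
        coefficients = [float(a), float(b)]
    elif family == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential initialization requires y > 0")
        # log-linear start, then least squares on the original scale
        b0, log_a0 = np.polyfit(x, np.log(y), 1)
        params, _ = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y,
                              p0=[np.exp(log_a0), b0], maxfev=10000)
        coefficients = [float(params[0]), float(params[1])]
    elif family == "power":
        if np.any(x <= 0):
            raise ValueError("power fit requires x > 0")
        if np.any(y <= 0):
            raise ValueError("power initialization requires y > 0")
        b0, log_a0 = np.polyfit(np.log(x), np.log(y), 1)
        params, _ = curve_fit(lambda t, a, b: a * np.power(t, b), x, y,
                              p0=[np.exp(log_a0), b0], maxfev=10000)
        coefficients = [float(params[0]), float(params[1])]
    else:
        raise ValueError(f"unknown family {family!r}")
    result = FitResult(family, coefficients, 0.0, None, n)
    result.rmse, result.r_squared = _metrics(y, result.predict(x))
    return result


def fit_curves(x, y) -> tuple[list[FitResult], list[FitResult]]:
    """Least-squares fit of all five families on the original scale.

    Returns ``(results, best)`` where *best* is every family tied for the
    minimal RMSE at 4-decimal rounding (ties are reported, not broken).
    Families whose domain constraints fail are skipped with a note in the
    results list. Zero variance in y makes R² undefined (flagged None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"curve fitting needs n ≥ 3, got {len(x)}")
    if np.ptp(y) == 0:
        logger.warning("fit_curves: zero variance in y, R² undefined")
    results: list[FitResult] = []
    for family in FIT_FAMILIES:
        try:
            results.append(_fit_family(family, x, y))
        except (ValueError, RuntimeError) as exc:
            results.append(FitResult(family, [], float("nan"), None, len(x),
                                     note=f"skipped: {exc}"))
    fitted = [r for r in results if r.note is None and np.isfinite(r.rmse)]
    if not fitted:
        return results, []
    best_rmse = min(round(r.rmse, RMSE_TIE_DECIMALS) for r in fitted)
    best = [r for r in fitted
            if round(r.rmse, RMSE_TIE_DECIMALS) == best_rmse]
    return results, best


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with optional truth ranking."""

    variables: list[str]
    matrix: pd.DataFrame
    ranking: list[tuple[str, float]] = field(default_factory=list)


def correlation_matrix(wide: pd.DataFrame, variables: list[str],
                       truth: str | None = None) -> CorrelationMatrix:
    """Pearson correlation of the named columns, pairwise-complete.

    Constant columns yield undefined (NaN) coefficients. When ``truth``
    names a column, the other variables are additionally ranked by
    absolute correlation with it.
    """
    missing = [v for v in variables if v not in wide.columns]
    if missing:
        raise ValueError(f"unknown variables: {missing}")
    frame = wide[variables].astype(float)
    counts = frame.notna().astype(int).T @ frame.notna().astype(int)
    if (counts.values[np.triu_indices(len(variables), 1)] < 3).any():
        logger.warning("correlation_matrix: some pairs have < 3 complete "
                       "observations")
    matrix = frame.corr(method="pearson", min_periods=3)
    np.fill_diagonal(matrix.values, 1.0)
    for name in variables:  # constant columns: undefined everywhere
        if frame[name].nunique(dropna=True) <= 1:
            matrix.loc[name, :] = np.nan
            matrix.loc[:, name] = np.nan
    ranking: list[tuple[str, float]] = []
    if truth is not None:
        if truth not in variables:
            raise ValueError(f"truth column {truth!r} not among variables")
        series = matrix[truth].drop(labels=[truth]).dropna()
        ranking = sorted(((k, float(v)) for k, v in series.items()),
                         key=lambda kv: -abs(kv[1]))
    return CorrelationMatrix(list(variables), matrix, ranking)


@dataclass
class SeriesSummary:
    """Per-date summary of one trait across plots."""

    trait: str
    per_date: pd.DataFrame  # indexed by date
    outliers: dict = field(default_factory=dict)  # date -> list of values


def _long_values(table, trait: str) -> pd.DataFrame:
    data = table.data if hasattr(table, "data") else table
    if trait not in set(data["trait"]):
        raise ValueError(f"unknown trait {trait!r}")
    subset = data[data["trait"] == trait].dropna(subset=["value"])
    return subset


def dynamic_curve(table, trait: str) -> SeriesSummary:
    """Mean and max of a trait per date, date-ordered.

    Dates where every plot is missing are omitted with a warning.
    """
    subset = _long_values(table, trait)
    grouped = subset.groupby("date")["value"].agg(["mean", "max", "count"])
    grouped = grouped.sort_index()
    data = table.data if hasattr(table, "data") else table
    dates_with_trait = set(data[data["trait"] == trait]["date"])
    dropped = dates_with_trait - set(grouped.index)
    if dropped:
        logger.warning("dynamic_curve: dates with all-missing %r omitted: %s",
                       trait, sorted(dropped))
    return SeriesSummary(trait, grouped)


def distribution_stats(table, trait: str) -> SeriesSummary:
    """Box statistics per date: min, Q1, median, Q3, max and outliers.

    Quartiles use linear interpolation; values beyond 1.5·IQR from the
    quartiles are listed as outliers (they stay included in min/max).
    """
    subset = _long_values(table, trait)
    rows = []
    outliers: dict = {}
    for date, chunk in subset.groupby("date"):
        values = chunk["value"].to_numpy(dtype=float)
        q1, median, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        low, high = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out = sorted(values[(values < low) | (values > high)].tolist())
        outliers[date] = out
        rows.append({"date": date, "min": values.min(), "q1": q1,
                     "median": median, "q3": q3, "max": values.max(),
                     "count": len(values)})
    per_date = pd.DataFrame(rows).set_index("date").sort_index()
    return SeriesSummary(trait, per_date, outliers)


def accuracy_report(predicted, observed) -> tuple[float | None, float, float | None]:
    """Prediction accuracy: (R², RMSE, rRMSE %).

    rRMSE is RMSE as a percentage of the observed mean; both R² (constant
    observed) and rRMSE (zero observed mean) can be undefined → None.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if len(observed) < 2:
        raise ValueError("accuracy report needs n ≥ 2")
    rmse, r2 = _metrics(observed, predicted)
    mean_observed = float(observed.mean())
    if mean_observed == 0:
        logger.warning("accuracy_report: zero observed mean, rRMSE undefined")
        rrmse = None
    else:
        rrmse = 100.0 * rmse / mean_observed
    if r2 is None:
        logger.warning("accuracy_report: constant observed values, R² undefined")
    return r2, rmse, rrmse
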