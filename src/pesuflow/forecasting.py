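"""Annual-demand forecasting battery with MAD-based model selection.

Five methods are available: ordinary least squares on the year index and
Holt's linear-trend exponential smoothing for trending series; simple
exponential smoothing, moving average and weighted moving average for
stationary series.  Each method produces in-sample one-step-ahead fitted
values; the mean absolute deviation (MAD) of those one-step errors ranks
the methods, and :func:`select_best_method` returns the candidate with the
lowest MAD (ties broken by candidate order).

Conventions (documented because the error window matters for MAD):

* linear regression: fitted values are the in-sample regression line, so
  every point contributes to the MAD;
* Holt: level/trend initialize as l1 = y1, b1 = y2 - y1; the first two
  points have no meaningful one-step error and are skipped;
* simple exponential smoothing: l1 = y1; the first point is skipped;
* (weighted) moving average with window k: the first k points are skipped.

Stationary methods produce flat multi-step forecasts; trend methods
extrapolate.  Negative forecasts are clamped to zero and the clamping is
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

METHODS = (
    "linear_regression",
    "holts",
    "exp_smoothing",
    "moving_average",
    "weighted_moving_average",
)


@dataclass(frozen=True)
class AnnualSeries:
    """An ordered annual demand series (visits per fiscal year)."""

    years: tuple
    values: tuple

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if any(v < 0 for v in self.values):
            raise ValueError("demand values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class ForecastResult:
    method: str
    fitted: np.ndarray  # in-sample one-step values, NaN where undefined
    forecasts: np.ndarray  # length-h horizon forecasts
    mad: float
    params: dict = field(default_factory=dict)
    clamped: bool = False

    def forecast_years(self, series: AnnualSeries) -> list:
        last = int(series.years[-1])
        return [str(last + i + 1) for i in range(len(self.forecasts))]


def _finalize(
    method: str,
    series: AnnualSeries,
    fitted: np.ndarray,
    raw_forecasts: np.ndarray,
    params: dict,
) -> ForecastResult:
    resid = np.abs(series.y - fitted)
    resid = resid[~np.isnan(resid)]
    if resid.size == 0:
        # window as long as the series: a forecast exists but no one-step
        # errors do, so the method cannot be ranked by MAD
        log.info("%s: no in-sample one-step errors; MAD undefined", method)
        mad = float("nan")
    else:
        mad = float(np.mean(resid))
    clamped = bool(np.any(raw_forecasts < 0))
    if clamped:
        log.warning("%s: negative forecasts clamped to zero", method)
    return ForecastResult(
        method, fitted, np.maximum(raw_forecasts, 0.0), mad, params, clamped
    )


def linear_regression_forecast(series: AnnualSeries, h: int) -> ForecastResult:
    """OLS of demand on the year index, extrapolated ``h`` years ahead."""
    n = len(series)
    if n < 3:
        raise ValueError("linear regression needs at least 3 points")
    x = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(x, series.y, 1)
    fitted = intercept + slope * x
    fc = intercept + slope * (n - 1 + np.arange(1, h + 1))
    return _finalize(
        "linear_regression", series, fitted, fc,
        {"slope": float(slope), "intercept": float(intercept)},
    )


def holts_forecast(series: AnnualSeries, alpha: float, beta: float, h: int) -> ForecastResult:
    """Holt's linear-trend method.

    Recursion: l_t = a*y_t + (1-a)(l_{t-1} + b_{t-1});
    b_t = B(l_t - l_{t-1}) + (1-B) b_{t-1}; forecast l_n + m*b_n.
    """
    if not (0 < alpha < 1) or not (0 < beta < 1):
        raise ValueError("alpha and beta must lie in (0, 1)")
    n = len(series)
    if n < 2:
        raise ValueError("Holt's method needs at least 2 points")
    y = series.y
    fitted = np.full(n, np.nan)
    level, trend = y[0], y[1] - y[0]
    for t in range(1, n):
        one_step = level + trend
        if t >= 2:
            fitted[t] = one_step
        new_level = alpha * y[t] + (1 - alpha) * one_step
        trend = beta * (new_level - level) + (1 - beta) * trend
        level = new_level
    fc = level + trend * np.arange(1, h + 1)
    return _finalize("holts", series, fitted, fc, {"alpha": alpha, "beta": beta})


def exp_smoothing_forecast(series: AnnualSeries, alpha: float, h: int) -> ForecastResult:
    """Simple exponential smoothing with a flat multi-step forecast."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    n = len(series)
    if n < 2:
        raise ValueError("exponential smoothing needs at least 2 points")
    y = series.y
    fitted = np.full(n, np.nan)
    level = y[0]
    for t in range(1, n):
        fitted[t] = level
        level = alpha * y[t] + (1 - alpha) * level
    fc = np.full(h, level)
    return _finalize("exp_smoothing", series, fitted, fc, {"alpha": alpha})


def moving_average_forecast(series: AnnualSeries, k: int, h: int) -> ForecastResult:
    """k-period moving average; flat multi-step forecast of the last window."""
    n = len(series)
    if k < 1:
        raise ValueError("window k must be >= 1")
    if n < k:
        raise ValueError("window longer than series")
    y = series.y
    fitted = np.full(n, np.nan)
    for t in range(k, n):
        fitted[t] = np.mean(y[t - k : t])
    fc = np.full(h, float(np.mean(y[-k:])))
    return _finalize("moving_average", series, fitted, fc, {"k": k})


def weighted_moving_average_forecast(
    series: AnnualSeries, k: int, weights, h: int
) -> ForecastResult:
    """Weighted k-period moving average with weights normalized to sum 1.

    Weights are ordered oldest-to-newest within the window (the last weight
    multiplies the most recent observation).  Raw weights that do not sum
    to 1 are normalized and both vectors logged.
    """
    w = np.asarray(weights, dtype=float)
    if k < 1 or w.shape != (k,):
        raise ValueError("need a weight vector of length k >= 1")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    n = len(series)
    if n < k:
        raise ValueError("window longer than series")
    if abs(float(w.sum()) - 1.0) > 1e-9:
        log.info("normalizing WMA weights %s -> %s", w, w / w.sum())
    w = w / w.sum()
    y = series.y
    fitted = np.full(n, np.nan)
    for t in range(k, n):
        fitted[t] = float(w @ y[t - k : t])
    fc = np.full(h, float(w @ y[-k:]))
    return _finalize(
        "weighted_moving_average", series, fitted, fc,
        {"k": k, "weights": tuple(float(x) for x in w)},
    )


@dataclass(frozen=True)
class ForecastConfig:
    """One candidate method with its tuning constants."""

    method: str
    alpha: float = 0.5
    beta: float = 0.5
    k: int = 3
    weights: tuple | None = None

    def run(self, series: AnnualSeries, h: int) -> ForecastResult:
        if self.method == "linear_regression":
            return linear_regression_forecast(series, h)
        if self.method == "holts":
            return holts_forecast(series, self.alpha, self.beta, h)
        if self.method == "exp_smoothing":
            return exp_smoothing_forecast(series, self.alpha, h)
        if self.method == "moving_average":
            return moving_average_forecast(series, self.k, h)
        if self.method == "weighted_moving_average":
            weights = self.weights if self.weights is not None else (1.0,) * self.k
            return weighted_moving_average_forecast(series, self.k, weights, h)
        raise ValueError(f"unknown forecasting method {self.method!r}")


def default_candidates() -> tuple[ForecastConfig, ...]:
    """The default battery: both trend methods and all three stationary ones."""
    return (
        ForecastConfig("linear_regression"),
        ForecastConfig("holts", alpha=0.5, beta=0.5),
        ForecastConfig("exp_smoothing", alpha=0.5),
        ForecastConfig("moving_average", k=3),
        ForecastConfig("weighted_moving_average", k=3, weights=(0.2, 0.3, 0.5)),
    )


def select_best_method(
    series: AnnualSeries, candidate_configs, h: int = 2
) -> ForecastResult:
    """Run every applicable candidate and return the one with minimal MAD.

    Candidates whose preconditions fail (series too short) are skipped;
    ties are broken by candidate order.
    """
    best: ForecastResult | None = None
    for cand in candidate_configs:
        try:
            result = cand.run(series, h)
        except ValueError as exc:
            log.info("candidate %s skipped: %s", cand.method, exc)
            continue
        if np.isnan(result.mad):
            log.info("candidate %s skipped: MAD undefined", cand.method)
            continue
        if best is None or result.mad < best.mad:
            best = result
    if best is None:
        raise ValueError("no applicable forecasting candidate for this series")
    return best
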