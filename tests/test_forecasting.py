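"""Forecasting battery: frozen hand oracles and selection properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pesuflow.forecasting import (
    AnnualSeries,
    ForecastConfig,
    default_candidates,
    exp_smoothing_forecast,
    holts_forecast,
    linear_regression_forecast,
    moving_average_forecast,
    select_best_method,
    weighted_moving_average_forecast,
)

YEARS5 = ("2012", "2013", "2014", "2015", "2016")


def test_linear_regression_on_exact_line():
    s = AnnualSeries(YEARS5, (10, 20, 30, 40, 50))
    r = linear_regression_forecast(s, 2)
    assert r.forecasts == pytest.approx([60.0, 70.0])
    assert r.mad == pytest.approx(0.0, abs=1e-9)


def test_linear_regression_hand_oracle():
    """Closed-form OLS on the alcohol-like series, frozen by hand:
    slope 138, intercept 1567.6, one-step extrapolation 2257.6, MAD 3.12."""
    s = AnnualSeries(YEARS5, (1_569, 1_700, 1_850, 1_980, 2_119))
    r = linear_regression_forecast(s, 1)
    assert r.params["slope"] == pytest.approx(138.0)
    assert r.forecasts[0] == pytest.approx(2_257.6)
    assert r.mad == pytest.approx(3.12)


def test_linear_regression_matches_statsmodels():
    import statsmodels.api as sm

    y = np.array([12.0, 19.0, 31.0, 38.0, 52.0])
    s = AnnualSeries(YEARS5, tuple(y))
    r = linear_regression_forecast(s, 1)
    x = sm.add_constant(np.arange(5.0))
    fit = sm.OLS(y, x).fit()
    assert r.params["intercept"] == pytest.approx(fit.params[0])
    assert r.params["slope"] == pytest.approx(fit.params[1])


def test_holt_hand_unrolled_recursion():
    """Three-step hand recursion: l3=145, b3=22.5, forecast 167.5, MAD 10."""
    s = AnnualSeries(("a", "b", "c"), (100, 120, 150))
    r = holts_forecast(s, 0.5, 0.5, 1)
    assert r.forecasts[0] == pytest.approx(167.5)
    assert r.mad == pytest.approx(10.0)


@pytest.mark.parametrize("alpha,beta", [(0.2, 0.3), (0.5, 0.5), (0.9, 0.1)])
def test_holt_is_exact_on_linear_series(alpha, beta):
    s = AnnualSeries(YEARS5, (7, 12, 17, 22, 27))
    r = holts_forecast(s, alpha, beta, 3)
    assert r.forecasts == pytest.approx([32.0, 37.0, 42.0])
    assert r.mad == pytest.approx(0.0, abs=1e-9)


def test_holt_rejects_bad_smoothing_constants():
    s = AnnualSeries(("a", "b"), (1, 2))
    with pytest.raises(ValueError):
        holts_forecast(s, 0.0, 0.5, 1)
    with pytest.raises(ValueError):
        holts_forecast(s, 0.5, 1.5, 1)


def test_exp_smoothing_alpha_one_returns_last_observation():
    s = AnnualSeries(YEARS5, (3, 9, 4, 8, 6))
    r = exp_smoothing_forecast(s, 1.0, 3)
    assert r.forecasts == pytest.approx([6.0, 6.0, 6.0])


def test_moving_average_flat_forecast():
    s = AnnualSeries(("a", "b", "c", "d"), (6, 6, 6, 6))
    r = moving_average_forecast(s, 3, 2)
    assert r.forecasts == pytest.approx([6.0, 6.0])
    with pytest.raises(ValueError, match="window longer"):
        moving_average_forecast(AnnualSeries(("a", "b"), (1, 2)), 3, 1)


def test_weighted_moving_average_hand_oracle():
    """w=(0.2,0.3,0.5) on (1,2,3): 0.2*1 + 0.3*2 + 0.5*3 = 2.3."""
    s = AnnualSeries(("a", "b", "c"), (1, 2, 3))
    r = weighted_moving_average_forecast(s, 3, (0.2, 0.3, 0.5), 1)
    assert r.forecasts[0] == pytest.approx(2.3)
    assert np.isnan(r.mad)  # window spans the whole series: no one-step errors


def test_weighted_moving_average_normalizes_raw_weights():
    s = AnnualSeries(YEARS5, (480, 490, 484, 486, 482))
    raw = weighted_moving_average_forecast(s, 3, (0.2, 8.0, 0.8), 1)
    normed = weighted_moving_average_forecast(
        s, 3, (0.2 / 9.0, 8.0 / 9.0, 0.8 / 9.0), 1
    )
    assert raw.forecasts[0] == pytest.approx(normed.forecasts[0])
    assert sum(raw.params["weights"]) == pytest.approx(1.0)


def test_negative_forecasts_are_clamped_and_flagged():
    s = AnnualSeries(("a", "b", "c"), (100, 60, 20))
    r = linear_regression_forecast(s, 3)
    assert r.clamped
    assert (r.forecasts >= 0).all()


def test_select_prefers_zero_mad_trend_method():
    s = AnnualSeries(YEARS5, (10, 20, 30, 40, 50))
    best = select_best_method(
        s, [ForecastConfig("moving_average", k=3), ForecastConfig("linear_regression")]
    )
    assert best.method == "linear_regression"
    assert best.mad == pytest.approx(0.0, abs=1e-9)


def test_select_tie_breaks_by_candidate_order():
    s = AnnualSeries(YEARS5, (5, 5, 5, 5, 5))
    best = select_best_method(
        s,
        [
            ForecastConfig("moving_average", k=3),
            ForecastConfig("linear_regression"),
            ForecastConfig("exp_smoothing", alpha=0.5),
        ],
    )
    assert best.method == "moving_average"  # every MAD is 0; first wins
    assert best.forecasts == pytest.approx([5.0, 5.0])


def test_select_picks_wma_on_stationary_series():
    """On a stationary, schizophrenia-like series the WMA one-step errors
    (hand-checkable) undercut the OLS residuals, so WMA is selected."""
    s = AnnualSeries(YEARS5, (492, 470, 485, 481, 484))
    w = (0.2, 0.3, 0.5)
    cands = [
        ForecastConfig("linear_regression"),
        ForecastConfig("weighted_moving_average", k=3, weights=w),
    ]
    best = select_best_method(s, cands)
    # independent hand computation of both MADs
    y = np.array(s.values, float)
    wma_fit = [np.dot(w, y[t - 3 : t]) for t in (3, 4)]
    wma_mad = np.mean(np.abs(y[3:] - wma_fit))
    slope, intercept = np.polyfit(np.arange(5.0), y, 1)
    lr_mad = np.mean(np.abs(y - (intercept + slope * np.arange(5.0))))
    assert wma_mad < lr_mad
    assert best.method == "weighted_moving_average"
    assert best.mad == pytest.approx(wma_mad)


def test_selection_invariant_to_candidate_reordering():
    s = AnnualSeries(YEARS5, (480, 510, 495, 505, 500))
    cands = list(default_candidates())
    a = select_best_method(s, cands)
    b = select_best_method(s, cands[::-1])
    assert a.mad == pytest.approx(b.mad)


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.floats(min_value=0, max_value=1e6), min_size=4, max_size=12)
)
def test_selection_is_a_pure_argmin(values):
    s = AnnualSeries(tuple(str(2000 + i) for i in range(len(values))), tuple(values))
    results = {}
    for cand in default_candidates():
        try:
            r = cand.run(s, 2)
        except ValueError:
            continue
        if not np.isnan(r.mad):
            results[cand.method] = r.mad
    best = select_best_method(s, default_candidates())
    assert best.mad == pytest.approx(min(results.values()))
    assert (best.forecasts >= 0).all()
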