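"""Engine correctness: analytic queueing oracles, conservation, determinism."""

import numpy as np
import pytest
from scipy import stats

from pesuflow import (
    RoutingSpec,
    ServiceSpec,
    SimulationParameters,
    run_experiment,
    run_replication,
    simulate_arrivals,
)
from pesuflow.taxonomy import PATIENT_CLASSES

from conftest import single_stream_params


def two_class_pesu_params(pesu_capacity=1, horizon=3000.0):
    """A small ED+PESU system with one NMHA and one fully eligible MHA class."""
    routing = RoutingSpec()
    for cls in ("NMHA", "schizophrenia"):
        routing.ctas_props[cls] = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        routing.dispo_props[(cls, None)] = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    service = {
        ("NMHA", None, None): ServiceSpec("NMHA", dist="exponential", mean=2.0),
        ("schizophrenia", None, None): ServiceSpec(
            "schizophrenia", dist="exponential", mean=2.0
        ),
    }
    return SimulationParameters(
        ed_beds=4,
        pesu_capacity=pesu_capacity,
        annual_rate={"NMHA": 8760.0, "schizophrenia": 0.3 * 8760.0},
        routing=routing,
        service=service,
        pesu_stay=(1.0, 2.0, 3.0),
        pesu_eligibility=1.0,
        service_scale=1.0,
        horizon_hours=horizon,
        warmup_hours=300.0,
    )


# ---------------------------------------------------------------------------
# Arrival process
# ---------------------------------------------------------------------------


def test_arrivals_ordered_and_bounded():
    rng = np.random.default_rng(0)
    times = simulate_arrivals(8760.0 / 58_947.0, 8760.0, rng)
    assert np.all(np.diff(times) > 0)
    assert times[-1] <= 8760.0
    # single replication count within a generous Poisson band
    assert abs(len(times) - 58_947) < 4 * np.sqrt(58_947)


def test_arrivals_edge_cases():
    rng = np.random.default_rng(1)
    assert len(simulate_arrivals(np.inf, 100.0, rng)) == 0
    with pytest.raises(ValueError):
        simulate_arrivals(0.0, 100.0, rng)
    with pytest.raises(ValueError):
        simulate_arrivals(-1.0, 100.0, rng)


def test_interarrival_gaps_are_exponential():
    rng = np.random.default_rng(2)
    times = simulate_arrivals(3.0, 4000.0, rng)
    gaps = np.diff(times)[:1000]
    assert stats.kstest(gaps, "expon", args=(0, 3.0)).pvalue > 0.01


# ---------------------------------------------------------------------------
# Queueing oracles
# ---------------------------------------------------------------------------


def test_mm1_sojourn_time():
    """Single bed, Poisson(0.7) arrivals, exp(1) service: E[LOS]=1/(1-0.7)."""
    params = single_stream_params(0.7, 1.0, beds=1, horizon=30_000.0, warmup=2_000.0)
    los = np.array(
        [run_replication(params, 300 + i).mean_los_overall for i in range(10)]
    )
    theory = 1.0 / (1.0 - 0.7)
    se = los.std(ddof=1) / np.sqrt(len(los))
    assert abs(los.mean() - theory) < 3 * se


def test_infinite_server_los_equals_service():
    """With capacity far above offered load, LOS collapses to E[T]."""
    params = single_stream_params(0.8, 1.0, beds=50)
    los = np.array([run_replication(params, 400 + i).mean_los_overall for i in range(5)])
    se = max(los.std(ddof=1) / np.sqrt(len(los)), 1e-4)
    assert abs(los.mean() - 1.0) < 3 * se


def test_zero_arrival_rates_yield_empty_kpis(baseline_params):
    params = baseline_params.replace(
        annual_rate={cls: 0.0 for cls in PATIENT_CLASSES}
    )
    r = run_replication(params, 0)
    assert sum(r.arrivals.values()) == 0
    assert r.pesu_treated == 0
    assert np.isnan(r.mean_los_overall)


def test_flow_conservation_per_class(baseline_params):
    """arrivals = departures + in-system-at-horizon, class by class."""
    params = baseline_params.replace(horizon_hours=2_000.0, warmup_hours=100.0)
    r = run_replication(params, 17)
    censored_by_class = {
        cls: r.arrivals[cls] - r.departures[cls] for cls in PATIENT_CLASSES
    }
    assert all(v >= 0 for v in censored_by_class.values())
    assert sum(censored_by_class.values()) == r.censored
    assert r.censored < 200  # in-system population, not a leak


def test_identical_seed_gives_identical_results(baseline_params):
    params = baseline_params.replace(horizon_hours=1_500.0, warmup_hours=100.0)
    a = run_replication(params, 9).kpi_row()
    b = run_replication(params, 9).kpi_row()
    for key, val in a.items():
        if isinstance(val, float) and np.isnan(val):
            assert np.isnan(b[key])
        else:
            assert b[key] == val


def test_pesu_capacity_monotonicity_under_crn():
    """More PESU spaces: share never lower, mean LOS never higher (paired)."""
    seeds = range(5)
    small = two_class_pesu_params(pesu_capacity=1)
    large = two_class_pesu_params(pesu_capacity=3)
    share_s, share_l, los_s, los_l = [], [], [], []
    for seed in seeds:
        a, b = run_replication(small, seed), run_replication(large, seed)
        share_s.append(a.pesu_share)
        share_l.append(b.pesu_share)
        los_s.append(a.mean_los_overall)
        los_l.append(b.mean_los_overall)
    assert np.mean(share_l) > np.mean(share_s)
    assert np.mean(los_l) <= np.mean(los_s) + 1e-9


def test_arrival_rate_monotonicity_under_crn():
    """Higher arrival rate cannot lower the mean LOS (paired seeds)."""
    lo = single_stream_params(0.5, 1.0, beds=1, horizon=4_000.0)
    hi = single_stream_params(0.8, 1.0, beds=1, horizon=4_000.0)
    lo_los = np.mean([run_replication(lo, s).mean_los_overall for s in range(5)])
    hi_los = np.mean([run_replication(hi, s).mean_los_overall for s in range(5)])
    assert hi_los > lo_los


def test_ctas_priority_mode_runs_and_conserves(baseline_params):
    params = baseline_params.replace(
        horizon_hours=1_000.0, warmup_hours=100.0, queue_discipline="ctas"
    )
    r = run_replication(params, 3)
    assert sum(r.arrivals.values()) == sum(r.departures.values()) + r.censored


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def test_run_experiment_requires_two_replications(baseline_params):
    with pytest.raises(ValueError, match="at least 2"):
        run_experiment(baseline_params, n_replications=1, base_seed=0)


def test_deterministic_system_zero_width_ci():
    """Deterministic service, ample capacity and a deterministic LOS: the
    per-replication mean LOS is constant, so the CI width is zero."""
    params = single_stream_params(
        0.2, 2.0, beds=50, dist="deterministic", horizon=2_000.0, warmup=200.0
    )
    report = run_experiment(params, n_replications=5, base_seed=0)
    mean, lo, hi, _ = report.summary["mean_los_overall"]
    assert mean == pytest.approx(2.0)
    assert hi - lo == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "changes",
    [
        {"ed_beds": 0},
        {"service_scale": 0.0},
        {"service_scale": 1.2},
        {"pesu_stay": (5.0, 2.0, 10.0)},
        {"pesu_capacity": -1},
        {"warmup_hours": 9000.0},
        {"queue_discipline": "lifo"},
    ],
)
def test_invalid_parameters_rejected(baseline_params, changes):
    with pytest.raises(ValueError):
        baseline_params.replace(**changes).validate()


def test_parameter_serialization_roundtrip(baseline_params):
    data = baseline_params.to_dict()
    back = SimulationParameters.from_dict(data)
    assert back.to_dict() == data
    r1 = run_replication(baseline_params.replace(horizon_hours=800.0), 5)
    r2 = run_replication(back.replace(horizon_hours=800.0), 5)
    assert r1.kpi_row()["arrivals_NMHA"] == r2.kpi_row()["arrivals_NMHA"]
    with pytest.raises(ValueError, match="schema"):
        SimulationParameters.from_dict({**data, "schema_version": "bogus"})
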