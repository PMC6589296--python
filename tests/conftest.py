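"""Shared fixtures: the default synthetic world and small analytic systems."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pesuflow import (
    RoutingSpec,
    ServiceSpec,
    SimulationParameters,
    calibrate_baseline,
    default_parameter_set,
    default_synthetic_config,
    generate_visit_history,
)


@pytest.fixture(scope="session")
def default_config():
    return default_synthetic_config()


@pytest.fixture(scope="session")
def history(default_config):
    """Full five-year synthetic visit table (~300k records), seed 1."""
    return generate_visit_history(default_config, seed=1)


@pytest.fixture(scope="session")
def baseline_params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def calibrated_baseline():
    """Calibrated baseline parameters plus the convergence report."""
    params, report = calibrate_baseline(default_parameter_set(), base_seed=1)
    return params, report


def single_stream_params(
    arrivals_per_hour: float,
    mean_service: float = 1.0,
    beds: int = 1,
    dist: str = "exponential",
    horizon: float = 8760.0,
    warmup: float = 500.0,
) -> SimulationParameters:
    """A one-class ED with no PESU: an M/G/c queue with LOS = wait + T."""
    routing = RoutingSpec()
    routing.ctas_props["NMHA"] = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    routing.dispo_props[("NMHA", None)] = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    return SimulationParameters(
        ed_beds=beds,
        pesu_capacity=0,
        annual_rate={"NMHA": arrivals_per_hour * 8760.0},
        routing=routing,
        service={
            ("NMHA", None, None): ServiceSpec("NMHA", dist=dist, mean=mean_service)
        },
        pesu_eligibility=0.0,
        service_scale=1.0,
        horizon_hours=horizon,
        warmup_hours=warmup,
    )
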