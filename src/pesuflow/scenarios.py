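"""Scenario experiments A-E as pure transformations of the calibrated baseline.

* **A** — demand forecast: every class's annual rate is replaced by its
  forecast for fiscal 2017/2018 (substance subgroup rates scale by the
  common factor forecast/base, since demand is forecast for the substance
  aggregate only).
* **B** — addiction-medicine diversion: alcohol and opioid rates reduced by
  10/30/45/63%.  Scaling a Poisson stream's rate is distributionally
  equivalent to random removal of each arrival with that probability.
* **C** — cannabis legalization: +19% in year 1, then -27% applied to the
  year-1 level (the sequential reading of the legalization history this
  scenario mimics; ``sequential=False`` applies -27% to the base instead).
* **D** — PESU capacity increased from 6 to 7..10 spaces.
* **E** — composition of A's rates with D's capacities.

``run_scenario`` executes a configuration with the same replication seeds
as the baseline, so per-replication differences are paired under common
random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .des_engine import SimulationParameters, run_experiment
from .kpi_reporting import KPIReport
from .taxonomy import SUBSTANCE_SUBGROUPS

#: Published demand forecasts (visits/year) used as scenario-A defaults.
DEFAULT_FORECASTS: dict[str, dict[str, float]] = {
    "2017": {
        "NMHA": 61_995.0,
        "substance": 3_206.0,
        "schizophrenia": 486.0,
        "mood": 1_027.0,
        "anxiety": 1_424.0,
        "others": 159.0,
    },
    "2018": {
        "NMHA": 63_800.0,
        "substance": 3_471.0,
        "schizophrenia": 486.0,
        "mood": 1_131.0,
        "anxiety": 1_467.0,
        "others": 177.0,
    },
}

_FORECAST_CLASSES = ("NMHA", "substance", "schizophrenia", "mood", "anxiety", "others")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named, declarative adjustment of the baseline parameters."""

    scenario_id: str
    rate_overrides: dict = field(default_factory=dict)  # class -> visits/year
    pesu_capacity: int | None = None

    def apply(self, params: SimulationParameters) -> SimulationParameters:
        """Return adjusted parameters; the baseline is never mutated."""
        for cls, rate in self.rate_overrides.items():
            if rate < 0:
                raise ValueError(f"negative rate override for {cls!r}")
        rates = dict(params.annual_rate)
        rates.update({k: float(v) for k, v in self.rate_overrides.items()})
        changes: dict = {"annual_rate": rates}
        if self.pesu_capacity is not None:
            changes["pesu_capacity"] = int(self.pesu_capacity)
        out = params.replace(**changes)
        out.validate()
        return out


def _substance_total(params: SimulationParameters) -> float:
    return sum(params.annual_rate.get(sub, 0.0) for sub in SUBSTANCE_SUBGROUPS)


def _forecast_overrides(params: SimulationParameters, forecasts: dict) -> dict:
    missing = [c for c in _FORECAST_CLASSES if c not in forecasts]
    if missing:
        raise ValueError(f"forecast table missing classes: {missing}")
    overrides = {
        cls: float(forecasts[cls])
        for cls in _FORECAST_CLASSES
        if cls != "substance"
    }
    base_sub = _substance_total(params)
    if base_sub <= 0:
        raise ValueError("baseline has no substance demand to scale")
    factor = float(forecasts["substance"]) / base_sub
    for sub in SUBSTANCE_SUBGROUPS:
        overrides[sub] = params.annual_rate.get(sub, 0.0) * factor
    return overrides


def build_scenario_A(
    params: SimulationParameters, forecast_table: dict | None = None
) -> list[ScenarioConfig]:
    """Demand-forecast scenarios for fiscal 2017 and 2018."""
    table = DEFAULT_FORECASTS if forecast_table is None else forecast_table
    return [
        ScenarioConfig(f"A{year}", _forecast_overrides(params, table[year]))
        for year in sorted(table)
    ]


def build_scenario_B(params: SimulationParameters, reduction_pct: float) -> ScenarioConfig:
    """Reduce alcohol and opioid arrival rates by ``reduction_pct`` percent."""
    if not (0 < reduction_pct < 100):
        raise ValueError("reduction_pct must lie in (0, 100)")
    keep = 1.0 - reduction_pct / 100.0
    overrides = {
        sub: params.annual_rate.get(sub, 0.0) * keep for sub in ("alcohol", "opioid")
    }
    return ScenarioConfig(f"B{int(reduction_pct)}", overrides)


def build_scenario_C(
    params: SimulationParameters, sequential: bool = True
) -> list[ScenarioConfig]:
    """Cannabis-legalization scenarios: +19% (year 1), -27% (year 2)."""
    base = params.annual_rate.get("cannabis", 0.0)
    year1 = base * 1.19
    year2 = (year1 if sequential else base) * (1.0 - 0.27)
    return [
        ScenarioConfig("C_year1", {"cannabis": year1}),
        ScenarioConfig("C_year2", {"cannabis": year2}),
    ]


def build_scenario_D(params: SimulationParameters, beds: int) -> ScenarioConfig:
    """Increase PESU capacity; only additions over the current size are valid."""
    if beds <= params.pesu_capacity:
        raise ValueError(
            f"scenario D only adds PESU spaces (current {params.pesu_capacity}, got {beds})"
        )
    return ScenarioConfig(f"D{beds}", {}, pesu_capacity=beds)


def build_scenario_E(
    params: SimulationParameters, forecast_table: dict | None = None, beds: int = 7
) -> list[ScenarioConfig]:
    """Compose A's demand adjustments with D's capacity override."""
    capacity = build_scenario_D(params, beds).pesu_capacity
    return [
        ScenarioConfig(
            cfg.scenario_id.replace("A", "E") + f"_{beds}",
            cfg.rate_overrides,
            pesu_capacity=capacity,
        )
        for cfg in build_scenario_A(params, forecast_table)
    ]


def scenario_suite(params: SimulationParameters) -> list[ScenarioConfig]:
    """All published experiments: A (2), B (4), C (2), D (4), E (8)."""
    configs = list(build_scenario_A(params))
    configs += [build_scenario_B(params, pct) for pct in (10, 30, 45, 63)]
    configs += build_scenario_C(params)
    configs += [build_scenario_D(params, beds) for beds in (7, 8, 9, 10)]
    for beds in (7, 8, 9, 10):
        configs += build_scenario_E(params, beds=beds)
    return configs


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    report: KPIReport
    deltas: pd.DataFrame  # per-replication paired differences vs baseline

    def summary_row(self) -> dict:
        row = {"scenario": self.config.scenario_id}
        for kpi in ("mean_los_overall", "pesu_share"):
            mean, lo, hi, _ = self.report.summary[kpi]
            row[kpi] = mean
            row[f"{kpi}_ci_lower"] = lo
            row[f"{kpi}_ci_upper"] = hi
            row[f"{kpi}_delta"] = float(self.deltas[kpi].mean())
        return row


def run_scenario(
    config: ScenarioConfig,
    calibrated_params: SimulationParameters,
    n_reps: int | None = None,
    base_seed: int | None = None,
    baseline_report: KPIReport | None = None,
) -> ScenarioResult:
    """Run one scenario with replication seeds shared with the baseline."""
    n = calibrated_params.n_replications if n_reps is None else int(n_reps)
    seed0 = calibrated_params.base_seed if base_seed is None else int(base_seed)
    if baseline_report is None:
        baseline_report = run_experiment(calibrated_params, n, seed0)
    scen_params = config.apply(calibrated_params)
    report = run_experiment(scen_params, n, seed0)
    return ScenarioResult(config, report, report.paired_deltas(baseline_report))


def comparison_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Combined scenario table: mean LOS and PESU share with CIs and deltas."""
    return pd.DataFrame([r.summary_row() for r in results])
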