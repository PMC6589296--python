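"""ICD grouping and simulation-input fitting."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pesuflow import (
    annual_summary,
    categorize_icd,
    estimate_proportions,
    fit_interarrival,
    fit_service,
    fit_simulation_inputs,
)
from pesuflow.taxonomy import CATEGORIES, SUBSTANCE_SUBGROUPS


@pytest.mark.parametrize(
    "code, expected",
    [
        ("F10", ("substance", "alcohol")),
        ("F10.1", ("substance", "alcohol")),
        ("F11", ("substance", "opioid")),
        ("F12.5", ("substance", "cannabis")),
        ("F19.2", ("substance", "multiple")),
        ("F13", ("substance", "other")),
        ("F17.2", ("substance", "other")),
        ("F55", ("substance", "other")),
        ("F20", ("schizophrenia", "none")),
        ("F20.4", ("NMHA", "none")),  # post-schizophrenic depression excluded
        ("F20.9", ("schizophrenia", "none")),
        ("F25.1", ("schizophrenia", "none")),
        ("F26", ("NMHA", "none")),
        ("F29", ("schizophrenia", "none")),
        ("F30", ("mood", "none")),
        ("F35", ("NMHA", "none")),
        ("F39", ("mood", "none")),
        ("F40", ("anxiety", "none")),
        ("F45.2", ("anxiety", "none")),
        ("F46", ("NMHA", "none")),
        ("F48", ("anxiety", "none")),
        ("F50", ("others", "none")),
        ("F60.3", ("others", "none")),
        ("F62", ("NMHA", "none")),
        ("F67", ("NMHA", "none")),
        ("F69", ("others", "none")),
        ("X59", ("NMHA", "none")),
        ("X60", ("others", "none")),
        ("X84", ("others", "none")),
        ("X85", ("NMHA", "none")),
        ("K35", ("NMHA", "none")),
        ("J18.9", ("NMHA", "none")),
    ],
)
def test_categorize_icd(code, expected):
    assert categorize_icd(code) == expected


@pytest.mark.parametrize("bad", ["", "  ", "F", "1F0", "10", "F10.1.2", "F1"])
def test_categorize_icd_rejects_malformed(bad):
    with pytest.raises(ValueError):
        categorize_icd(bad)


@settings(max_examples=300, deadline=None)
@given(
    letter=st.sampled_from("ABCFJKMRSTXZ"),
    digits=st.integers(0, 99),
    decimal=st.one_of(st.none(), st.integers(0, 9)),
)
def test_categorize_icd_total_and_partitioning(letter, digits, decimal):
    """Every well-formed code maps to exactly one category; substance codes
    and only substance codes carry a subgroup."""
    code = f"{letter}{digits:02d}" + ("" if decimal is None else f".{decimal}")
    cat, sub = categorize_icd(code)
    assert cat in CATEGORIES
    if cat == "substance":
        assert sub in SUBSTANCE_SUBGROUPS
    else:
        assert sub == "none"
    # deterministic and idempotent
    assert categorize_icd(code) == (cat, sub)


def _records(rows):
    return pd.DataFrame(
        rows, columns=["category", "substance_subgroup", "ctas", "disposition", "los_hours"]
    )


def test_fit_interarrival_arithmetic():
    df = _records([("NMHA", "none", 3, "discharged", 5.0)] * 10)
    spec = fit_interarrival(df, "NMHA", 8760.0)
    assert spec.mean_interarrival == pytest.approx(876.0)
    single = _records([("NMHA", "none", 3, "discharged", 5.0)])
    assert fit_interarrival(single, "NMHA", 8760.0).mean_interarrival == 8760.0
    with pytest.raises(ValueError, match="no records"):
        fit_interarrival(df, "mood", 8760.0)


def test_fit_interarrival_recovers_poisson_rate():
    """MLE = sample mean: recovery within 3 SE on a synthetic stream."""
    rng = np.random.default_rng(11)
    n = 10_000
    mean = 0.1486
    horizon = float(np.sum(rng.exponential(mean, n)))
    df = _records([("NMHA", "none", 3, "discharged", 1.0)] * n)
    spec = fit_interarrival(df, "NMHA", horizon)
    se = mean / np.sqrt(n)
    assert abs(spec.mean_interarrival - mean) < 3 * se


def test_fit_service_moment_oracle():
    """Recover lognormal(mu=1, sigma=0.5) parameters from 10,000 draws."""
    rng = np.random.default_rng(5)
    x = rng.lognormal(1.0, 0.5, 10_000)
    df = _records(
        [("mood", "none", 3, "discharged", v) for v in x]
    )
    spec = fit_service(df, "mood", method="moments")
    assert spec.mu == pytest.approx(1.0, abs=0.05)
    assert spec.sigma == pytest.approx(0.5, abs=0.05)
    assert spec.mean == pytest.approx(float(np.mean(x)), rel=1e-9)
    mle = fit_service(df, "mood", method="log-mle")
    assert mle.mu == pytest.approx(1.0, abs=3 * 0.5 / np.sqrt(10_000))


def test_fit_service_degenerate_sample():
    df = _records([("anxiety", "none", 3, "discharged", 4.0)] * 5)
    spec = fit_service(df, "anxiety")
    assert spec.degenerate
    assert spec.sigma == 0.0
    assert spec.mean == pytest.approx(4.0)


def test_fit_service_sparse_stratum_falls_back(caplog):
    rows = [("mood", "none", 3, "discharged", v) for v in (2.0, 4.0, 8.0, 16.0)]
    rows.append(("mood", "none", 1, "admitted", 30.0))  # lone stratum record
    df = _records(rows)
    with caplog.at_level(logging.INFO, logger="pesuflow.input_modelling"):
        spec = fit_service(df, "mood", ctas=1, disposition="admitted")
    assert "falling back" in caplog.text
    class_level = fit_service(df, "mood")
    assert spec.mean == pytest.approx(class_level.mean)
    with pytest.raises(ValueError, match="need >= 2 records"):
        fit_service(_records(rows[:1]), "mood")


def test_estimate_proportions_trivial_and_errors():
    df = _records([("NMHA", "none", 3, "discharged", 1.0)] * 4)
    with pytest.raises(ValueError, match="no records"):
        estimate_proportions(df)  # other classes absent


def test_estimate_proportions_recovers_configured_mix(default_config, history):
    spec = estimate_proportions(history)
    n = int((history["category"] == "NMHA").sum())
    for p_hat, p in zip(spec.ctas_props["NMHA"], default_config.ctas_props["NMHA"]):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se + 1e-12
    vec = spec.dispo_props[("NMHA", None)]
    assert vec.sum() == pytest.approx(1.0, abs=1e-12)
    for p_hat, p in zip(vec, default_config.dispo_props["NMHA"]):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se + 1e-12


def test_annual_summary_counts(history):
    table = annual_summary(history)
    assert table.loc[("substance", "all"), "2016"] == 2_879
    assert table.loc[("substance", "alcohol"), "2016"] == 2_119
    assert table.loc[("MHA", "all"), "2016"] == 6_131
    # subgroup counts always sum to the substance total
    for year in ("2012", "2013", "2014", "2015", "2016", "total"):
        subs = sum(
            table.loc[("substance", s), year]
            for s in SUBSTANCE_SUBGROUPS
            if ("substance", s) in table.index
        )
        assert subs == table.loc[("substance", "all"), year]


def test_annual_summary_single_record():
    df = pd.DataFrame(
        {
            "category": ["mood"],
            "substance_subgroup": ["none"],
            "fiscal_year": ["2016"],
        }
    )
    table = annual_summary(df)
    assert table.loc[("mood", "all"), "2016"] == 1


def test_fit_simulation_inputs_roundtrip(history):
    """Fitting the synthetic extract recovers rates and LOS means."""
    params = fit_simulation_inputs(history, "2016")
    assert params.annual_rate["NMHA"] == 58_947
    assert params.annual_rate["schizophrenia"] == 484
    fitted = params.service[("schizophrenia", None, None)]
    n = int((history["category"] == "schizophrenia").sum())
    assert fitted.mean == pytest.approx(14.4, abs=3 * 14.4 / np.sqrt(n))
    with pytest.raises(ValueError, match="no records in fiscal year"):
        fit_simulation_inputs(history, "1999")
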