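"""ICD-10 visit grouping and simulation-input fitting.

Two responsibilities live here:

* :func:`categorize_icd` — the deterministic mapping from an ICD-10 main
  problem code to the (category, substance subgroup) pair used throughout
  the pipeline.  Membership is decided on the 3-character root (letter +
  two digits); the F20.4 exclusion from the schizophrenia group is tested
  before the F20 inclusion.
* Input fitting — exponential interarrival means (the MLE under a Poisson
  arrival model is observation time over count), lognormal ED-bed time
  distributions per (class, acuity, disposition) stratum with hierarchical
  fallback for sparse strata, and empirical acuity/disposition routing
  proportions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import (
    CTAS_LEVELS,
    DISPOSITIONS,
    PATIENT_CLASSES,
    SUBSTANCE_SUBGROUPS,
    patient_class_of,
)

log = logging.getLogger(__name__)

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}(?:[0-9]{1,4}|\.[0-9A-Z]{1,4})?$")

# Substance subgroup by 3-character root.
_SUBSTANCE_ROOTS = {
    "F10": "alcohol",
    "F11": "opioid",
    "F12": "cannabis",
    "F19": "multiple",
    # F13-F18 (sedatives, cocaine, stimulants, hallucinogens, tobacco,
    # volatile solvents) and F55 (non-dependence-producing substances)
    # fall in the residual "other" subgroup.
    "F13": "other",
    "F14": "other",
    "F15": "other",
    "F16": "other",
    "F17": "other",
    "F18": "other",
    "F55": "other",
}

_SCHIZOPHRENIA_ROOTS = {"F20", "F21", "F22", "F23", "F24", "F25", "F28", "F29"}
_MOOD_ROOTS = {"F30", "F31", "F32", "F33", "F34", "F39"}
_ANXIETY_ROOTS = {"F40", "F41", "F42", "F43", "F44", "F45", "F48"}
_OTHERS_ROOTS = (
    {"F50", "F51", "F52", "F53", "F54", "F59", "F60"}
    | {"F63", "F64", "F65", "F66", "F68", "F69"}
    | {f"X{n}" for n in range(60, 85)}  # intentional self-harm X60-X84
)


def categorize_icd(icd_code: str) -> tuple[str, str]:
    """Map an ICD-10 code to its (category, substance_subgroup) pair.

    The subgroup is ``"none"`` for every non-substance category.  Raises
    :class:`ValueError` for empty or malformed codes.
    """
    if not isinstance(icd_code, str) or not icd_code.strip():
        raise ValueError(f"empty ICD-10 code: {icd_code!r}")
    code = icd_code.strip().upper()
    if not _ICD_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {icd_code!r}")
    root = code[:3]

    if root in _SUBSTANCE_ROOTS:
        return "substance", _SUBSTANCE_ROOTS[root]
    if root in _SCHIZOPHRENIA_ROOTS:
        # Schizotypal grouping excludes F20.4 (post-schizophrenic depression).
        if code.startswith("F20.4") or code.startswith("F204"):
            return "NMHA", "none"
        return "schizophrenia", "none"
    if root in _MOOD_ROOTS:
        return "mood", "none"
    if root in _ANXIETY_ROOTS:
        return "anxiety", "none"
    if root in _OTHERS_ROOTS:
        return "others", "none"
    return "NMHA", "none"


# ---------------------------------------------------------------------------
# Fitted-input containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrivalSpec:
    """Homogeneous Poisson arrival stream for one patient class."""

    patient_class: str
    mean_interarrival: float  # hours

    def __post_init__(self) -> None:
        if not self.mean_interarrival > 0:
            raise ValueError("mean_interarrival must be positive")

    @property
    def annual_rate(self) -> float:
        from .taxonomy import HOURS_PER_YEAR

        return HOURS_PER_YEAR / self.mean_interarrival


@dataclass(frozen=True)
class ServiceSpec:
    """Total ED treatment-time requirement distribution for one stratum.

    ``dist`` is ``"lognormal"`` (location ``mu``, scale ``sigma`` on the log
    scale) for fitted inputs; ``"exponential"`` and ``"deterministic"`` are
    available so the engine can be exercised against analytic queueing
    oracles.
    """

    patient_class: str
    ctas: int | None = None
    disposition: str | None = None
    dist: str = "lognormal"
    mu: float = 0.0
    sigma: float = 0.0
    mean: float = 1.0  # implied mean, hours
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "exponential", "deterministic"):
            raise ValueError(f"unknown service distribution {self.dist!r}")
        if self.sigma < 0 or not self.mean > 0:
            raise ValueError("service spec needs sigma >= 0 and mean > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "lognormal":
            return rng.lognormal(self.mu, self.sigma, n)
        if self.dist == "exponential":
            return rng.exponential(self.mean, n)
        return np.full(n, self.mean)


@dataclass
class RoutingSpec:
    """Empirical acuity and disposition mixes.

    ``ctas_props[cls]`` is a 5-vector over CTAS 1..5; ``dispo_props`` is
    keyed by ``(cls, ctas)`` with a ``(cls, None)`` class-level fallback
    entry, each a 5-vector over :data:`~pesuflow.taxonomy.DISPOSITIONS`.
    """

    ctas_props: dict[str, np.ndarray] = field(default_factory=dict)
    dispo_props: dict[tuple[str, int | None], np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for key, vec in self.ctas_props.items():
            if abs(float(np.sum(vec)) - 1.0) > 1e-9 or np.any(np.asarray(vec) < 0):
                raise ValueError(f"CTAS proportions for {key!r} do not sum to 1")
        for key, vec in self.dispo_props.items():
            if abs(float(np.sum(vec)) - 1.0) > 1e-9 or np.any(np.asarray(vec) < 0):
                raise ValueError(f"disposition proportions for {key!r} do not sum to 1")

    def dispo_for(self, patient_class: str, ctas: int) -> np.ndarray:
        try:
            return self.dispo_props[(patient_class, ctas)]
        except KeyError:
            return self.dispo_props[(patient_class, None)]


# ---------------------------------------------------------------------------
# Fitting operations
# ---------------------------------------------------------------------------


def _with_class(records: pd.DataFrame) -> pd.DataFrame:
    if "patient_class" in records.columns:
        return records
    out = records.copy()
    out["patient_class"] = [
        patient_class_of(c, s)
        for c, s in zip(records["category"], records["substance_subgroup"])
    ]
    return out


def fit_interarrival(
    records: pd.DataFrame, patient_class: str, observation_hours: float
) -> ArrivalSpec:
    """Exponential interarrival fit: observation time over arrival count."""
    if observation_hours <= 0:
        raise ValueError("observation_hours must be positive")
    n = int((_with_class(records)["patient_class"] == patient_class).sum())
    if n == 0:
        raise ValueError(f"no records of class {patient_class!r} to fit arrivals")
    return ArrivalSpec(patient_class, observation_hours / n)


def _lognormal_from_sample(x: np.ndarray, method: str) -> tuple[float, float, float, bool]:
    """Return (mu, sigma, implied mean, degenerate flag)."""
    m = float(np.mean(x))
    if m <= 0:
        raise ValueError("LOS sample has non-positive mean")
    v = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
    if method == "moments":
        if v <= 0:
            return float(np.log(m)), 0.0, m, True
        sigma2 = float(np.log1p(v / m**2))
        return float(np.log(m)) - sigma2 / 2.0, float(np.sqrt(sigma2)), m, False
    if method == "log-mle":
        logs = np.log(x)
        mu = float(np.mean(logs))
        sigma = float(np.std(logs, ddof=1)) if x.size > 1 else 0.0
        return mu, sigma, float(np.exp(mu + sigma**2 / 2.0)), sigma == 0.0
    raise ValueError(f"unknown fitting method {method!r}")


def fit_service(
    records: pd.DataFrame,
    patient_class: str,
    ctas: int | None = None,
    disposition: str | None = None,
    method: str = "moments",
    min_records: int = 2,
) -> ServiceSpec:
    """Lognormal fit to ``los_hours`` in a (class, CTAS, disposition) stratum.

    Sparse strata fall back hierarchically: class x ctas x disposition ->
    class x disposition -> class; each fallback is logged.  The default is a
    method-of-moments fit; ``method="log-mle"`` fits the Gaussian MLE on
    log-LOS instead.
    """
    df = _with_class(records)
    df = df[df["patient_class"] == patient_class]
    if len(df) < min_records:
        raise ValueError(
            f"need >= {min_records} records of class {patient_class!r}, got {len(df)}"
        )

    levels: list[tuple[int | None, str | None]] = [(ctas, disposition)]
    if ctas is not None and disposition is not None:
        levels.append((None, disposition))
    if disposition is not None:
        levels.append((None, None))

    for used_ctas, used_dispo in levels:
        sel = df
        if used_ctas is not None:
            sel = sel[sel["ctas"] == used_ctas]
        if used_dispo is not None:
            sel = sel[sel["disposition"] == used_dispo]
        if len(sel) >= min_records:
            if (used_ctas, used_dispo) != (ctas, disposition):
                log.info(
                    "sparse stratum (%s, ctas=%s, dispo=%s): falling back to "
                    "(ctas=%s, dispo=%s) with %d records",
                    patient_class, ctas, disposition, used_ctas, used_dispo, len(sel),
                )
            x = sel["los_hours"].to_numpy(dtype=float)
            mu, sigma, mean, degenerate = _lognormal_from_sample(x, method)
            if degenerate:
                log.warning(
                    "degenerate LOS fit for (%s, %s, %s): zero variance, mean %.3f h",
                    patient_class, ctas, disposition, mean,
                )
            return ServiceSpec(
                patient_class, ctas, disposition, "lognormal", mu, sigma, mean, degenerate
            )
    raise ValueError(
        f"stratum ({patient_class!r}, ctas={ctas}, dispo={disposition!r}) "
        f"has fewer than {min_records} records at every fallback level"
    )


def estimate_proportions(records: pd.DataFrame) -> RoutingSpec:
    """Empirical CTAS and disposition frequencies for every patient class."""
    df = _with_class(records)
    spec = RoutingSpec()
    for cls, grp in df.groupby("patient_class", sort=False):
        ctas_counts = grp["ctas"].value_counts()
        vec = np.array([ctas_counts.get(level, 0) for level in CTAS_LEVELS], float)
        spec.ctas_props[str(cls)] = vec / vec.sum()
        dispo_counts = grp["disposition"].value_counts()
        dvec = np.array([dispo_counts.get(d, 0) for d in DISPOSITIONS], float)
        spec.dispo_props[(str(cls), None)] = dvec / dvec.sum()
        for level, sub in grp.groupby("ctas"):
            sub_counts = sub["disposition"].value_counts()
            svec = np.array([sub_counts.get(d, 0) for d in DISPOSITIONS], float)
            spec.dispo_props[(str(cls), int(level))] = svec / svec.sum()
    missing = [cls for cls in PATIENT_CLASSES if cls not in spec.ctas_props]
    if missing:
        raise ValueError(f"no records for patient classes {missing}")
    spec.validate()
    return spec


def annual_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Visit counts per (fiscal_year, category, substance_subgroup).

    Returns a table indexed by (category, substance_subgroup) with one
    column per fiscal year plus a ``total`` column.  Aggregate rows are
    included for the substance category (sum of its subgroups), the MHA
    group, and the grand total.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    counts = (
        records.groupby(["category", "substance_subgroup", "fiscal_year"])
        .size()
        .unstack("fiscal_year", fill_value=0)
    )
    counts.columns = [str(c) for c in counts.columns]

    rows: dict[tuple[str, str], pd.Series] = {}
    for cat in ("NMHA", "substance", "schizophrenia", "mood", "anxiety", "others"):
        if cat == "substance":
            for sub in SUBSTANCE_SUBGROUPS:
                if ("substance", sub) in counts.index:
                    rows[("substance", sub)] = counts.loc[("substance", sub)]
            subs = [r for r in rows if r[0] == "substance"]
            if subs:
                rows[("substance", "all")] = sum(rows[r] for r in subs)
        elif (cat, "none") in counts.index:
            rows[(cat, "all")] = counts.loc[(cat, "none")]
    mha = [r for r in rows if r[1] == "all" and r[0] != "NMHA"]
    if mha:
        rows[("MHA", "all")] = sum(rows[r] for r in mha)
    rows[("ALL", "all")] = sum(
        rows[r] for r in rows if r[1] == "all" and r[0] in ("NMHA", "MHA")
    )

    table = pd.DataFrame(rows).T.fillna(0).astype(int)
    table.index.names = ["category", "substance_subgroup"]
    table = table[sorted(table.columns)]
    table["total"] = table.sum(axis=1)
    return table


def fit_simulation_inputs(
    records: pd.DataFrame,
    fiscal_year: str,
    base_params=None,
    method: str = "moments",
):
    """Build a :class:`~pesuflow.des_engine.SimulationParameters` from records.

    Arrival rates come from the chosen fiscal year; routing proportions and
    per-(class, disposition) service distributions are fitted on the full
    table.  Capacities and PESU-side parameters are taken from
    ``base_params`` (default parameter set when omitted).
    """
    from .des_engine import SimulationParameters
    from .synthetic_data import default_parameter_set
    from .taxonomy import HOURS_PER_YEAR

    if base_params is None:
        base_params = default_parameter_set()
    df = _with_class(records)
    year = df[df["fiscal_year"].astype(str) == str(fiscal_year)]
    if year.empty:
        raise ValueError(f"no records in fiscal year {fiscal_year!r}")

    rates = {
        cls: float((year["patient_class"] == cls).sum()) for cls in PATIENT_CLASSES
    }
    routing = estimate_proportions(df)
    service: dict[tuple[str, int | None, str | None], ServiceSpec] = {}
    for cls in PATIENT_CLASSES:
        service[(cls, None, None)] = fit_service(df, cls, method=method)
        for dispo in DISPOSITIONS:
            try:
                service[(cls, None, dispo)] = fit_service(
                    df, cls, disposition=dispo, method=method
                )
            except ValueError:
                log.info("no records for (%s, %s); class-level fit applies", cls, dispo)

    params = base_params.replace(annual_rate=rates, routing=routing, service=service)
    params.validate()
    return params
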