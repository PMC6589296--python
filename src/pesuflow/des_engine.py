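"""Discrete-event simulation of ED/PESU patient flow.

The model is an event-driven queueing network with two finite resources:

* a pool of ED beds (default 32) served by a single FIFO queue, and
* the PESU (psychiatric emergency services unit, default 6 spaces).

Every arrival belongs to one of ten patient classes (NMHA, the five
substance subgroups, schizophrenia, mood, anxiety, others) and samples an
acuity level, a discharge disposition and a total treatment requirement
``T`` from the fitted input distributions.  The flow contract:

* NMHA patients (and MHA patients who are PESU-ineligible or blocked) join
  the ED queue.  A bed is held for ``service_scale * T`` — the remainder of
  the requirement (initial assessment, waiting-room phases) does not occupy
  a stretcher — and the visit's LOS is ``wait + T``.
* An eligible MHA arrival who finds a free PESU space enters it directly
  and stays a triangular-distributed time; that stay is the visit's LOS.
* An eligible MHA arrival who finds the PESU full follows the ED path *and*
  joins a FIFO transfer list.  If a PESU space frees before their ED
  discharge they release any held ED bed immediately, move to the PESU for
  a freshly drawn stay, and count as PESU-treated.

KPIs accumulate only for patients arriving after the warm-up period;
arrival counts are reported over the full horizon.  Patients still in the
system at the horizon are censored.  Each (parameters, seed) pair is fully
reproducible: every class has its own arrival and attribute random streams,
so scenarios that perturb one class or only a capacity remain comparable
under common random numbers.
"""

from __future__ import annotations

import copy
import heapq
from collections import deque
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable

import numpy as np

from .input_modelling import ArrivalSpec, RoutingSpec, ServiceSpec
from .taxonomy import (
    CTAS_LEVELS,
    DISPOSITIONS,
    HOURS_PER_YEAR,
    MHA_CLASSES,
    PATIENT_CLASSES,
)

_EVT_ARRIVAL, _EVT_BED_FREE, _EVT_ED_DISCHARGE, _EVT_PESU_DEPART = range(4)

SCHEMA_VERSION = "pesuflow-params-1"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class SimulationParameters:
    """Complete input set for one simulation experiment.

    ``annual_rate`` is in visits per (8,760 h) year per patient class;
    ``pesu_eligibility`` maps each MHA class to the probability that an
    arrival of that class is medically stable and unmonitored (a scalar is
    broadcast to all MHA classes); ``service_scale`` is the fraction of the
    treatment requirement spent holding an ED bed.
    """

    ed_beds: int = 32
    pesu_capacity: int = 6
    annual_rate: dict = field(default_factory=dict)
    routing: RoutingSpec = field(default_factory=RoutingSpec)
    service: dict = field(default_factory=dict)
    pesu_stay: tuple = (2.0, 8.0, 20.0)  # triangular (min, mode, max), hours
    pesu_eligibility: dict | float = 1.0
    service_scale: float = 0.6
    horizon_hours: float = HOURS_PER_YEAR
    warmup_hours: float = 504.0
    n_replications: int = 20
    base_seed: int = 0
    queue_discipline: str = "fifo"  # or "ctas" (priority by acuity)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if isinstance(self.pesu_eligibility, (int, float)):
            self.pesu_eligibility = {
                cls: float(self.pesu_eligibility) for cls in MHA_CLASSES
            }

    def validate(self) -> None:
        if self.ed_beds < 1:
            raise ValueError("ed_beds must be >= 1")
        if self.pesu_capacity < 0:
            raise ValueError("pesu_capacity must be >= 0")
        lo, mode, hi = self.pesu_stay
        if not (0 <= lo <= mode <= hi):
            raise ValueError("pesu_stay must satisfy 0 <= min <= mode <= max")
        if not (0.0 < self.service_scale <= 1.0):
            raise ValueError("service_scale must be in (0, 1]")
        for cls, rate in self.annual_rate.items():
            if rate < 0:
                raise ValueError(f"negative annual rate for {cls!r}")
        for cls, p in self.pesu_eligibility.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"pesu_eligibility[{cls!r}] outside [0, 1]")
        if not (0 <= self.warmup_hours < self.horizon_hours):
            raise ValueError("need 0 <= warmup_hours < horizon_hours")
        if self.queue_discipline not in ("fifo", "ctas"):
            raise ValueError("queue_discipline must be 'fifo' or 'ctas'")

    def replace(self, **changes) -> "SimulationParameters":
        """Pure update: returns a deep copy with ``changes`` applied."""
        return _dc_replace(copy.deepcopy(self), **changes)

    def service_for(self, cls: str, ctas: int, dispo: str) -> ServiceSpec:
        for key in ((cls, ctas, dispo), (cls, None, dispo), (cls, None, None)):
            if key in self.service:
                return self.service[key]
        raise KeyError(f"no service distribution for class {cls!r}")

    @property
    def pesu_stay_mean(self) -> float:
        return float(sum(self.pesu_stay)) / 3.0

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def spec_key(key):
            cls, ctas, dispo = key
            return f"{cls}|{'*' if ctas is None else ctas}|{dispo or '*'}"

        return {
            "schema_version": self.schema_version,
            "ed_beds": self.ed_beds,
            "pesu_capacity": self.pesu_capacity,
            "annual_rate": {k: float(v) for k, v in self.annual_rate.items()},
            "ctas_props": {
                k: [float(x) for x in v] for k, v in self.routing.ctas_props.items()
            },
            "dispo_props": {
                f"{k[0]}|{'*' if k[1] is None else k[1]}": [float(x) for x in v]
                for k, v in self.routing.dispo_props.items()
            },
            "service": {
                spec_key(k): {
                    "dist": s.dist,
                    "mu": float(s.mu),
                    "sigma": float(s.sigma),
                    "mean": float(s.mean),
                }
                for k, s in self.service.items()
            },
            "pesu_stay": [float(x) for x in self.pesu_stay],
            "pesu_eligibility": {k: float(v) for k, v in self.pesu_eligibility.items()},
            "service_scale": float(self.service_scale),
            "horizon_hours": float(self.horizon_hours),
            "warmup_hours": float(self.warmup_hours),
            "n_replications": int(self.n_replications),
            "base_seed": int(self.base_seed),
            "queue_discipline": self.queue_discipline,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationParameters":
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported parameter schema {data.get('schema_version')!r}; "
                f"expected {SCHEMA_VERSION!r}"
            )
        routing = RoutingSpec()
        for k, v in data.get("ctas_props", {}).items():
            routing.ctas_props[k] = np.asarray(v, float)
        for k, v in data.get("dispo_props", {}).items():
            name, ctas = k.rsplit("|", 1)
            routing.dispo_props[(name, None if ctas == "*" else int(ctas))] = (
                np.asarray(v, float)
            )
        service = {}
        for k, v in data.get("service", {}).items():
            name, ctas, dispo = k.split("|")
            key = (
                name,
                None if ctas == "*" else int(ctas),
                None if dispo == "*" else dispo,
            )
            service[key] = ServiceSpec(
                name, key[1], key[2], v["dist"], v["mu"], v["sigma"], v["mean"]
            )
        return cls(
            ed_beds=int(data["ed_beds"]),
            pesu_capacity=int(data["pesu_capacity"]),
            annual_rate={k: float(v) for k, v in data["annual_rate"].items()},
            routing=routing,
            service=service,
            pesu_stay=tuple(data["pesu_stay"]),
            pesu_eligibility={
                k: float(v) for k, v in data["pesu_eligibility"].items()
            },
            service_scale=float(data["service_scale"]),
            horizon_hours=float(data["horizon_hours"]),
            warmup_hours=float(data["warmup_hours"]),
            n_replications=int(data["n_replications"]),
            base_seed=int(data["base_seed"]),
            queue_discipline=data.get("queue_discipline", "fifo"),
        )


# ---------------------------------------------------------------------------
# Replication output
# ---------------------------------------------------------------------------


@dataclass
class ReplicationResult:
    """Per-replication KPIs.

    LOS means are over patients who arrived after warm-up and departed by
    the horizon; arrival/departure counts cover the full horizon.
    ``pesu_share`` is PESU-treated MHA patients as a percentage of MHA
    arrivals, both over the post-warm-up cohort.
    """

    seed: int
    arrivals: dict
    departures: dict
    censored: int
    mean_los: dict  # per patient class, NaN when no observations
    mean_los_overall: float
    mean_los_nmha: float
    mean_los_mha: float
    pesu_treated: int
    mha_arrivals_kpi: int
    pesu_share: float  # percent
    util_ed: float
    util_pesu: float

    def kpi_row(self) -> dict:
        row = {
            "seed": self.seed,
            "arrivals_NMHA": self.arrivals["NMHA"],
            "arrivals_MHA": sum(self.arrivals[c] for c in MHA_CLASSES),
            "mean_los_overall": self.mean_los_overall,
            "mean_los_NMHA": self.mean_los_nmha,
            "mean_los_MHA": self.mean_los_mha,
            "pesu_share": self.pesu_share,
            "pesu_treated": self.pesu_treated,
            "util_ed": self.util_ed,
            "util_pesu": self.util_pesu,
            "censored": self.censored,
        }
        for cls in PATIENT_CLASSES:
            row[f"mean_los_{cls}"] = self.mean_los[cls]
        return row


# ---------------------------------------------------------------------------
# Arrival process
# ---------------------------------------------------------------------------


def simulate_arrivals(
    mean_interarrival: float, horizon: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson arrival times on (0, horizon].

    Gaps are i.i.d. exponential with the given mean; an infinite mean yields
    an empty stream.
    """
    if not mean_interarrival > 0:
        raise ValueError("mean_interarrival must be positive")
    if not np.isfinite(mean_interarrival) or horizon <= 0:
        return np.empty(0)
    expected = horizon / mean_interarrival
    chunk = max(16, int(expected + 4.0 * np.sqrt(expected) + 10))
    times = np.cumsum(rng.exponential(mean_interarrival, chunk))
    while times[-1] < horizon:
        more = np.cumsum(rng.exponential(mean_interarrival, chunk)) + times[-1]
        times = np.concatenate([times, more])
    return times[times <= horizon]


# ---------------------------------------------------------------------------
# Core replication
# ---------------------------------------------------------------------------


def _sample_population(params: SimulationParameters, seed: int):
    """Pre-draw every patient and attribute, one stream pair per class.

    Attribute draws are indexed by within-class arrival order, which keeps
    common-random-number comparisons tight: a scenario that changes only a
    capacity sees the identical patient population, and one that rescales a
    single class's rate leaves every other class untouched.
    """
    cols: dict[str, list] = {
        "arrival": [], "cls": [], "ctas": [], "dispo": [], "T": [],
        "eligible": [], "stay1": [], "stay2": [],
    }
    lo, mode, hi = params.pesu_stay
    degenerate_tri = hi <= lo
    for idx, cls in enumerate(PATIENT_CLASSES):
        rate = float(params.annual_rate.get(cls, 0.0))
        if rate <= 0:
            continue
        arr_rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + idx]))
        attr_rng = np.random.default_rng(np.random.SeedSequence([seed, 2000 + idx]))
        times = simulate_arrivals(
            HOURS_PER_YEAR / rate, params.horizon_hours, arr_rng
        )
        n = len(times)
        if n == 0:
            continue
        ctas_p = params.routing.ctas_props[cls]
        ctas = attr_rng.choice(len(CTAS_LEVELS), size=n, p=ctas_p) + 1
        dispo = np.empty(n, dtype=np.int64)
        for level in CTAS_LEVELS:
            mask = ctas == level
            if mask.any():
                dvec = params.routing.dispo_for(cls, level)
                dispo[mask] = attr_rng.choice(len(DISPOSITIONS), size=mask.sum(), p=dvec)
        T = np.empty(n)
        for level in CTAS_LEVELS:
            for d_idx, d_name in enumerate(DISPOSITIONS):
                mask = (ctas == level) & (dispo == d_idx)
                if mask.any():
                    spec = params.service_for(cls, level, d_name)
                    T[mask] = spec.sample(attr_rng, int(mask.sum()))
        p_elig = float(params.pesu_eligibility.get(cls, 0.0)) if cls != "NMHA" else 0.0
        eligible = attr_rng.random(n) < p_elig
        if degenerate_tri:
            stay1 = np.full(n, float(lo))
            stay2 = np.full(n, float(lo))
        else:
            stay1 = attr_rng.triangular(lo, mode, hi, n)
            stay2 = attr_rng.triangular(lo, mode, hi, n)
        cols["arrival"].append(times)
        cols["cls"].append(np.full(n, idx, dtype=np.int64))
        cols["ctas"].append(ctas)
        cols["dispo"].append(dispo)
        cols["T"].append(T)
        cols["eligible"].append(eligible)
        cols["stay1"].append(stay1)
        cols["stay2"].append(stay2)

    if not cols["arrival"]:
        empty = {k: np.empty(0) for k in cols}
        empty["cls"] = np.empty(0, dtype=np.int64)
        return empty
    out = {k: np.concatenate(v) for k, v in cols.items()}
    order = np.argsort(out["arrival"], kind="stable")
    return {k: v[order] for k, v in out.items()}


def run_replication(params: SimulationParameters, seed: int) -> ReplicationResult:
    """Simulate one replication of the ED/PESU network."""
    params.validate()
    pop = _sample_population(params, seed)
    n = len(pop["arrival"])
    arrival = pop["arrival"]
    cls_idx = pop["cls"]
    T = pop["T"]
    eligible = pop["eligible"]
    stay1 = pop["stay1"]
    stay2 = pop["stay2"]
    ctas = pop["ctas"] if n else np.empty(0, dtype=np.int64)
    is_mha = cls_idx != 0  # index 0 is NMHA in PATIENT_CLASSES

    beta = params.service_scale
    horizon = params.horizon_hours
    warmup = params.warmup_hours
    ed_beds = params.ed_beds
    pesu_cap = params.pesu_capacity
    priority_queue = params.queue_discipline == "ctas"

    # patient state
    in_queue = np.zeros(n, dtype=bool)
    holds_bed = np.zeros(n, dtype=bool)
    waiting_transfer = np.zeros(n, dtype=bool)
    transferred = np.zeros(n, dtype=bool)
    departed = np.zeros(n, dtype=bool)
    pesu_treated_flag = np.zeros(n, dtype=bool)
    los = np.full(n, np.nan)

    heap: list[tuple[float, int, int, int]] = [
        (float(arrival[i]), i, _EVT_ARRIVAL, i) for i in range(n)
    ]
    heapq.heapify(heap)
    seq = n  # tie-break counter: (time, seq) is a total order on events

    ed_queue: deque[int] | list = [] if priority_queue else deque()
    transfer_list: deque[int] = deque()
    ed_busy = 0
    pesu_busy = 0

    # busy-resource time integrals over [warmup, horizon]
    util_ed_area = 0.0
    util_pesu_area = 0.0
    last_t = 0.0

    def push(t: float, kind: int, pid: int) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, pid))
        seq += 1

    def queue_push(pid: int) -> None:
        if priority_queue:
            heapq.heappush(ed_queue, (int(ctas[pid]), pid))
        else:
            ed_queue.append(pid)
        in_queue[pid] = True

    def queue_pop() -> int:
        if priority_queue:
            return heapq.heappop(ed_queue)[1]
        return ed_queue.popleft()

    def try_admit(t: float) -> None:
        nonlocal ed_busy
        while ed_busy < ed_beds and ed_queue:
            pid = queue_pop()
            if not in_queue[pid]:
                continue  # cancelled by a PESU transfer while queued
            in_queue[pid] = False
            ed_busy += 1
            holds_bed[pid] = True
            push(t + beta * T[pid], _EVT_BED_FREE, pid)
            push(t + T[pid], _EVT_ED_DISCHARGE, pid)

    def enter_pesu(t: float, pid: int, stay: float) -> None:
        nonlocal pesu_busy
        pesu_busy += 1
        pesu_treated_flag[pid] = True
        push(t + stay, _EVT_PESU_DEPART, pid)

    def pull_transfer(t: float) -> None:
        nonlocal ed_busy, pesu_busy
        while transfer_list and pesu_busy < pesu_cap:
            pid = transfer_list.popleft()
            if not waiting_transfer[pid] or departed[pid] or transferred[pid]:
                continue
            waiting_transfer[pid] = False
            transferred[pid] = True
            if holds_bed[pid]:
                holds_bed[pid] = False
                ed_busy -= 1
                try_admit(t)
            elif in_queue[pid]:
                in_queue[pid] = False  # lazy removal from the ED queue
            enter_pesu(t, pid, float(stay2[pid]))

    while heap and heap[0][0] <= horizon:
        t, _, kind, pid = heapq.heappop(heap)
        if t < last_t:
            raise AssertionError("event times must be non-decreasing")
        dt = max(0.0, min(t, horizon) - max(last_t, warmup))
        if dt > 0:
            util_ed_area += ed_busy * dt
            util_pesu_area += pesu_busy * dt
        last_t = t

        if kind == _EVT_ARRIVAL:
            if is_mha[pid] and eligible[pid] and pesu_busy < pesu_cap:
                enter_pesu(t, pid, float(stay1[pid]))
            else:
                queue_push(pid)
                if is_mha[pid] and eligible[pid]:
                    waiting_transfer[pid] = True
                    transfer_list.append(pid)
                try_admit(t)
        elif kind == _EVT_BED_FREE:
            if holds_bed[pid] and not transferred[pid]:
                holds_bed[pid] = False
                ed_busy -= 1
                try_admit(t)
        elif kind == _EVT_ED_DISCHARGE:
            if not transferred[pid]:
                if holds_bed[pid]:  # only possible when service_scale == 1
                    holds_bed[pid] = False
                    ed_busy -= 1
                    try_admit(t)
                departed[pid] = True
                waiting_transfer[pid] = False
                los[pid] = t - arrival[pid]
        else:  # _EVT_PESU_DEPART
            pesu_busy -= 1
            departed[pid] = True
            los[pid] = t - arrival[pid]
            pull_transfer(t)

        if not (0 <= ed_busy <= ed_beds):
            raise AssertionError("ED bed occupancy out of bounds")
        if not (0 <= pesu_busy <= pesu_cap):
            raise AssertionError("PESU occupancy out of bounds")

    if last_t < horizon:
        dt = horizon - max(last_t, warmup)
        if dt > 0:
            util_ed_area += ed_busy * dt
            util_pesu_area += pesu_busy * dt

    # ---- KPI extraction ---------------------------------------------------
    arrivals = {
        cls: int((cls_idx == i).sum()) for i, cls in enumerate(PATIENT_CLASSES)
    }
    departures = {
        cls: int(((cls_idx == i) & departed).sum())
        for i, cls in enumerate(PATIENT_CLASSES)
    }
    censored = int(n - departed.sum())

    kpi = departed & (arrival >= warmup)
    mean_los = {}
    for i, cls in enumerate(PATIENT_CLASSES):
        sel = kpi & (cls_idx == i)
        mean_los[cls] = float(np.mean(los[sel])) if sel.any() else float("nan")

    def _mean(mask: np.ndarray) -> float:
        return float(np.mean(los[mask])) if mask.any() else float("nan")

    mha_kpi = int((is_mha & (arrival >= warmup)).sum())
    treated = int((pesu_treated_flag & (arrival >= warmup)).sum())
    window = max(1e-12, horizon - warmup)
    return ReplicationResult(
        seed=seed,
        arrivals=arrivals,
        departures=departures,
        censored=censored,
        mean_los=mean_los,
        mean_los_overall=_mean(kpi),
        mean_los_nmha=_mean(kpi & ~is_mha),
        mean_los_mha=_mean(kpi & is_mha),
        pesu_treated=treated,
        mha_arrivals_kpi=mha_kpi,
        pesu_share=100.0 * treated / mha_kpi if mha_kpi else 0.0,
        util_ed=util_ed_area / (window * ed_beds) if ed_beds else 0.0,
        util_pesu=util_pesu_area / (window * pesu_cap) if pesu_cap else 0.0,
    )


def run_experiment(
    params: SimulationParameters,
    n_replications: int | None = None,
    base_seed: int | None = None,
):
    """Run independent replications and summarize KPIs with 95% t-CIs.

    Replication ``i`` uses seed ``base_seed + i``, so two experiments with
    the same base seed are paired under common random numbers.  Returns a
    :class:`~pesuflow.kpi_reporting.KPIReport`.
    """
    from .kpi_reporting import KPIReport

    n_reps = params.n_replications if n_replications is None else int(n_replications)
    seed0 = params.base_seed if base_seed is None else int(base_seed)
    if n_reps < 2:
        raise ValueError("need at least 2 replications for confidence intervals")
    results = [run_replication(params, seed0 + i) for i in range(n_reps)]
    return KPIReport.from_replications(results)


def mean_service_requirement(params: SimulationParameters) -> float:
    """Arrival-rate-weighted mean treatment requirement E[T], hours."""
    total_rate = 0.0
    total = 0.0
    for cls in PATIENT_CLASSES:
        rate = float(params.annual_rate.get(cls, 0.0))
        if rate <= 0:
            continue
        ctas_p = params.routing.ctas_props[cls]
        mean_t = 0.0
        for level, pc in zip(CTAS_LEVELS, ctas_p):
            dvec = params.routing.dispo_for(cls, level)
            for d_name, pd_ in zip(DISPOSITIONS, dvec):
                if pc * pd_ > 0:
                    mean_t += pc * pd_ * params.service_for(cls, level, d_name).mean
        total += rate * mean_t
        total_rate += rate
    return total / total_rate if total_rate else 0.0
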