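"""Baseline calibration of the unpublished simulation knobs.

The historical extract pins the arrival rates and the LOS marginals, but
three model inputs are not published: the PESU stay triangular, the PESU
eligibility probabilities, and the fraction of the treatment requirement
that occupies an ED bed (``service_scale``).  Calibration tunes them until
the simulated baseline reproduces the validation statistics: the overall,
NMHA and MHA mean ED LOS and the share of MHA patients treated in the
PESU.

Procedure
---------
If the incoming parameter set already meets the targets it is returned
unchanged.  Otherwise a two-knob common-random-number search runs first:
eligibility pinned at 1, bisection on the triangular stay mean until the
PESU share enters its interval (the share is monotone decreasing in stay
length at fixed capacity), then bisection on ``service_scale`` for the
overall LOS.  With every MHA arrival eligible, matching the share requires
stays so long that the PESU-treated LOS pushes the overall LOS above its
interval for *any* bed-holding fraction; when the feasibility probe
detects this, eligibility is exposed as a third knob: a common scale
factor on the per-class eligibility profile targets the share, the
triangular mean targets the MHA LOS, and ``service_scale`` targets the
overall LOS.  ``service_scale`` is only weakly identified by the baseline
mean, so its stage aims at the upper half of the validation interval — the
reported sensitivity of LOS to the forecast demand shows the real ED
operates near its congestion knee, and an uncongested fit would suppress
every capacity/demand scenario response.

All stages share fixed seeds, so rerunning calibration is deterministic;
monotonicity of each knob/KPI pair is probed empirically before bisecting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .des_engine import SimulationParameters, run_experiment
from .taxonomy import MHA_CLASSES

log = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """A monotonicity assumption failed; bisection would be meaningless."""


@dataclass(frozen=True)
class CalibrationTarget:
    """One KPI with its target value and acceptance interval."""

    kpi: str
    target: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.target <= self.hi):
            raise ValueError("acceptance interval must contain the target")

    def met(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def default_targets() -> dict[str, CalibrationTarget]:
    """Validation targets: simulated-vs-historical CIs plus the PESU share
    (+-1 percentage point)."""
    return {
        "mean_los_overall": CalibrationTarget("mean_los_overall", 6.2, 5.9, 6.4),
        "mean_los_NMHA": CalibrationTarget("mean_los_NMHA", 6.1, 5.8, 6.3),
        "mean_los_MHA": CalibrationTarget("mean_los_MHA", 7.7, 7.6, 7.8),
        "pesu_share": CalibrationTarget("pesu_share", 37.9, 36.9, 38.9),
    }


#: KPIs actively driven by a knob (NMHA LOS follows from the LOS marginals
#: and the ED queue; it is reported but has no dedicated knob).
_PRIMARY = ("pesu_share", "mean_los_MHA", "mean_los_overall")


@dataclass
class CalibrationReport:
    converged: bool
    phase: str
    iterations: list = field(default_factory=list)
    final_kpis: dict = field(default_factory=dict)
    unmet: list = field(default_factory=list)
    message: str = ""

    def record(self, stage: str, knob: str, value: float, kpis: dict) -> None:
        self.iterations.append(
            {"stage": stage, "knob": knob, "value": value, **kpis}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.iterations)


# ---------------------------------------------------------------------------
# Knob appliers
# ---------------------------------------------------------------------------


def _set_stay_mean(params: SimulationParameters, mean: float) -> SimulationParameters:
    """Rescale the triangular mode/max (min fixed) to reach a target mean."""
    lo, mode, hi = params.pesu_stay
    if mean <= lo:
        # target below the fixed minimum: shrink the whole triangle
        scale = max(1e-6, mean / max(params.pesu_stay_mean, 1e-9))
        return params.replace(pesu_stay=(lo * scale, mode * scale, hi * scale))
    s = (3.0 * mean - lo) / (mode + hi)
    new_mode, new_hi = mode * s, hi * s
    if new_mode < lo:  # keep min <= mode <= max
        new_mode = lo
        new_hi = 3.0 * mean - 2.0 * lo
    return params.replace(pesu_stay=(lo, new_mode, new_hi))


def _set_eligibility_scale(
    params: SimulationParameters, profile: dict, scale: float
) -> SimulationParameters:
    elig = {cls: min(1.0, profile.get(cls, 0.0) * scale) for cls in MHA_CLASSES}
    return params.replace(pesu_eligibility=elig)


def _set_service_scale(params: SimulationParameters, beta: float) -> SimulationParameters:
    return params.replace(service_scale=float(beta))


# ---------------------------------------------------------------------------
# Search machinery
# ---------------------------------------------------------------------------


def _evaluate(params: SimulationParameters, base_seed: int, n_reps: int) -> dict:
    report = run_experiment(params, n_replications=n_reps, base_seed=base_seed)
    return {k: report.mean(k) for k in report.summary}


def _check_monotone(xs, ys, increasing: bool, tol: float, label: str) -> None:
    """Probe-point monotonicity check with a noise tolerance."""
    sign = 1.0 if increasing else -1.0
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), list(zip(xs, ys))[1:]):
        if sign * (y1 - y0) < -tol:
            raise CalibrationError(
                f"{label}: KPI not {'increasing' if increasing else 'decreasing'} "
                f"in the knob (f({x0:.3g})={y0:.3g}, f({x1:.3g})={y1:.3g})"
            )


def _bisect_knob(
    params: SimulationParameters,
    apply,
    kpi: str,
    target: CalibrationTarget,
    bracket: tuple[float, float],
    increasing: bool,
    aim: float,
    base_seed: int,
    n_reps: int,
    report: CalibrationReport,
    stage: str,
    max_steps: int = 8,
):
    """CRN bisection of one knob against one KPI.

    Stops as soon as the KPI enters the target's acceptance interval (and
    the value is within a small distance of ``aim``), or when the bracket
    is exhausted; returns (params, kpis, knob_value).
    """
    a, b = bracket
    mid = 0.5 * (a + b)
    ys = {}
    for x in (a, mid, b):
        ys[x] = _evaluate(apply(params, x), base_seed, n_reps)
        report.record(stage, kpi, x, ys[x])
    tol = 2.0 * (target.hi - target.lo)
    _check_monotone(
        [a, mid, b], [ys[x][kpi] for x in (a, mid, b)], increasing, tol, stage
    )

    def value(x):
        if x not in ys:
            ys[x] = _evaluate(apply(params, x), base_seed, n_reps)
            report.record(stage, kpi, x, ys[x])
        return ys[x][kpi]

    # clamp when the aim is outside the attainable range
    lo_val, hi_val = value(a), value(b)
    ordered = (lo_val, hi_val) if increasing else (hi_val, lo_val)
    if aim <= ordered[0]:
        best = a if increasing else b
        return apply(params, best), ys[best], best
    if aim >= ordered[1]:
        best = b if increasing else a
        return apply(params, best), ys[best], best

    half_width = 0.5 * (target.hi - target.lo)
    for _ in range(max_steps):
        mid = 0.5 * (a + b)
        v = value(mid)
        if target.met(v) and abs(v - aim) <= half_width:
            return apply(params, mid), ys[mid], mid
        if (v < aim) == increasing:
            a = mid
        else:
            b = mid
    mid = 0.5 * (a + b)
    v = value(mid)
    return apply(params, mid), ys[mid], mid


def _targets_met(kpis: dict, targets: dict, names=_PRIMARY) -> list:
    return [n for n in names if n in targets and not targets[n].met(kpis.get(n, np.nan))]


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------


def calibrate_baseline(
    params: SimulationParameters,
    targets: dict | None = None,
    max_iter: int = 3,
    base_seed: int = 0,
    n_eval_reps: int = 3,
) -> tuple[SimulationParameters, CalibrationReport]:
    """Tune (eligibility, PESU stay, service_scale) to the validation targets.

    ``max_iter`` bounds the outer stage-iteration loops per phase; every
    KPI evaluation uses ``n_eval_reps`` replications under fixed seeds.
    Returns the calibrated parameters and a convergence report; on
    non-convergence the best-found parameters are returned with
    ``report.converged`` False.
    """
    params.validate()
    targets = default_targets() if targets is None else targets
    report = CalibrationReport(converged=False, phase="fixed-point")

    kpis = _evaluate(params, base_seed, n_eval_reps)
    report.record("initial", "-", np.nan, kpis)
    if not _targets_met(kpis, targets):
        report.converged = True
        report.final_kpis = kpis
        report.message = "targets already met; parameters returned unchanged"
        return params, report

    share_t = targets["pesu_share"]
    overall_t = targets["mean_los_overall"]
    mha_t = targets.get("mean_los_MHA")
    # service_scale aims at the upper half of the overall-LOS interval (see
    # module docstring: the knob is weakly identified and the real system
    # operates near its congestion knee).
    overall_aim = overall_t.target + 0.5 * (overall_t.hi - overall_t.target)

    profile = dict(params.pesu_eligibility)

    # ---- phase 1: the two-knob search (eligibility pinned at 1) ----------
    report.phase = "two-knob"
    current = _set_eligibility_scale(params, {c: 1.0 for c in MHA_CLASSES}, 1.0)
    for _ in range(max_iter):
        current, kpis, _ = _bisect_knob(
            current, _set_stay_mean, "pesu_share", share_t,
            bracket=(2.0, 40.0), increasing=False, aim=share_t.target,
            base_seed=base_seed, n_reps=n_eval_reps, report=report,
            stage="two-knob/stay-mean",
        )
        # feasibility probe: minimal bed-holding fraction
        floor = _evaluate(_set_service_scale(current, 0.05), base_seed, n_eval_reps)
        report.record("two-knob/los-floor", "service_scale", 0.05, floor)
        if floor["mean_los_overall"] > overall_t.hi:
            report.message = (
                "two-knob search infeasible: with every MHA arrival eligible, "
                f"matching the PESU share forces overall LOS >= "
                f"{floor['mean_los_overall']:.2f} h at any service_scale; "
                "exposing eligibility as a third knob"
            )
            log.info(report.message)
            break
        current, kpis, _ = _bisect_knob(
            current, _set_service_scale, "mean_los_overall", overall_t,
            bracket=(0.05, 0.95), increasing=True, aim=overall_aim,
            base_seed=base_seed, n_reps=n_eval_reps, report=report,
            stage="two-knob/service-scale",
        )
        if not _targets_met(kpis, targets, ("pesu_share", "mean_los_overall")):
            report.converged = True
            report.final_kpis = kpis
            report.unmet = _targets_met(kpis, targets)
            report.message = "converged with the two-knob search"
            return current, report
    else:
        report.message = "two-knob search did not converge; exposing eligibility"

    # ---- phase 2: eligibility scale + stay mean + service scale -----------
    report.phase = "three-knob"
    current = params.replace()  # restart from the (profiled) input parameters
    s_max = 1.0 / max(max(profile.values()), 1e-9)
    kpis = {}
    for _ in range(max_iter):
        current, kpis, _ = _bisect_knob(
            current,
            lambda p, s: _set_eligibility_scale(p, profile, s),
            "pesu_share", share_t,
            bracket=(0.2, min(2.5, s_max)), increasing=True, aim=share_t.target,
            base_seed=base_seed, n_reps=n_eval_reps, report=report,
            stage="three-knob/eligibility",
        )
        if mha_t is not None:
            current, kpis, _ = _bisect_knob(
                current, _set_stay_mean, "mean_los_MHA", mha_t,
                bracket=(3.0, 20.0), increasing=True, aim=mha_t.target,
                base_seed=base_seed, n_reps=n_eval_reps, report=report,
                stage="three-knob/stay-mean",
            )
        current, kpis, _ = _bisect_knob(
            current, _set_service_scale, "mean_los_overall", overall_t,
            bracket=(0.05, 0.95), increasing=True, aim=overall_aim,
            base_seed=base_seed, n_reps=n_eval_reps, report=report,
            stage="three-knob/service-scale",
        )
        if not _targets_met(kpis, targets):
            report.converged = True
            break

    report.final_kpis = kpis
    report.unmet = _targets_met(
        kpis, targets, tuple(targets)
    )
    if report.converged:
        report.message = report.message or "converged with the three-knob search"
    else:
        report.message = (
            "calibration did not converge within max_iter; returning best found "
            f"(unmet primary targets: {_targets_met(kpis, targets)})"
        )
        log.warning(report.message)
    return current, report
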