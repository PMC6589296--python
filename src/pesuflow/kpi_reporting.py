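"""Headline statistics: percent changes, shares, replication CIs, trends.

Percentages and LOS hours are presented to one decimal place, matching the
usual reporting convention for ED operational statistics; underlying values
are kept at full precision in the tabular outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import SUBSTANCE_SUBGROUPS


def percent_change(old: float, new: float) -> float:
    """100 * (new - old) / old, to one decimal. Requires old > 0."""
    if old <= 0:
        raise ValueError("percent_change needs a positive base value")
    return round(100.0 * (new - old) / old, 1)


def share(part: float, whole: float) -> float:
    """100 * part / whole, to one decimal. Requires 0 <= part <= whole."""
    if whole <= 0:
        raise ValueError("share needs a positive denominator")
    if not (0 <= part <= whole):
        raise ValueError("share needs 0 <= part <= whole")
    return round(100.0 * part / whole, 1)


def ci95(values) -> tuple[float, float, float]:
    """Mean and 95% CI using the t distribution with n-1 df."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    mean = float(np.mean(x))
    half = float(stats.t.ppf(0.975, n - 1) * np.std(x, ddof=1) / np.sqrt(n))
    return mean, mean - half, mean + half


# ---------------------------------------------------------------------------
# Replication-level report
# ---------------------------------------------------------------------------

#: KPIs summarized across replications.
_KPI_NAMES = (
    "arrivals_NMHA",
    "arrivals_MHA",
    "mean_los_overall",
    "mean_los_NMHA",
    "mean_los_MHA",
    "pesu_share",
    "util_ed",
    "util_pesu",
)


@dataclass
class KPIReport:
    """Cross-replication KPI means with 95% confidence intervals.

    ``summary`` maps KPI name -> (mean, lower, upper, n); ``replications``
    keeps the per-replication rows for paired (common-random-number)
    comparisons against another report.
    """

    summary: dict = field(default_factory=dict)
    replications: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_replications(cls, results) -> "KPIReport":
        rows = pd.DataFrame([r.kpi_row() for r in results])
        summary = {}
        for name in _KPI_NAMES:
            vals = rows[name].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) >= 2:
                mean, lo, hi = ci95(vals)
                summary[name] = (mean, lo, hi, len(vals))
        return cls(summary=summary, replications=rows)

    def mean(self, name: str) -> float:
        return self.summary[name][0]

    def interval(self, name: str) -> tuple[float, float]:
        _, lo, hi, _ = self.summary[name]
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"kpi": k, "mean": m, "ci_lower": lo, "ci_upper": hi, "n": n}
                for k, (m, lo, hi, n) in self.summary.items()
            ]
        )

    def paired_deltas(self, reference: "KPIReport") -> pd.DataFrame:
        """Per-replication differences (self - reference) by shared seed."""
        a = self.replications.set_index("seed")
        b = reference.replications.set_index("seed")
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ValueError("no common seeds between reports; runs are not paired")
        cols = [c for c in _KPI_NAMES if c in a.columns and c in b.columns]
        return (a.loc[common, cols] - b.loc[common, cols]).reset_index()


# ---------------------------------------------------------------------------
# Historical-trend report
# ---------------------------------------------------------------------------


def trend_report(summary: pd.DataFrame, first: str = "2012", last: str = "2016") -> pd.DataFrame:
    """Per-category growth between two fiscal years plus subgroup shares.

    ``summary`` is the table produced by
    :func:`pesuflow.input_modelling.annual_summary`.  Output rows carry the
    endpoint counts, the percent change, and — for substance subgroups —
    the subgroup's share of substance visits in the final year.
    """
    for year in (first, last):
        if year not in summary.columns:
            raise ValueError(f"summary table does not cover fiscal year {year!r}")

    rows = []
    substance_last = None
    if ("substance", "all") in summary.index:
        substance_last = float(summary.loc[("substance", "all"), last])
    for (cat, sub), rec in summary.iterrows():
        old, new = float(rec[first]), float(rec[last])
        if old <= 0:
            continue
        row = {
            "category": cat,
            "substance_subgroup": sub,
            first: old,
            last: new,
            "percent_change": percent_change(old, new),
        }
        if cat == "substance" and sub != "all" and substance_last:
            row[f"share_of_substance_{last}"] = share(new, substance_last)
        rows.append(row)

    out = pd.DataFrame(rows)
    # MHA visits as a share of all visits over the full table span.
    if ("MHA", "all") in summary.index and ("ALL", "all") in summary.index:
        out.attrs["mha_share_of_total"] = share(
            float(summary.loc[("MHA", "all"), "total"]),
            float(summary.loc[("ALL", "all"), "total"]),
        )
    return out
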