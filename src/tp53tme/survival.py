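"""Kaplan-Meier estimation and log-rank comparison of score groups.

Wraps lifelines behind small typed containers so downstream code and the
report writers work with plain step tables.  Conventions: censored
observations at an event time are counted as at-risk through that time
(censored after the events), and the log-rank statistic is referred to a
chi-square distribution with one degree of freedom, two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve over the distinct event times of one group."""

    times: np.ndarray      # strictly increasing event times
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # number at risk just before each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_records(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise SurvivalError("empty survival record list")
    if not np.all(np.isfinite(time)):
        raise SurvivalError("non-finite survival time")
    if np.any(time < 0):
        raise SurvivalError("negative survival time")
    if not np.isin(event, (0, 1)).all():
        raise SurvivalError("event indicator must be 0 (censored) or 1 (death)")
    return time, event


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    with d_i deaths among n_i at risk.  Censored-only input yields S == 1
    (an empty step table).
    """
    time, event = _check_records(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    event_times = steps.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    at_risk = steps["at_risk"].to_numpy(dtype=int)
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-sided log-rank test between two groups.

    Returns ``(statistic, p_value)`` where the statistic follows a
    chi-square(1) distribution under the null of equal survival.
    """
    time, event = _check_records(time, event)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise SurvivalError(f"expected exactly 2 groups, got {list(labels)}")
    mask = group == labels[0]
    if mask.all() or (~mask).all():
        raise SurvivalError("one group is empty")
    if event.sum() == 0:
        raise SurvivalError("no events observed; log-rank statistic undefined")
    res = _ll_logrank(time[mask], time[~mask], event[mask], event[~mask])
    return float(res.test_statistic), float(res.p_value)


def compare_groups(clinical: pd.DataFrame, scores: pd.DataFrame) -> dict:
    """Join clinical records to score groups and run the KM / log-rank stage.

    ``clinical`` needs columns ``time`` and ``event`` indexed by sample id;
    ``scores`` is a classified score table with a ``group`` column.
    Returns per-group KM step tables and the log-rank statistic and p-value.
    """
    merged = clinical.join(scores["group"], how="inner")
    if merged.empty:
        raise SurvivalError("no overlapping sample ids between clinical table and scores")
    curves = {}
    for label, sub in merged.groupby("group"):
        curve = km_estimate(sub["time"], sub["event"])
        curves[label] = pd.DataFrame(
            {"time": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
        )
    stat, p = logrank_test(merged["time"], merged["event"], merged["group"])
    return {"curves": curves, "statistic": stat, "p_value": p, "n": len(merged)}
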