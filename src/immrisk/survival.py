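"""Kaplan-Meier curves per immune-risk group and k-sample log-rank tests.

Thin wrappers around lifelines.  Conventions: the product-limit estimator
steps only at observed event times (deaths precede censorings at tied
times, the standard convention); the log-rank test is the unweighted
k-sample chi-square with k-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the observed event times."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def _as_arrays(records: pd.DataFrame | Sequence[tuple[float, int]]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["time"].to_numpy(float), records["event"].to_numpy(int)
    arr = np.asarray(records, dtype=float).reshape(-1, 2)
    return arr[:, 0], arr[:, 1].astype(int)


def km_estimate(records: pd.DataFrame | Sequence[tuple[float, int]], group: str = "") -> KMCurve:
    """Kaplan-Meier estimate from (time, event) records.

    ``records`` is either a DataFrame with ``time``/``event`` columns or a
    sequence of (time, event) tuples.  With no observed events the curve is
    flat at 1 (empty ``times``).
    """
    times, events = _as_arrays(records)
    if times.size == 0:
        raise ValueError("no survival records")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    t = ev.index.to_numpy(float)
    s = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(float)
    return KMCurve(group=group, times=t, survival=s, at_risk=ev["at_risk"].to_numpy(int))


def log_rank(groups: Mapping[str, pd.DataFrame | Sequence[tuple[float, int]]]) -> LogRankResult:
    """Unweighted k-sample log-rank test across labeled record groups."""
    labels, times, events = [], [], []
    for label, records in groups.items():
        t, e = _as_arrays(records)
        if t.size == 0:
            continue
        labels += [label] * t.size
        times.append(t)
        events.append(e)
    k = len(set(labels))
    if k < 2:
        raise ValueError("log-rank needs at least 2 non-empty groups")
    res = multivariate_logrank_test(
        np.concatenate(times), np.array(labels), np.concatenate(events)
    )
    return LogRankResult(
        statistic=float(res.test_statistic), df=k - 1, p_value=float(res.p_value)
    )


def compare_groups(
    clinical: pd.DataFrame, group_of: Mapping[str, str]
) -> tuple[dict[str, KMCurve], LogRankResult]:
    """KM curve per group plus the log-rank comparison.

    ``clinical`` is indexed by patient id with ``time``/``event`` columns;
    ``group_of`` maps patient id to group label.  Patients missing a
    clinical record are dropped with a logged count.
    """
    present = [p for p in group_of if p in clinical.index]
    n_missing = len(group_of) - len(present)
    if n_missing:
        logger.info("dropping %d patients without clinical records", n_missing)
    by_group: dict[str, pd.DataFrame] = {}
    for label in sorted(set(group_of[p] for p in present)):
        ids = [p for p in present if group_of[p] == label]
        by_group[label] = clinical.loc[ids]
    curves = {label: km_estimate(df, group=label) for label, df in by_group.items()}
    return curves, log_rank(by_group)


def km_table(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"time": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
    )
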