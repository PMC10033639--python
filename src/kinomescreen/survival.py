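"""Kaplan-Meier estimation and two-group log-rank testing.

Thin, validated surface over lifelines: the product-limit estimator with the
standard at-risk convention (events processed before censorings tied at the
same time), median survival defined as the smallest time with S(t) <= 0.5
(``None`` when the curve never reaches 0.5), and the standard
observed-minus-expected log-rank chi-square with hypergeometric variance,
two-sided p from chi-square with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("survival table is empty")
    if (table["time"] < 0).any():
        raise ValueError("times must be nonnegative")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return table


@dataclass(frozen=True)
class KMEstimate:
    """Fitted step survival function for one group."""

    group: str
    n_subjects: int
    event_times: np.ndarray  # ordered distinct times with >=1 event
    survival: np.ndarray  # S(t) at those times
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None  # smallest t with S(t) <= 0.5; None if undefined

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(table: pd.DataFrame, group: str) -> KMEstimate:
    """Product-limit (Kaplan-Meier) fit for one group of a survival table."""
    table = _validate_table(table)
    sub = table[table["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"group {group!r} has no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"], label=str(group))
    et = kmf.event_table
    with_events = et[et["observed"] > 0]
    times = with_events.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[with_events.index].to_numpy().ravel()
    med = kmf.median_survival_time_
    return KMEstimate(
        group=str(group),
        n_subjects=len(sub),
        event_times=times,
        survival=surv,
        n_at_risk=with_events["at_risk"].to_numpy(dtype=int),
        n_events=with_events["observed"].to_numpy(dtype=int),
        median=None if np.isinf(med) else float(med),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square, df = 1
    df: int
    p_two_sided: float

    def __post_init__(self) -> None:
        if self.statistic < -1e-12:
            raise ValueError("log-rank statistic must be nonnegative")


def logrank(table: pd.DataFrame, group_a: str, group_b: str) -> LogrankResult:
    """Two-group log-rank test (chi-square with one degree of freedom)."""
    table = _validate_table(table)
    a = table[table["group"] == group_a]
    b = table[table["group"] == group_b]
    for name, sub in ((group_a, a), (group_b, b)):
        if len(sub) == 0:
            raise ValueError(f"group {name!r} has no subjects")
    if int(a["event"].sum() + b["event"].sum()) == 0:
        raise ValueError("no events in either group; log-rank test undefined")
    res = logrank_test(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return LogrankResult(
        statistic=float(res.test_statistic), df=1, p_two_sided=float(res.p_value)
    )


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    """Read a survival table TSV (subject_id, time, event, group)."""
    df = pd.read_csv(path, sep="\t")
    return _validate_table(df)
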