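"""Survival stratification by a regulator's expression.

Samples are split at the median of the candidate regulator's expression
(values equal to the median go to the low group); Kaplan-Meier curves and the
Mantel-Haenszel log-rank test (via lifelines) compare the two groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


def median_split(expression: pd.Series) -> pd.Series:
    """'high' iff expression > median; median ties go to 'low'."""
    if len(expression) < 2:
        raise ValueError("need at least 2 samples to split")
    vals = expression.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("constant expression: no median split possible")
    med = np.median(vals)
    return pd.Series(np.where(vals > med, "high", "low"), index=expression.index, name="group")


def km_estimate(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Product-limit survival curve for one group.

    Returns a frame with columns time, survival, at_risk over the group's
    distinct observed times; censored-only times lower the at-risk count but
    leave the curve flat.
    """
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    et = kmf.event_table
    ev = et[(et["observed"] + et["censored"]) > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    return pd.DataFrame({"time": times, "survival": surv, "at_risk": ev["at_risk"].to_numpy()})


def logrank_test(table: pd.DataFrame) -> tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank test.

    ``table`` needs columns time, event, group (two levels). Returns the
    1-df chi-square statistic and its two-sided p-value.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    if int(table["event"].sum()) < 1:
        raise ValueError("log-rank needs at least one event")
    a = table[table["group"] == groups[0]]
    b = table[table["group"] == groups[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def driver_survival_analysis(
    expression: pd.Series, survival_table: pd.DataFrame
) -> dict:
    """Median-split ``expression`` and log-rank test survival between groups.

    ``survival_table`` needs columns sample, time, event; only samples present
    in both inputs are used.
    """
    surv = survival_table.set_index("sample")
    common = [s for s in expression.index if s in surv.index]
    if len(common) < 4:
        raise ValueError("too few samples shared between expression and survival")
    groups = median_split(expression.loc[common])
    merged = surv.loc[common, ["time", "event"]].copy()
    merged["group"] = groups
    chi2, p = logrank_test(merged)
    return {
        "chi_square": chi2,
        "p_value": p,
        "n_high": int((groups == "high").sum()),
        "n_low": int((groups == "low").sum()),
        "table": merged.reset_index(),
    }
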