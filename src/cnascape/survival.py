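"""Cause-specific survival processing, Kaplan-Meier curves and log-rank tests.

Ten-year disease-specific survival is derived by censoring: deaths from
other causes become censored observations at their recorded time, and any
follow-up beyond 120 months is truncated to 120 months and censored.  Risk
groups come from the tertile rule (top third vs bottom two-thirds) applied
to either an observed signature score or a model-predicted probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import ValidationError
from .signatures import dichotomize

TEN_YEARS_MONTHS = 120.0


def censor_10yr_cause_specific(
    records: pd.DataFrame,
    disease_cause: str = "disease",
    horizon: float = TEN_YEARS_MONTHS,
) -> pd.DataFrame:
    """Apply cause-specific censoring at a 10-year (120-month) horizon.

    ``records`` needs columns ``time`` (months), ``event`` (0/1) and
    ``cause`` (label for deaths).  Non-disease deaths are censored at their
    original time; any time beyond the horizon is truncated to the horizon
    and censored; disease deaths within the horizon keep event = 1.
    """
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValidationError(f"survival records missing column {col!r}")
    if (records["time"] <= 0).any():
        bad = records.index[records["time"] <= 0][0]
        raise ValidationError(f"non-positive survival time for sample {bad!r}")
    out = records.copy()
    if "cause" in out.columns:
        other = (out["event"] == 1) & (out["cause"].astype(str) != disease_cause)
        out.loc[other, "event"] = 0
    late = out["time"] > horizon
    out.loc[late, "time"] = horizon
    out.loc[late, "event"] = 0
    return out


def km_curve(records: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Per-group Kaplan-Meier product-limit estimates.

    Returns, per group, a step-function table with columns ``time`` and
    ``survival``.
    """
    out: dict[str, pd.DataFrame] = {}
    for g in sorted(groups.unique(), key=str):
        ids = groups.index[groups == g]
        if len(ids) == 0:
            raise ValidationError(f"empty survival group {g!r}")
        sub = records.loc[ids]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank(records: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """K-group log-rank test; returns (chi-square, p) with k-1 df."""
    groups = groups.loc[records.index]
    if groups.nunique() < 2:
        raise ValidationError("log-rank test needs >=2 groups")
    for g in groups.unique():
        if len(groups[groups == g]) == 0:
            raise ValidationError(f"empty survival group {g!r}")
    res = multivariate_logrank_test(
        records["time"], groups.astype(str), records["event"]
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class RiskGroups:
    """High/low risk groups with per-group event accounting."""

    groups: pd.Series  # sample -> "high" | "low"
    events: dict[str, tuple[int, int]]  # group -> (events, total)


def risk_groups(
    values: pd.Series, records: pd.DataFrame, rule: str = "top_third"
) -> RiskGroups:
    """Tertile risk groups from a score or predicted probability.

    Reports events/total per group, matching the usual KM-legend accounting.
    """
    labels = dichotomize(values, rule=rule)
    groups = labels.labels.map({1: "high", 0: "low"})
    events: dict[str, tuple[int, int]] = {}
    for g in ("high", "low"):
        ids = groups.index[groups == g]
        sub = records.loc[[i for i in ids if i in records.index]]
        events[g] = (int(sub["event"].sum()), int(len(sub)))
    return RiskGroups(groups=groups, events=events)
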