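"""Kaplan-Meier estimation and log-rank stratification of patient cohorts.

Survival records carry a time in months and an event flag (death
observed vs. censored).  The cohort analysis follows the convention of
excluding patients with follow-up longer than 60 months ("longer than"
read strictly, so a time of exactly 60 is kept), splitting the remaining
patients on a molecular stratifier (median split or extreme quantiles),
and comparing the groups with a two-group log-rank test.  Estimation and
testing are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort_scoring import median_split, quantile_groups

log = logging.getLogger(__name__)

REQUIRED_COLS = ("patient_id", "time_months", "event")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLS) - set(records.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s) {sorted(missing)}")
    rec = records.copy()
    rec["time_months"] = rec["time_months"].astype(float)
    rec["event"] = rec["event"].astype(int)
    if not np.isfinite(rec["time_months"]).all() or (rec["time_months"] <= 0).any():
        raise ValueError("survival times must be finite and positive")
    if rec["patient_id"].duplicated().any():
        dups = rec.loc[rec["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id(s): {dups}")
    if not rec["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return rec


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV (patient_id, time_months, event in {0,1})."""
    return _validate(pd.read_csv(path, sep="\t"))


def filter_survival(records: pd.DataFrame, max_months: float = 60.0) -> pd.DataFrame:
    """Drop patients with survival times longer than ``max_months``.

    The boundary is inclusive: time == max_months is retained.
    """
    if max_months <= 0:
        raise ValueError("max_months must be positive")
    rec = _validate(records)
    kept = rec[rec["time_months"] <= max_months].reset_index(drop=True)
    n_removed = len(rec) - len(kept)
    if n_removed:
        log.info("filter_survival: excluded %d patient(s) with time > %g", n_removed, max_months)
    if kept.empty:
        raise ValueError("no patients remain after the follow-up filter")
    return kept


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored times reduce the risk set but not the survival estimate;
    ties between events and censorings at one time count the events
    first (the standard convention).
    """
    rec = _validate(records)
    if rec.empty:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(rec["time_months"], event_observed=rec["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(float)
    surv = kmf.survival_function_at_times(times).to_numpy(float)
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(int),
        n_events=ev["observed"].to_numpy(int),
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    a = _validate(group_a)
    b = _validate(group_b)
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if int(a["event"].sum() + b["event"].sum()) == 0:
        raise ValueError("no events in the pooled data; log-rank undefined")
    res = _ll_logrank(
        a["time_months"], b["time_months"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class StratifiedSurvival:
    low_ids: list[str]
    high_ids: list[str]
    low_curve: KMCurve
    high_curve: KMCurve
    chi2: float
    p_value: float


def stratified_survival(
    records: pd.DataFrame,
    stratifier: pd.Series,
    grouping: Literal["median"] | float = "median",
    max_months: float = 60.0,
) -> StratifiedSurvival:
    """Follow-up filter -> stratifier split -> per-group KM -> log-rank.

    ``grouping`` is either "median" or an extreme fraction (e.g. 0.10 for
    the lowest vs. highest deciles).  The stratifier must cover every
    patient that survives the follow-up filter.
    """
    kept = filter_survival(records, max_months)
    uncovered = set(kept["patient_id"]) - set(stratifier.index)
    if uncovered:
        raise ValueError(f"stratifier missing patient(s): {sorted(uncovered)[:5]}")
    values = stratifier.loc[kept["patient_id"]]
    if grouping == "median":
        low_ids, high_ids = median_split(values)
    else:
        low_ids, high_ids = quantile_groups(values, float(grouping))
    if not low_ids or not high_ids:
        raise ValueError("empty stratification group (constant stratifier?)")
    by_id = kept.set_index("patient_id", drop=False)
    low = by_id.loc[low_ids]
    high = by_id.loc[high_ids]
    chi2, p = logrank_test(low, high)
    return StratifiedSurvival(
        low_ids=list(low_ids),
        high_ids=list(high_ids),
        low_curve=km_estimate(low),
        high_curve=km_estimate(high),
        chi2=chi2,
        p_value=p,
    )
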