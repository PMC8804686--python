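"""Time-to-event analysis: Kaplan-Meier estimates and log-rank tests.

Endpoints: time to first qualifying irAE and to first severe (grade 3-5)
irAE in weeks from the first ICI dose, and PFS/OS in months restricted to
stage IV patients. Event-free patients are censored at their last
follow-up. Estimation and testing go through lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .synthetic import qualifying_events

WEEKS_PER_MONTH = 365.25 / 7 / 12  # ~4.348

ENDPOINTS = ("first_irae", "first_severe_irae", "pfs", "os")


@dataclass
class KMEstimate:
    curve: pd.DataFrame  # time, survival, at_risk
    median: float  # earliest time with S <= 0.5; nan if never reached
    n: int
    n_events: int


def km_estimate(times, events=None) -> KMEstimate:
    """Product-limit survival estimate.

    ``events`` defaults to all-observed. The median is the earliest time
    at which the estimated survival drops to 0.5 or below, NaN when the
    curve never reaches it (e.g. everything censored).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need >= 1 subject")
    if np.any(times < 0):
        raise ValueError("negative times")
    events = np.ones_like(times, dtype=bool) if events is None else np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    curve = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
        }
    )
    median = kmf.median_survival_time_
    median = float(median) if np.isfinite(median) else np.nan
    return KMEstimate(curve=curve, median=median, n=int(times.size), n_events=int(events.sum()))


def logrank(times_a, times_b, events_a=None, events_b=None) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p.

    With no events in either group the test is undefined and
    ``(nan, nan)`` is returned.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be nonempty")
    events_a = np.ones_like(times_a, dtype=bool) if events_a is None else np.asarray(events_a, dtype=bool)
    events_b = np.ones_like(times_b, dtype=bool) if events_b is None else np.asarray(events_b, dtype=bool)
    if events_a.sum() + events_b.sum() == 0:
        return np.nan, np.nan
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def build_time_to_event(
    events: pd.DataFrame,
    clinical: pd.DataFrame,
    survival: pd.DataFrame,
    endpoint: str,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble (time, event, stratum) rows for one endpoint.

    irAE endpoints: time in weeks to the first qualifying (definite or
    probable) event — any grade or grade >= 3 — with event-free patients
    censored at last follow-up. PFS/OS: months, stage IV patients only.
    ``strata`` optionally maps patient_id to a group label (e.g. baseline
    seropositivity).
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    clin = clinical.set_index("patient_id")
    if endpoint in ("pfs", "os"):
        rows = survival[survival["stage"] == "IV"]
        out = pd.DataFrame(
            {
                "patient_id": rows["patient_id"],
                "time": rows[f"{endpoint}_months"].astype(float),
                "event": rows[f"{endpoint}_event"].astype(bool),
                "unit": "months",
            }
        )
    else:
        qual = qualifying_events(events)
        if endpoint == "first_severe_irae":
            qual = qual[qual["grade"] >= 3]
        first = qual.groupby("patient_id")["onset_week"].min() if not qual.empty else pd.Series(dtype=float)
        followup_weeks = clin["followup_months"].astype(float) * WEEKS_PER_MONTH
        time = first.reindex(clin.index)
        observed = time.notna()
        out = pd.DataFrame(
            {
                "patient_id": clin.index,
                "time": np.where(observed, time, followup_weeks),
                "event": observed.to_numpy(),
                "unit": "weeks",
            }
        )
    if strata is not None:
        out["stratum"] = strata.reindex(out["patient_id"]).to_numpy()
    return out.reset_index(drop=True)


def km_by_stratum(tte: pd.DataFrame) -> tuple[dict[str, KMEstimate], tuple[float, float]]:
    """KM per stratum plus the two-group log-rank when exactly 2 strata."""
    curves = {}
    for label, chunk in tte.groupby("stratum"):
        curves[str(label)] = km_estimate(chunk["time"], chunk["event"])
    labels = sorted(curves)
    if len(labels) == 2:
        a = tte[tte["stratum"] == labels[0]]
        b = tte[tte["stratum"] == labels[1]]
        stat_p = logrank(a["time"], b["time"], a["event"], b["event"])
    else:
        stat_p = (np.nan, np.nan)
    return curves, stat_p
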