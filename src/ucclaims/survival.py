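"""Time-to-event machinery: event-free curves from onset and treatment
persistence, with log-rank comparisons.

Estimation is the product-limit (Kaplan–Meier) method via ``lifelines``;
censored subjects at an event time are counted at risk for that time
(the standard convention).  Death is handled as right-censoring, not as
a competing risk — a documented simplification appropriate for plain KM
readouts.  The 5-year readout point is 1826 days (365.25 × 5, rounded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "FIVE_YEARS_DAYS",
    "SurvivalCurve",
    "extract_time_to_event",
    "km_estimate",
    "greenwood_se",
    "logrank_test",
    "persistence_curve",
    "persistence_times",
]

#: days used for "at 5 years" readouts
FIVE_YEARS_DAYS = 1826

_OUTCOME_DATE = {"steroid": "steroid_date", "mtd": "mtd_date", "surgery": "surgery_date"}


@dataclass
class SurvivalCurve:
    """A right-continuous step-function survival estimate."""

    times: np.ndarray          # distinct event/censor times, days from origin
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray       # estimate immediately after each time
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function value at time ``t`` (1.0 before the first time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
                "survival": self.survival,
                "group": self.label,
            }
        )


def extract_time_to_event(cohort: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Per-patient time from onset to an outcome, with censoring.

    ``outcome`` is one of ``steroid``, ``mtd``, ``surgery``.  The origin
    is the onset date; events are the first new steroid prescription,
    first MTD episode start, or first surgery; censoring is at the
    earlier of observation end and death.  Returns columns
    ``patient_id``, ``time`` (days), ``event``, ``group``.
    """
    try:
        date_col = _OUTCOME_DATE[outcome]
    except KeyError:
        raise ValueError(
            f"unknown outcome {outcome!r}; expected one of {sorted(_OUTCOME_DATE)}"
        ) from None
    censor = cohort["obs_end"].copy()
    has_death = cohort["death_date"].notna()
    censor[has_death] = np.minimum(censor[has_death], cohort.loc[has_death, "death_date"])
    event_date = pd.to_datetime(cohort[date_col])
    event = event_date.notna() & (event_date <= censor)
    end = event_date.where(event, censor)
    time = (pd.to_datetime(end) - cohort["onset_date"]).dt.days
    if (time < 0).any():
        raise ValueError("negative follow-up time; outcome date precedes onset")
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "time": time.astype(int),
            "event": event.astype(int),
            "group": cohort["onset_group"],
        }
    ).reset_index(drop=True)


def km_estimate(
    times, events, label: str = ""
) -> SurvivalCurve:
    """Product-limit estimate from durations and event indicators."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate needs at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # lifelines inserts a t=0 row when no subject has time 0; drop it
    table = kmf.event_table
    if table.index[0] == 0.0 and table.iloc[0][["observed", "censored"]].sum() == 0:
        table = table.iloc[1:]
    tt = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(tt).to_numpy(dtype=float)
    return SurvivalCurve(
        times=tt,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        survival=surv,
        label=label,
    )


def greenwood_se(curve: SurvivalCurve, t: float) -> float:
    """Greenwood standard error of the survival estimate at time ``t``."""
    mask = (curve.times <= t) & (curve.events > 0)
    n = curve.at_risk[mask].astype(float)
    d = curve.events[mask].astype(float)
    if np.any(n <= d):
        return math.nan  # estimate hit zero; variance undefined beyond
    var = curve.survival_at(t) ** 2 * np.sum(d / (n * (n - d)))
    return float(math.sqrt(var))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank test; returns ``(chi-square statistic, p)``."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(events_a, int),
                      event_observed_B=np.asarray(events_b, int))
    return float(res.test_statistic), float(res.p_value)


def persistence_times(
    first_mtd_table: pd.DataFrame,
) -> pd.DataFrame:
    """Durations from first-MTD start to discontinuation or censoring.

    Input is the per-patient first-MTD table (columns ``patient_id``,
    ``drug_id``, ``start_date``, ``end_date``, ``status``).  Event = the
    episode ended discontinued; ongoing episodes are censored at their
    ``end_date`` (the censor date).
    """
    time = (pd.to_datetime(first_mtd_table["end_date"])
            - pd.to_datetime(first_mtd_table["start_date"])).dt.days
    event = (first_mtd_table["status"] == "discontinued").astype(int)
    return pd.DataFrame(
        {
            "patient_id": first_mtd_table["patient_id"].to_numpy(),
            "drug_id": first_mtd_table["drug_id"].to_numpy(),
            "time": time.to_numpy(dtype=int),
            "event": event.to_numpy(),
        }
    )


def persistence_curve(
    first_mtd_table: pd.DataFrame, labels: pd.Series | None = None
) -> dict[str, SurvivalCurve]:
    """Treatment-persistence curves of the first MTD, one per stratum.

    ``labels`` maps patient_id -> stratum (onset group, drug, or the
    azathioprine combination flag); omitted, a single curve labelled
    ``"all"`` is returned.
    """
    tte = persistence_times(first_mtd_table)
    if labels is None:
        return {"all": km_estimate(tte["time"], tte["event"], label="all")}
    lab = tte["patient_id"].map(labels)
    curves = {}
    for value, grp in tte.groupby(lab):
        curves[str(value)] = km_estimate(grp["time"], grp["event"], label=str(value))
    return curves
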