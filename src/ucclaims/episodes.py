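"""New/old prescription classification and exposure-episode construction.

Two definitions drive everything here:

* a prescription of a drug is **new** when the same drug was not
  prescribed within the 26 weeks (182 days) before it, and **old**
  otherwise;
* a treatment episode is **discontinued** when no refill arrives for more
  than 13 weeks (91 days) past the *next scheduled prescription date*
  (:func:`ucclaims.catalog.next_scheduled_date`).

Both windows are deliberately asymmetric at their boundaries: a prior
prescription at exactly 182 days does *not* make a prescription old, and
a refill exactly 91 days late does *not* discontinue the episode (the
rules read "within 26 weeks" / "for >13 weeks").  A discontinued
episode's ``end_date`` is its last scheduled date, so persistence time
never credits uncovered calendar time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .catalog import DrugCatalog, DrugSpec, next_scheduled_date, refill_interval_days

__all__ = [
    "WASHOUT_DAYS",
    "GRACE_DAYS",
    "ExposureEpisode",
    "classify_prescription_novelty",
    "build_episodes",
    "build_all_episodes",
    "episodes_to_frame",
    "first_mtd",
    "combination_flag",
    "count_mtd_lines",
]

logger = logging.getLogger(__name__)

#: 26-week washout defining a "new" prescription, in days
WASHOUT_DAYS = 182
#: 13-week grace past the next scheduled date before discontinuation, in days
GRACE_DAYS = 91


@dataclass
class ExposureEpisode:
    """A continuous treatment interval for one patient-drug."""

    patient_id: str
    drug_id: str
    start_date: pd.Timestamp
    last_rx_date: pd.Timestamp
    scheduled_next: pd.Timestamp
    end_date: pd.Timestamp
    status: str  # "discontinued" | "ongoing_at_censor"
    covered_days: int
    n_prescriptions: int

    @property
    def duration_days(self) -> int:
        return int((self.end_date - self.start_date).days)


def classify_prescription_novelty(
    history: Iterable[pd.Timestamp], rx_date: pd.Timestamp
) -> str:
    """Classify a prescription as ``"new"`` or ``"old"``.

    ``history`` holds the patient's earlier prescription dates of the
    *same drug*.  The washout window is half-open: a prior prescription
    at exactly 182 days before ``rx_date`` leaves it new.
    """
    rx_date = pd.Timestamp(rx_date)
    for prior in history:
        delta = (rx_date - pd.Timestamp(prior)).days
        if delta <= 0:
            raise ValueError("history must lie strictly before rx_date")
        if delta < WASHOUT_DAYS:
            return "old"
    return "new"


def _merge_same_day(
    prescriptions: Sequence[tuple[pd.Timestamp, int]],
) -> list[tuple[pd.Timestamp, int]]:
    """Merge duplicate same-day claim lines of one drug, summing amounts."""
    merged: list[tuple[pd.Timestamp, int]] = []
    for date, qty in prescriptions:
        if merged and merged[-1][0] == date:
            merged[-1] = (date, merged[-1][1] + int(qty))
        else:
            merged.append((pd.Timestamp(date), int(qty)))
    return merged


def _covered_days(
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]], censor_date: pd.Timestamp
) -> int:
    """Days in the union of half-open coverage intervals, clipped at censor."""
    clip_end = censor_date + pd.Timedelta(days=1)
    total = 0
    cur_start = cur_end = None
    for start, end in intervals:  # already start-sorted
        end = min(end, clip_end)
        if end <= start:
            continue
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += (cur_end - cur_start).days
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += (cur_end - cur_start).days
    return int(total)


def build_episodes(
    prescriptions: Sequence[tuple[pd.Timestamp, int]],
    spec: DrugSpec,
    censor_date: pd.Timestamp,
    patient_id: str = "",
) -> list[ExposureEpisode]:
    """Assemble ordered exposure episodes for one patient-drug.

    ``prescriptions`` is a date-sorted sequence of ``(date, amount)``
    claim lines (amount = covered days or dispensed count, per the drug's
    rule).  A prescription on or before ``scheduled_next + 91 days``
    extends the running episode; a later one closes it as discontinued at
    ``scheduled_next`` and opens a new episode.  The final episode is
    discontinued if the censor date lies beyond its grace window,
    otherwise it is ongoing at censoring with ``end_date`` = censor.
    """
    censor_date = pd.Timestamp(censor_date)
    rxs = [(pd.Timestamp(d), int(q)) for d, q in prescriptions]
    if any(rxs[i][0] > rxs[i + 1][0] for i in range(len(rxs) - 1)):
        raise ValueError("prescriptions must be date-sorted")
    rxs = _merge_same_day(rxs)
    if not rxs:
        return []
    if censor_date < rxs[-1][0]:
        raise ValueError("censor_date precedes the last prescription")

    grace = pd.Timedelta(days=GRACE_DAYS)
    episodes: list[ExposureEpisode] = []

    start = last = rxs[0][0]
    scheduled = next_scheduled_date(spec, last, rxs[0][1])
    n_rx = 1
    cover: list[tuple[pd.Timestamp, pd.Timestamp]] = [
        (last, last + pd.Timedelta(days=refill_interval_days(spec, rxs[0][1])))
    ]

    def close(status: str, end: pd.Timestamp) -> None:
        episodes.append(
            ExposureEpisode(
                patient_id=patient_id,
                drug_id=spec.drug_id,
                start_date=start,
                last_rx_date=last,
                scheduled_next=scheduled,
                end_date=end,
                status=status,
                covered_days=_covered_days(cover, min(end, censor_date)),
                n_prescriptions=n_rx,
            )
        )

    for date, qty in rxs[1:]:
        if date <= scheduled + grace:
            last = date
            scheduled = next_scheduled_date(spec, date, qty)
            n_rx += 1
            cover.append((date, date + pd.Timedelta(days=refill_interval_days(spec, qty))))
        else:
            close("discontinued", scheduled)
            start = last = date
            scheduled = next_scheduled_date(spec, date, qty)
            n_rx = 1
            cover = [(date, date + pd.Timedelta(days=refill_interval_days(spec, qty)))]

    if censor_date > scheduled + grace:
        close("discontinued", scheduled)
    else:
        close("ongoing_at_censor", censor_date)
    return episodes


def build_all_episodes(
    prescriptions: pd.DataFrame,
    catalog: DrugCatalog,
    censor_dates: pd.Series,
) -> pd.DataFrame:
    """Build episodes for every patient-drug in a prescription table.

    ``prescriptions`` needs columns ``patient_id``, ``drug_id``, ``date``,
    ``quantity``; ``censor_dates`` maps patient_id -> censor date (end of
    that patient's observation).  Returns the episode table produced by
    :func:`episodes_to_frame`.
    """
    out: list[ExposureEpisode] = []
    rx = prescriptions.sort_values(["patient_id", "drug_id", "date"])
    for (pid, drug_id), grp in rx.groupby(["patient_id", "drug_id"], sort=True):
        spec = catalog.get(drug_id)
        censor = pd.Timestamp(censor_dates.loc[pid])
        out.extend(
            build_episodes(
                list(zip(grp["date"], grp["quantity"])), spec, censor, patient_id=pid
            )
        )
    return episodes_to_frame(out)


_EPISODE_COLUMNS = [
    "patient_id",
    "drug_id",
    "start_date",
    "last_rx_date",
    "scheduled_next",
    "end_date",
    "status",
    "covered_days",
    "n_prescriptions",
]


def episodes_to_frame(episodes: Iterable[ExposureEpisode]) -> pd.DataFrame:
    rows = [
        {col: getattr(ep, col) for col in _EPISODE_COLUMNS} for ep in episodes
    ]
    if not rows:
        return pd.DataFrame(columns=_EPISODE_COLUMNS)
    return pd.DataFrame(rows, columns=_EPISODE_COLUMNS)


def first_mtd(
    episodes: pd.DataFrame, catalog: DrugCatalog
) -> pd.DataFrame:
    """Earliest molecular-targeting-drug episode per patient.

    Ties on the start date are broken lexicographically on drug id and
    logged.  Returns one row per patient with an MTD episode: columns
    ``patient_id``, ``drug_id``, ``start_date``, ``end_date``, ``status``.
    """
    mtd = episodes[episodes["drug_id"].isin(catalog.mtd_ids)]
    if mtd.empty:
        return mtd.loc[:, ["patient_id", "drug_id", "start_date", "end_date", "status"]]
    mtd = mtd.sort_values(["patient_id", "start_date", "drug_id"])
    firsts = mtd.groupby("patient_id", sort=True).head(1)
    # log start-date ties between distinct drugs
    earliest = mtd.groupby("patient_id")["start_date"].transform("min")
    at_min = mtd[mtd["start_date"] == earliest]
    ties = at_min.groupby("patient_id")["drug_id"].nunique()
    for pid in ties.index[ties > 1]:
        tied = sorted(at_min.loc[at_min["patient_id"] == pid, "drug_id"].unique())
        logger.info(
            "first-MTD tie for patient %s between %s; kept %s (lexicographic)",
            pid,
            tied,
            tied[0],
        )
    return firsts.loc[:, ["patient_id", "drug_id", "start_date", "end_date", "status"]]


def combination_flag(
    ifx_start: pd.Timestamp, aza_episodes: pd.DataFrame | list[ExposureEpisode]
) -> bool:
    """True when an azathioprine episode is active on the infliximab start date.

    An episode is active on a date when ``start_date <= date <= end_date``
    (ongoing episodes extend to their censor-valued ``end_date``).
    """
    ifx_start = pd.Timestamp(ifx_start)
    if isinstance(aza_episodes, pd.DataFrame):
        rows = aza_episodes.itertuples()
        return any(r.start_date <= ifx_start <= r.end_date for r in rows)
    return any(ep.start_date <= ifx_start <= ep.end_date for ep in aza_episodes)


def count_mtd_lines(episodes: pd.DataFrame, catalog: DrugCatalog) -> int:
    """Number of distinct molecular targeting drugs with >=1 episode."""
    mtd = episodes[episodes["drug_id"].isin(catalog.mtd_ids)]
    return int(mtd["drug_id"].nunique())
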