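"""Cohort extraction: case identification, onset estimation, age grouping.

The extraction flow mirrors a new-user claims design for ulcerative
colitis (UC):

1. UC cases are patients with at least one non-suspicious ICD-10 K51
   diagnosis and no Crohn's disease (K50) code at any time.
2. Disease onset is proxied by the earliest *new* prescription of a
    5-ASA, systemic steroid, or topical steroid; a patient with any *old*
   prescription of those classes anywhere in the observation period is
   treated as a prevalent (not new-onset) case and dropped.
3. Retained patients must be aged >=65 at the end of observation and are
   split by age at onset: elderly onset (EO, onset at >=65) versus
   non-elderly onset (NEO, onset before 65 with ageing past 65 under
   observation).

Birth dates are year-month only; the day is taken as the 1st and ages
are completed calendar years, so the grouping is deterministic under the
claims extract's granularity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .bundle import ClaimsBundle
from .catalog import DrugCatalog
from .episodes import (
    WASHOUT_DAYS,
    build_all_episodes,
    classify_prescription_novelty,
    combination_flag,
    count_mtd_lines,
    first_mtd,
)

__all__ = [
    "ExclusionTally",
    "identify_uc_cases",
    "estimate_onset",
    "classify_group",
    "build_cohort",
    "age_completed_years",
    "parse_birth_ym",
]

logger = logging.getLogger(__name__)

_ICD_PATTERN = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")


def parse_birth_ym(birth_year_month: str) -> pd.Timestamp:
    """Year-month birth field -> timestamp at the 1st of the month."""
    return pd.Timestamp(f"{birth_year_month}-01")


def age_completed_years(birth_year_month: str, at: pd.Timestamp) -> int:
    """Completed age in years at ``at`` with a month-granular birth date.

    The birth day is unknown and taken as the 1st, so any date in the
    birth month counts the birthday as passed.
    """
    birth = parse_birth_ym(birth_year_month)
    at = pd.Timestamp(at)
    if at < birth:
        raise ValueError("date precedes birth")
    return at.year - birth.year - (1 if at.month < birth.month else 0)


@dataclass
class ExclusionTally:
    """Per-step exclusion counts of the extraction flow."""

    input_patients: int = 0
    no_uc_diagnosis: int = 0
    suspicious_only: int = 0
    crohns: int = 0
    not_new_onset: int = 0
    under_65: int = 0
    retained: int = 0
    malformed_diagnosis_rows: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}

    def check(self) -> None:
        steps = (
            self.no_uc_diagnosis
            + self.suspicious_only
            + self.crohns
            + self.not_new_onset
            + self.under_65
            + self.retained
        )
        if steps != self.input_patients:
            raise AssertionError(
                f"exclusion tally does not sum: {steps} != {self.input_patients}"
            )


def identify_uc_cases(diagnoses: pd.DataFrame) -> tuple[set[str], int]:
    """Patients with >=1 non-suspicious K51 code and no K50 code.

    Rows with malformed ICD-10 codes are skipped with a logged count;
    returns ``(patient ids, n malformed rows skipped)``.
    """
    codes = diagnoses["icd10"].astype(str).str.strip()
    ok = codes.str.match(_ICD_PATTERN)
    n_malformed = int((~ok).sum())
    if n_malformed:
        logger.warning("skipped %d malformed ICD-10 diagnosis rows", n_malformed)
    dx = diagnoses[ok.values]
    codes = codes[ok.values]
    is_k51 = codes.str.startswith("K51")
    is_k50 = codes.str.startswith("K50")
    suspicion = dx["suspicion"].astype(int) != 0
    uc = set(dx.loc[is_k51.values & (~suspicion).values, "patient_id"])
    crohns = set(dx.loc[is_k50.values, "patient_id"])
    return uc - crohns, n_malformed


def estimate_onset(
    prescriptions: pd.DataFrame,
    catalog: DrugCatalog,
    observation_start: pd.Timestamp | None = None,
) -> tuple[pd.Timestamp | None, bool]:
    """Estimated UC onset date for one patient, or ``None``.

    ``prescriptions`` holds one patient's claims (columns ``drug_id``,
    ``date``).  Onset is the earliest new prescription among the 5-ASA /
    systemic steroid / topical steroid classes, provided *no*
    prescription of those classes is old anywhere in the record; a
    single old qualifying prescription marks the patient prevalent and
    returns ``None``.

    The second element flags insufficient washout lookback: the earliest
    qualifying prescription falls within 26 weeks of the observation
    start (or of the first record when ``observation_start`` is not
    given), so a pre-observation prescription cannot be ruled out.
    Such patients are still classified new-onset (absence of evidence),
    with the shortfall recorded as a quality flag.
    """
    qualifying = catalog.onset_ids
    rx = prescriptions[prescriptions["drug_id"].isin(qualifying)]
    if rx.empty:
        return None, False
    rx = rx.sort_values("date")
    for drug_id, grp in rx.groupby("drug_id"):
        dates = list(grp["date"])
        for i, d in enumerate(dates):
            history = [p for p in dates[:i] if p < d]  # same-day merged upstream
            if classify_prescription_novelty(history, d) == "old":
                return None, False
    onset = rx["date"].min()
    if observation_start is None:
        observation_start = prescriptions["date"].min()
    lookback_short = (onset - pd.Timestamp(observation_start)).days < WASHOUT_DAYS
    return onset, bool(lookback_short)


def classify_group(
    onset_date: pd.Timestamp, birth_year_month: str, observation_end: pd.Timestamp
) -> str:
    """``"EO"``, ``"NEO"`` or ``"ineligible"`` by age at onset and at end."""
    age_at_onset = age_completed_years(birth_year_month, onset_date)
    age_at_end = age_completed_years(birth_year_month, observation_end)
    if age_at_onset >= 65:
        return "EO"
    if age_at_end >= 65:
        return "NEO"
    return "ineligible"


_COHORT_COLUMNS = [
    "patient_id", "sex", "birth_year_month", "onset_date", "age_at_onset",
    "age_at_end", "onset_group", "obs_start", "obs_end", "academic",
    "lookback_short", "death", "death_date", "surgery", "surgery_date",
    "steroid_use", "steroid_date", "mtd_use", "mtd_drug", "mtd_date",
    "mtd_end", "mtd_status", "mtd_lines", "steroid_po_days", "steroid_iv_days",
    "ifx_combo",
]


def build_cohort(
    bundle: ClaimsBundle, catalog: DrugCatalog
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionTally]:
    """Run the full extraction flow on a claims bundle.

    Returns ``(cohort, episodes, tally)``: the cohort table (one row per
    retained patient, with outcome indicators and dates), the exposure
    episode table for retained patients, and the per-step exclusion
    tally.  Exclusions are applied in flowchart order: no UC code,
    suspicious-only UC codes, Crohn's co-diagnosis, not new-onset,
    never aged >=65.
    """
    patients = bundle.patients
    tally = ExclusionTally(input_patients=len(patients))

    dx = bundle.diagnoses
    codes = dx["icd10"].astype(str).str.strip()
    valid = codes.str.match(_ICD_PATTERN)
    uc_ids, tally.malformed_diagnosis_rows = identify_uc_cases(dx)
    has_k51 = set(dx.loc[valid.values & codes.str.startswith("K51").values, "patient_id"])
    has_clean_k51 = set(
        dx.loc[
            valid.values
            & codes.str.startswith("K51").values
            & (dx["suspicion"].astype(int) == 0).values,
            "patient_id",
        ]
    )
    has_k50 = set(dx.loc[valid.values & codes.str.startswith("K50").values, "patient_id"])

    all_ids = list(patients["patient_id"])
    tally.no_uc_diagnosis = sum(1 for p in all_ids if p not in has_k51)
    tally.suspicious_only = sum(
        1 for p in all_ids if p in has_k51 and p not in has_clean_k51
    )
    tally.crohns = sum(1 for p in all_ids if p in has_clean_k51 and p in has_k50)

    rx_all = bundle.prescriptions.sort_values(["patient_id", "date"])
    rx_by_patient = dict(tuple(rx_all.groupby("patient_id")))
    pat_idx = patients.set_index("patient_id")

    onset_info: dict[str, tuple[pd.Timestamp, bool]] = {}
    grouped: dict[str, str] = {}
    for pid in all_ids:
        if pid not in uc_ids:
            continue
        rx = rx_by_patient.get(pid)
        if rx is None:
            tally.not_new_onset += 1
            continue
        row = pat_idx.loc[pid]
        onset, lookback_short = estimate_onset(rx, catalog, row["obs_start"])
        if onset is None:
            tally.not_new_onset += 1
            continue
        group = classify_group(onset, row["birth_year_month"], row["obs_end"])
        if group == "ineligible":
            tally.under_65 += 1
            continue
        onset_info[pid] = (onset, lookback_short)
        grouped[pid] = group

    retained = sorted(onset_info)
    tally.retained = len(retained)
    tally.check()

    rx_retained = rx_all[rx_all["patient_id"].isin(retained)]
    episodes = build_all_episodes(rx_retained, catalog, bundle.censor_dates)

    ev = bundle.events
    surgery_first = (
        ev[ev["event_type"] == "surgery"].groupby("patient_id")["date"].min()
    )

    steroid_ids = catalog.ids_of_classes({"systemic_steroid"})
    steroid_po = {s for s in steroid_ids if catalog.get(s).route == "po"}
    steroid_iv = {s for s in steroid_ids if catalog.get(s).route == "iv"}
    firsts = first_mtd(episodes, catalog).set_index("patient_id") if len(episodes) else None

    rows = []
    for pid in retained:
        row = pat_idx.loc[pid]
        onset, lookback_short = onset_info[pid]
        ep = episodes[episodes["patient_id"] == pid]
        rx = rx_by_patient[pid]

        # first *new* systemic steroid prescription = first steroid episode start
        st_ep = ep[ep["drug_id"].isin(steroid_ids)]
        steroid_date = st_ep["start_date"].min() if len(st_ep) else pd.NaT

        mtd_drug = mtd_date = mtd_end = mtd_status = None
        if firsts is not None and pid in firsts.index:
            f = firsts.loc[pid]
            mtd_drug, mtd_date = f["drug_id"], f["start_date"]
            mtd_end, mtd_status = f["end_date"], f["status"]

        ifx_combo = None
        if mtd_drug == "infliximab":
            aza = ep[ep["drug_id"] == "azathioprine"]
            ifx_combo = combination_flag(mtd_date, aza)

        st_rx = rx[rx["drug_id"].isin(steroid_po)]
        po_days = int(st_rx["quantity"].sum()) if len(st_rx) else 0
        st_rx = rx[rx["drug_id"].isin(steroid_iv)]
        iv_days = int(st_rx["quantity"].sum()) if len(st_rx) else 0

        death_date = row["death_date"]
        surg_date = surgery_first.get(pid, pd.NaT)
        rows.append(
            {
                "patient_id": pid,
                "sex": row["sex"],
                "birth_year_month": row["birth_year_month"],
                "onset_date": onset,
                "age_at_onset": age_completed_years(row["birth_year_month"], onset),
                "age_at_end": age_completed_years(row["birth_year_month"], row["obs_end"]),
                "onset_group": grouped[pid],
                "obs_start": row["obs_start"],
                "obs_end": row["obs_end"],
                "academic": int(row["academic"]),
                "lookback_short": bool(lookback_short),
                "death": int(pd.notna(death_date)),
                "death_date": death_date,
                "surgery": int(pd.notna(surg_date)),
                "surgery_date": surg_date,
                "steroid_use": int(pd.notna(steroid_date)),
                "steroid_date": steroid_date,
                "mtd_use": int(mtd_drug is not None),
                "mtd_drug": mtd_drug,
                "mtd_date": mtd_date,
                "mtd_end": mtd_end,
                "mtd_status": mtd_status,
                "mtd_lines": count_mtd_lines(ep, catalog),
                "steroid_po_days": po_days,
                "steroid_iv_days": iv_days,
                "ifx_combo": ifx_combo,
            }
        )

    cohort = pd.DataFrame(rows, columns=_COHORT_COLUMNS)
    return cohort, episodes, tally
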