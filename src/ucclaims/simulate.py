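"""Synthetic claims generator emulating an insurer UC extract.

The generator produces the four claims tables with the statistical
structure the downstream analysis assumes, so the whole pipeline is
testable without any proprietary data:

* onset ages from a two-component normal mixture (young-adult and
  elderly peaks of ulcerative colitis incidence);
* a 5-ASA maintenance refill process from onset.  Maintenance supplies
  are dispensed as 27-week (189-day) prescriptions refilled on
  schedule, so consecutive refills are always >=26 weeks apart and every
  refill stays "new" under the washout rule — the new-onset condition
  (no old qualifying prescription anywhere in the record) then retains
  these patients by construction;
* systemic (and optional topical) steroid exposure as single-course
  prescriptions, initiated at exponential group-specific hazards
  calibrated by 5-year steroid-free survival;
* molecular-targeting-drug (MTD) initiation at group-specific hazards,
  with per-drug refill trains following each catalog rule plus bounded
  jitter, explicit simulated discontinuations and second-line switches,
  and optional azathioprine combination at infliximab start;
* surgery at group-specific hazards; death from a logistic model with
  configurable odds ratios for elderly onset and steroid use (death
  closes the observation window and truncates later records);
* contamination paths (suspicious-only diagnoses, Crohn's co-diagnosis,
  prevalent 5-ASA users) to exercise each exclusion branch.

Everything is drawn from one ``numpy`` generator seeded from the config,
so equal configs give byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle
from .catalog import DrugCatalog, default_catalog, refill_interval_days
from .cohort import age_completed_years

__all__ = ["GeneratorConfig", "generate_claims", "make_fixture", "FIXTURE_CASES",
           "rate_from_s5"]


def rate_from_s5(s5: float) -> float:
    """Yearly exponential rate from a 5-year event-free survival."""
    if not 0.0 < s5 < 1.0:
        raise ValueError(f"5-year survival must be in (0,1); got {s5}")
    return -math.log(s5) / 5.0


#: first-MTD choice distribution (breakdown typical of elderly UC claims)
_DEFAULT_MTD_PROBS = {
    "infliximab": 0.314,
    "adalimumab": 0.076,
    "golimumab": 0.060,
    "ustekinumab": 0.070,
    "vedolizumab": 0.195,
    "tofacitinib": 0.016,
    "tacrolimus": 0.195,
    "ciclosporin_po": 0.069,
    "ciclosporin_iv": 0.005,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic claims generator.

    Event-process intensities are parameterised the way results are
    usually reported: 5-year event-free survival per onset group for the
    time-to-event processes, and a baseline probability plus odds ratios
    for death.
    """

    n_patients: int = 3000
    seed: int = 0
    # onset-age mixture: (young, elderly) components
    onset_age_means: tuple[float, float] = (25.0, 70.0)
    onset_age_sds: tuple[float, float] = (10.0, 7.0)
    onset_age_weights: tuple[float, float] = (0.3, 0.7)
    p_male: float = 0.565
    observation_start: str = "2014-04-01"
    observation_end: str = "2022-02-28"
    # 5-year event-free survival per onset group
    s5_steroid: dict = field(default_factory=lambda: {"EO": 0.576, "NEO": 0.686})
    s5_mtd: dict = field(default_factory=lambda: {"EO": 0.888, "NEO": 0.929})
    s5_surgery: dict = field(default_factory=lambda: {"EO": 0.975, "NEO": 0.985})
    # logistic death process
    p_death_base: float = 0.0072
    effect_or_death_eo: float = 6.18
    effect_or_death_steroid: float = 1.65
    refill_noise_days: int = 7
    # contamination / ancillary probabilities
    p_suspicious: float = 0.02
    p_crohns: float = 0.02
    p_academic: float = 0.005
    p_prevalent: float = 0.05
    p_topical: float = 0.15
    p_steroid_iv: float = 0.25
    p_mtd_discontinue: float = 0.35
    p_second_mtd: float = 0.30
    p_combo_aza: float = 0.40
    first_mtd_probs: dict = field(default_factory=lambda: dict(_DEFAULT_MTD_PROBS))

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name in ("p_male", "p_suspicious", "p_crohns", "p_academic",
                     "p_prevalent", "p_topical", "p_steroid_iv",
                     "p_mtd_discontinue", "p_second_mtd", "p_combo_aza",
                     "p_death_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]; got {v}")
        for d in (self.s5_steroid, self.s5_mtd, self.s5_surgery):
            for g in ("EO", "NEO"):
                rate_from_s5(d[g])  # raises if out of range
        if self.effect_or_death_eo <= 0 or self.effect_or_death_steroid <= 0:
            raise ValueError("death odds ratios must be positive")
        if not math.isclose(sum(self.onset_age_weights), 1.0, abs_tol=1e-9):
            raise ValueError("onset_age_weights must sum to 1")
        if self.refill_noise_days < 0 or self.refill_noise_days > 60:
            raise ValueError("refill_noise_days must be in [0, 60]")
        if abs(sum(self.first_mtd_probs.values()) - 1.0) > 1e-6:
            raise ValueError("first_mtd_probs must sum to 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_K51_CODES = ["K51.0", "K51.2", "K51.3", "K51.9"]
_DAY = pd.Timedelta(days=1)


def _jitter(rng: np.random.Generator, noise: int) -> int:
    return int(rng.integers(-noise, noise + 1)) if noise else 0


def _exp_event_date(
    rng: np.random.Generator,
    origin: pd.Timestamp,
    yearly_rate: float,
    limit: pd.Timestamp,
) -> pd.Timestamp | None:
    """Exponential event date from ``origin``, or None past ``limit``."""
    days = rng.exponential(1.0 / yearly_rate) * 365.25
    if days > 36525:  # beyond any claims window; avoids timedelta overflow
        return None
    date = origin + pd.Timedelta(days=round(days))
    return date if date <= limit else None


def _refill_train(
    rng: np.random.Generator,
    catalog: DrugCatalog,
    drug_id: str,
    start: pd.Timestamp,
    stop: pd.Timestamp,
    qty_draw,
    noise: int,
) -> list[tuple[str, pd.Timestamp, int]]:
    """Scheduled refills of one drug from ``start`` until past ``stop``.

    Jitter is bounded by ``noise`` (well inside the 91-day grace), so
    the train forms one continuous episode; discontinuation is simulated
    by choosing ``stop`` before the censor date.
    """
    spec = catalog.get(drug_id)
    out = []
    t = start
    while t <= stop:
        qty = int(qty_draw())
        out.append((drug_id, t, qty))
        step = refill_interval_days(spec, qty) + _jitter(rng, noise)
        t = t + pd.Timedelta(days=max(1, step))
    return out


def generate_claims(
    config: GeneratorConfig, catalog: DrugCatalog | None = None
) -> ClaimsBundle:
    """Generate a claims bundle under ``config``."""
    config.validate()
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)

    window_start = pd.Timestamp(config.observation_start)
    window_end = pd.Timestamp(config.observation_end)
    noise = config.refill_noise_days

    rate_steroid = {g: rate_from_s5(v) for g, v in config.s5_steroid.items()}
    rate_mtd = {g: rate_from_s5(v) for g, v in config.s5_mtd.items()}
    rate_surgery = {g: rate_from_s5(v) for g, v in config.s5_surgery.items()}
    logit_base = math.log(config.p_death_base / (1 - config.p_death_base))
    beta_eo = math.log(config.effect_or_death_eo)
    beta_st = math.log(config.effect_or_death_steroid)
    mtd_drugs = sorted(config.first_mtd_probs)
    mtd_p = np.array([config.first_mtd_probs[d] for d in mtd_drugs])
    mtd_p = mtd_p / mtd_p.sum()

    patients, diagnoses, prescriptions, events = [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        sex = "M" if rng.random() < config.p_male else "F"
        academic = int(rng.random() < config.p_academic)
        comp = int(rng.random() < config.onset_age_weights[1])
        age = float(
            np.clip(
                rng.normal(config.onset_age_means[comp], config.onset_age_sds[comp]),
                18.0,
                95.0,
            )
        )
        obs_start = window_start + pd.Timedelta(days=int(rng.integers(0, 366)))
        obs_end = window_end
        death_date = pd.NaT

        prevalent = rng.random() < config.p_prevalent
        if prevalent:
            # ongoing maintenance at entry: 90-day refills from day 0, so the
            # second refill is "old" and the patient drops as not new-onset
            index_date = obs_start
            birth = index_date - pd.Timedelta(days=round(age * 365.25))
            birth_ym = f"{birth.year:04d}-{birth.month:02d}"
            diagnoses.append((pid, str(rng.choice(_K51_CODES)),
                              int(rng.random() < config.p_suspicious), index_date))
            prescriptions.extend(
                (pid, d, t, q)
                for d, t, q in _refill_train(rng, catalog, "mesalazine", index_date,
                                             obs_end, lambda: 90, noise=min(noise, 7))
            )
            patients.append((pid, sex, birth_ym, obs_start, obs_end, academic, death_date))
            continue

        onset = obs_start + pd.Timedelta(days=182 + int(rng.integers(0, 181)))
        birth = onset - pd.Timedelta(days=round(age * 365.25))
        birth_ym = f"{birth.year:04d}-{birth.month:02d}"
        group = "EO" if age_completed_years(birth_ym, onset) >= 65 else "NEO"
        admin_end = obs_end

        # diagnoses: one at onset, possibly one later; per-row suspicion flag
        diagnoses.append((pid, str(rng.choice(_K51_CODES)),
                          int(rng.random() < config.p_suspicious), onset))
        if rng.random() < 0.5:
            later = onset + pd.Timedelta(days=int(rng.integers(30, 400)))
            if later <= admin_end:
                diagnoses.append((pid, str(rng.choice(_K51_CODES)),
                                  int(rng.random() < config.p_suspicious), later))
        if rng.random() < config.p_crohns:
            d = onset + pd.Timedelta(days=int(rng.integers(0, 200)))
            diagnoses.append((pid, "K50.1", 0, min(d, admin_end)))

        rx: list[tuple[str, pd.Timestamp, int]] = []
        # 5-ASA maintenance: 189-day supplies; refill gaps stay >=182 days
        t = onset
        while t <= admin_end:
            rx.append(("mesalazine", t, 189))
            t = t + pd.Timedelta(days=189 + abs(_jitter(rng, min(noise, 7))))

        if rng.random() < config.p_topical:
            rx.append(("budesonide_enema", onset, int(rng.integers(14, 57))))

        # single-course systemic steroid at an exponential group hazard
        t_steroid = _exp_event_date(rng, onset, rate_steroid[group], admin_end)
        steroid_use = t_steroid is not None
        if steroid_use:
            po_days = int(np.clip(round(rng.lognormal(math.log(60.0), 1.2)), 3, 270))
            rx.append(("prednisolone_po", t_steroid, po_days))
            if rng.random() < config.p_steroid_iv:
                iv_days = int(np.clip(round(rng.lognormal(math.log(10.0), 0.8)), 1, 60))
                rx.append(("prednisolone_iv", t_steroid, iv_days))

        # first (and possibly second) molecular targeting drug
        t_mtd = _exp_event_date(
            rng, onset, rate_mtd[group], admin_end - pd.Timedelta(days=30)
        )
        if t_mtd is not None:
            drug = str(rng.choice(mtd_drugs, p=mtd_p))
            discontinue = rng.random() < config.p_mtd_discontinue
            stop = (
                t_mtd + pd.Timedelta(days=round(rng.exponential(550.0)))
                if discontinue
                else admin_end
            )
            stop = min(stop, admin_end)
            rx.extend(_refill_train(rng, catalog, drug, t_mtd, stop,
                                    _qty_drawer(rng, catalog, drug), noise))
            if drug == "infliximab" and rng.random() < config.p_combo_aza:
                aza_stop = min(
                    t_mtd + pd.Timedelta(days=round(rng.exponential(900.0))), admin_end
                )
                rx.extend(_refill_train(rng, catalog, "azathioprine", t_mtd, aza_stop,
                                        lambda: 90, noise))
            if discontinue and rng.random() < config.p_second_mtd:
                t2 = stop + pd.Timedelta(days=150 + int(rng.integers(0, 120)))
                if t2 <= admin_end - pd.Timedelta(days=30):
                    others = [d for d in mtd_drugs if d != drug]
                    drug2 = str(rng.choice(others))
                    rx.extend(_refill_train(rng, catalog, drug2, t2, admin_end,
                                            _qty_drawer(rng, catalog, drug2), noise))

        # surgery at an exponential group hazard
        t_surg = _exp_event_date(rng, onset, rate_surgery[group], admin_end)
        if t_surg is not None:
            events.append((pid, "surgery", t_surg))

        # logistic death; the death date closes the observation window
        p_death = 1.0 / (
            1.0 + math.exp(-(logit_base + beta_eo * (group == "EO")
                             + beta_st * steroid_use))
        )
        if rng.random() < p_death:
            lower = max(onset, t_steroid if steroid_use else onset) + _DAY
            if lower >= admin_end:
                death_date = admin_end
            else:
                span = (admin_end - lower).days
                death_date = lower + pd.Timedelta(days=int(rng.integers(0, span + 1)))
            obs_end = death_date
            rx = [r for r in rx if r[1] <= death_date]
            events = [e for e in events if e[0] != pid or e[2] <= death_date]
            diagnoses = [d for d in diagnoses if d[0] != pid or d[3] <= death_date]

        prescriptions.extend((pid, d, t, q) for d, t, q in rx)
        patients.append((pid, sex, birth_ym, obs_start, obs_end, academic, death_date))

    bundle = ClaimsBundle(
        patients=pd.DataFrame(
            patients,
            columns=["patient_id", "sex", "birth_year_month", "obs_start",
                     "obs_end", "academic", "death_date"],
        ),
        diagnoses=pd.DataFrame(
            diagnoses, columns=["patient_id", "icd10", "suspicion", "date"]
        ),
        prescriptions=pd.DataFrame(
            prescriptions, columns=["patient_id", "drug_id", "date", "quantity"]
        ),
        events=pd.DataFrame(events, columns=["patient_id", "event_type", "date"]),
        provenance={"generator": "ucclaims.simulate", "seed": config.seed,
                    "config_hash": config.config_hash()},
    )
    return bundle


def _qty_drawer(rng: np.random.Generator, catalog: DrugCatalog, drug_id: str):
    spec = catalog.get(drug_id)
    if spec.rule == "fixed_weeks":
        return lambda: 1
    if spec.rule == "count_times_14":
        return lambda: int(rng.integers(1, 3))
    if drug_id == "ciclosporin_iv":
        return lambda: 14
    return lambda: 30  # oral small molecules: 30-day supplies


# ---------------------------------------------------------------------------
# hand-built edge-case fixtures

def _fixture_frame(patients, diagnoses, prescriptions, events, name):
    return ClaimsBundle(
        patients=pd.DataFrame(
            patients,
            columns=["patient_id", "sex", "birth_year_month", "obs_start",
                     "obs_end", "academic", "death_date"],
        ),
        diagnoses=pd.DataFrame(diagnoses, columns=["patient_id", "icd10", "suspicion", "date"]),
        prescriptions=pd.DataFrame(
            prescriptions, columns=["patient_id", "drug_id", "date", "quantity"]
        ),
        events=pd.DataFrame(events, columns=["patient_id", "event_type", "date"]),
        provenance={"generator": "ucclaims.simulate.make_fixture", "case": name},
    )


def _ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


_OBS = (_ts("2014-04-01"), _ts("2022-02-28"))
_ELDER = "1945-06"  # aged ~70 at window entry


def _fx_washout_boundary():
    # two 5-ASA prescriptions exactly 182 days apart: both new, patient retained
    d1 = _OBS[0] + pd.Timedelta(days=200)
    d2 = d1 + pd.Timedelta(days=182)
    return _fixture_frame(
        [("F01", "M", _ELDER, *_OBS, 0, pd.NaT)],
        [("F01", "K51.3", 0, d1)],
        [("F01", "mesalazine", d1, 182), ("F01", "mesalazine", d2, 182)],
        [],
        "washout_boundary",
    )


def _fx_crohns_overlap():
    d = _OBS[0] + pd.Timedelta(days=300)
    return _fixture_frame(
        [("F02", "F", _ELDER, *_OBS, 0, pd.NaT)],
        [("F02", "K51.9", 0, d), ("F02", "K50.1", 0, d + pd.Timedelta(days=10))],
        [("F02", "mesalazine", d, 60)],
        [],
        "crohns_overlap",
    )


def _fx_gap_13_weeks():
    # 30-day prednisolone; refill exactly 91 days past the scheduled date:
    # a single continuous episode (">13 weeks" is strict)
    d1 = _OBS[0] + pd.Timedelta(days=200)
    d2 = d1 + pd.Timedelta(days=30 + 91)
    return _fixture_frame(
        [("F03", "M", _ELDER, *_OBS, 0, pd.NaT)],
        [("F03", "K51.0", 0, d1)],
        [("F03", "prednisolone_po", d1, 30), ("F03", "prednisolone_po", d2, 30)],
        [],
        "gap_13_weeks",
    )


def _fx_suspicious_only():
    d = _OBS[0] + pd.Timedelta(days=250)
    return _fixture_frame(
        [("F04", "F", _ELDER, *_OBS, 0, pd.NaT)],
        [("F04", "K51.9", 1, d)],
        [("F04", "mesalazine", d, 60)],
        [],
        "suspicious_only",
    )


def _fx_prevalent_user():
    # refill 100 days after the first: the second prescription is old,
    # so the patient is not new-onset
    d1 = _OBS[0] + pd.Timedelta(days=10)
    return _fixture_frame(
        [("F05", "M", _ELDER, *_OBS, 0, pd.NaT)],
        [("F05", "K51.3", 0, d1)],
        [("F05", "mesalazine", d1, 90), ("F05", "mesalazine", d1 + pd.Timedelta(days=90), 90)],
        [],
        "prevalent_user",
    )


def _fx_death_before_rx():
    d = _OBS[0] + pd.Timedelta(days=400)
    death = d + pd.Timedelta(days=20)
    return _fixture_frame(
        [("F06", "F", _ELDER, _OBS[0], death, 0, death)],
        [("F06", "K51.9", 0, d)],
        [],
        [],
        "death_before_rx",
    )


FIXTURE_CASES = {
    "washout_boundary": _fx_washout_boundary,
    "crohns_overlap": _fx_crohns_overlap,
    "gap_13_weeks": _fx_gap_13_weeks,
    "suspicious_only": _fx_suspicious_only,
    "prevalent_user": _fx_prevalent_user,
    "death_before_rx": _fx_death_before_rx,
}


def make_fixture(case_name: str) -> ClaimsBundle:
    """Tiny hand-built bundles exercising extraction edge cases."""
    try:
        builder = FIXTURE_CASES[case_name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {case_name!r}; available: {sorted(FIXTURE_CASES)}"
        ) from None
    return builder()
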