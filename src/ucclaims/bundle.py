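"""The four-table claims bundle and its delimited-text round trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["ClaimsBundle", "PATIENT_COLUMNS", "DIAGNOSIS_COLUMNS",
           "PRESCRIPTION_COLUMNS", "EVENT_COLUMNS"]

PATIENT_COLUMNS = [
    "patient_id", "sex", "birth_year_month", "obs_start", "obs_end",
    "academic", "death_date",
]
DIAGNOSIS_COLUMNS = ["patient_id", "icd10", "suspicion", "date"]
PRESCRIPTION_COLUMNS = ["patient_id", "drug_id", "date", "quantity"]
EVENT_COLUMNS = ["patient_id", "event_type", "date"]

_DATE_COLS = {
    "patients": ["obs_start", "obs_end", "death_date"],
    "diagnoses": ["date"],
    "prescriptions": ["date"],
    "events": ["date"],
}


@dataclass
class ClaimsBundle:
    """Patients, diagnoses, prescriptions and events tables plus provenance.

    Dates are ``pandas`` timestamps in memory and ISO ``YYYY-MM-DD``
    strings on disk; birth dates carry year and month only (``YYYY-MM``),
    mirroring the granularity of insurer claims extracts.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    events: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cols in (
            ("patients", PATIENT_COLUMNS),
            ("diagnoses", DIAGNOSIS_COLUMNS),
            ("prescriptions", PRESCRIPTION_COLUMNS),
            ("events", EVENT_COLUMNS),
        ):
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table missing columns {missing}")

    @property
    def censor_dates(self) -> pd.Series:
        """Per-patient end of observation (death closes the window)."""
        return self.patients.set_index("patient_id")["obs_end"]

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        digests = {}
        for name in ("patients", "diagnoses", "prescriptions", "events"):
            df = getattr(self, name).copy()
            for col in _DATE_COLS[name]:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
            path = directory / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = dict(self.provenance)
        manifest["table_sha256"] = digests
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return directory

    @classmethod
    def read(cls, directory: str | Path) -> "ClaimsBundle":
        directory = Path(directory)
        tables = {}
        for name in ("patients", "diagnoses", "prescriptions", "events"):
            df = pd.read_csv(directory / f"{name}.tsv", sep="\t", dtype={"patient_id": str})
            for col in _DATE_COLS[name]:
                df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
            tables[name] = df
        manifest_path = directory / "manifest.json"
        provenance = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
        return cls(**tables, provenance=provenance)
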