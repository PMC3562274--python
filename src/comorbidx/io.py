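"""Reading and writing the two-table registry extract.

``patients.csv`` — one row per patient: patient_id, age_group, gender,
mechanism, injury_group, the four non-orthopaedic injury flags (0/1)
and ``gose`` (2-8, empty if lost to follow-up).

``diagnoses.csv`` — long table, one row per prefixed ICD-10-AM code:
patient_id, seq (1-40), prefix (P|A|C), icd10_code (dotted or dotless).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .synthetic import Cohort

__all__ = ["read_patients", "read_diagnoses", "write_cohort", "PATIENT_COLUMNS"]

PATIENT_COLUMNS = [
    "patient_id", "age_group", "gender", "mechanism", "injury_group",
    "head_injury", "rib_fractures", "organ_injury", "burns", "gose",
]


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": "int64"})
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"patients file missing columns: {sorted(missing)}")
    df["gose"] = pd.array(df["gose"], dtype="Int64")
    for f in ("head_injury", "rib_fractures", "organ_injury", "burns"):
        df[f] = df[f].astype(int)
    return df[PATIENT_COLUMNS]


def read_diagnoses(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": "int64", "prefix": str, "icd10_code": str})
    missing = {"patient_id", "prefix", "icd10_code"} - set(df.columns)
    if missing:
        raise ValueError(f"diagnoses file missing columns: {sorted(missing)}")
    return df


def write_cohort(cohort: Cohort, out_dir, seed: int | None = None, config_repr: str | None = None) -> dict:
    """Write patients.csv + diagnoses.csv (+ provenance.json) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(out / "patients.csv", index=False)
    cohort.diagnoses.to_csv(out / "diagnoses.csv", index=False)
    prov = {
        "n_patients": int(len(cohort.patients)),
        "n_diagnoses": int(len(cohort.diagnoses)),
    }
    if seed is not None:
        prov["seed"] = int(seed)
    if config_repr is not None:
        prov["config_sha1"] = hashlib.sha1(config_repr.encode()).hexdigest()
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    return prov
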