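"""File round-tripping for the pipeline's delimited-text artifacts.

Concentration data travel in long CSV format (patient_id, study_index,
dose_mg, time_min, conc_mg_L); covariates in a CSV keyed by patient_id.
An XLSX reader with the same column contract sits behind the same
interface.  All files are UTF-8, decimal-point, header row mandatory;
floats are serialized with 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pk_clearance import ClearanceStudy, PatientCovariates, SampleObservation
from .synthetic_cohort import PatientTruth

__all__ = [
    "read_concentrations",
    "read_covariates",
    "load_studies",
    "write_studies",
    "write_covariates",
    "write_truths",
    "write_gfr_table",
    "read_gfr_table",
    "write_json",
]

CONC_COLUMNS = ["patient_id", "study_index", "dose_mg", "time_min", "conc_mg_L"]
COV_COLUMNS = ["patient_id", "age_years", "sex", "race_black",
               "weight_kg", "height_cm", "scr_mg_dL"]

_FLOAT_FMT = "%.6g"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _require(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_concentrations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_table(path)
    _require(df, CONC_COLUMNS, path)
    bad = df[CONC_COLUMNS[2:]].isna().any(axis=1) | df[CONC_COLUMNS[:2]].isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 0-based indexing
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    return df


def read_covariates(path: str | Path) -> dict[str, PatientCovariates]:
    path = Path(path)
    df = _read_table(path)
    _require(df, COV_COLUMNS, path)
    out: dict[str, PatientCovariates] = {}
    for _, r in df.iterrows():
        out[str(r["patient_id"])] = PatientCovariates(
            age_years=float(r["age_years"]),
            sex=str(r["sex"]),
            race_black=bool(r["race_black"]),
            weight_kg=float(r["weight_kg"]),
            height_cm=float(r["height_cm"]),
            serum_creatinine_mg_dL=float(r["scr_mg_dL"]),
        )
    return out


def load_studies(
    conc_path: str | Path, cov_path: str | Path
) -> list[ClearanceStudy]:
    """Assemble ClearanceStudy objects from the two CSV (or XLSX) files."""
    conc = read_concentrations(conc_path)
    covs = read_covariates(cov_path)
    studies: list[ClearanceStudy] = []
    for (pid, sidx), grp in conc.groupby(["patient_id", "study_index"], sort=True):
        pid = str(pid)
        if pid not in covs:
            raise ValueError(f"no covariates for patient {pid}")
        doses = grp["dose_mg"].unique()
        if len(doses) != 1:
            raise ValueError(f"patient {pid} study {sidx}: inconsistent dose")
        grp = grp.sort_values("time_min")
        samples = tuple(
            SampleObservation(float(t), float(c))
            for t, c in zip(grp["time_min"], grp["conc_mg_L"])
        )
        studies.append(
            ClearanceStudy(
                patient_id=pid, study_index=int(sidx),
                dose_mg=float(doses[0]), samples=samples, covariates=covs[pid],
            )
        )
    return studies


def write_studies(studies: Iterable[ClearanceStudy], path: str | Path) -> None:
    rows = [
        (s.patient_id, s.study_index, s.dose_mg, o.time_min, o.conc_mg_L)
        for s in studies
        for o in s.samples
    ]
    df = pd.DataFrame(rows, columns=CONC_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_covariates(studies_or_truths: Iterable, path: str | Path) -> None:
    seen: dict[str, PatientCovariates] = {}
    for item in studies_or_truths:
        seen.setdefault(item.patient_id, item.covariates)
    rows = [
        (pid, c.age_years, c.sex, c.race_black, c.weight_kg, c.height_cm,
         c.serum_creatinine_mg_dL)
        for pid, c in sorted(seen.items())
    ]
    df = pd.DataFrame(rows, columns=COV_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_truths(truths: Iterable[PatientTruth], path: str | Path) -> None:
    rows = [
        (t.patient_id, t.true_gfr_mL_min_173, t.true_clearance_mL_min,
         t.v_central_L, t.v_peripheral_L, t.q_intercomp_mL_min)
        for t in truths
    ]
    df = pd.DataFrame(rows, columns=[
        "patient_id", "true_gfr_mL_min_173", "true_clearance_mL_min",
        "v_central_L", "v_peripheral_L", "q_intercomp_mL_min",
    ])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_gfr_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gfr_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("patient_id", "study_index"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
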