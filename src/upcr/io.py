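"""Cohort CSV dialect: one row per pregnancy, UTF-8, '.' decimal.

Header comment lines (prefixed ``#``) document units; replicate PI columns
are ``<vessel>_pi_1..3``.  Missing outcome fields are empty cells.  The
``exclusion_reason`` column uses the controlled vocabulary
{early_fgr, lost_followup, missing_data, malformation, none}.
"""

from __future__ import annotations

import math
from typing import List

import numpy as np
import pandas as pd

from .errors import ValidationError
from .records import Cohort, DopplerExam, PregnancyRecord, EXCLUSION_VOCAB

_BOOL_COLS = [
    "nulliparous", "previous_fgr", "previous_stillbirth", "gestational_diabetes",
    "liver_disease", "hypertensive_disease", "preeclampsia", "crossed_quartiles",
    "lost_followup", "malformation",
]
_OUTCOME_BOOL_COLS = ["stillbirth", "emergency_cs_fetal_distress", "nicu_admission"]
_REPLICATE_COLS = [
    f"{vessel}_pi_{i}" for vessel in ("ua", "mca", "uta_left", "uta_right") for i in (1, 2, 3)
]

COLUMNS = (
    ["record_id", "maternal_age", "bmi"]
    + _BOOL_COLS[:7]
    + ["ga_detection", "ga_delivery", "bpd_cm", "hc_cm", "ac_cm", "fl_cm",
       "birthweight", "birthweight_percentile", "efw_percentile", "ac_percentile",
       "crossed_quartiles", "ga_exam"]
    + _REPLICATE_COLS
    + _OUTCOME_BOOL_COLS
    + ["apgar5", "ua_ph", "lost_followup", "malformation", "exclusion_reason"]
)

_HEADER_COMMENT = """\
# Synthetic late-onset FGR cohort, one row per recruited pregnancy.
# Units: maternal_age years; bmi kg/m2; ga_* decimal weeks; biometry *_cm cm;
# birthweight g; percentiles %; pulsatility indices dimensionless (3 replicates
# per vessel); ua_ph pH units. Empty cells mark unknown/missing values.
# exclusion_reason in {early_fgr, lost_followup, missing_data, malformation, none}.
"""


def _opt(value):
    return np.nan if value is None else value


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for rec in cohort.records:
        row = {
            "record_id": rec.record_id,
            "maternal_age": rec.maternal_age,
            "bmi": rec.bmi,
            "ga_detection": rec.ga_detection,
            "ga_delivery": _opt(rec.ga_delivery),
            "bpd_cm": rec.bpd_cm, "hc_cm": rec.hc_cm, "ac_cm": rec.ac_cm, "fl_cm": rec.fl_cm,
            "birthweight": _opt(rec.birthweight),
            "birthweight_percentile": _opt(rec.birthweight_percentile),
            "efw_percentile": rec.efw_percentile,
            "ac_percentile": rec.ac_percentile,
            "apgar5": _opt(rec.apgar5),
            "ua_ph": _opt(rec.ua_ph),
            "exclusion_reason": rec.exclusion_reason,
            "ga_exam": rec.exam.ga_weeks if rec.exam is not None else np.nan,
        }
        for col in _BOOL_COLS:
            row[col] = getattr(rec, col)
        for col in _OUTCOME_BOOL_COLS:
            row[col] = _opt(getattr(rec, col))
        for vessel, attr in (("ua", "ua_pi"), ("mca", "mca_pi"),
                             ("uta_left", "uta_left_pi"), ("uta_right", "uta_right_pi")):
            reps = getattr(rec.exam, attr) if rec.exam is not None else (np.nan,) * 3
            for i, v in enumerate(reps, start=1):
                row[f"{vessel}_pi_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def write_cohort_csv(cohort: Cohort, path) -> None:
    frame = cohort_to_frame(cohort)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_HEADER_COMMENT)
        frame.to_csv(fh, index=False)


def _cell(row, col, cast=float):
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return cast(v)


def _parse_bool(v) -> bool:
    # Columns with missing cells come back from pandas as object dtype, so
    # booleans may arrive as the strings "True"/"False".
    if isinstance(v, str):
        if v.lower() in ("true", "1"):
            return True
        if v.lower() in ("false", "0"):
            return False
        raise ValidationError(f"cannot parse boolean cell {v!r}")
    return bool(v)


def frame_to_cohort(frame: pd.DataFrame) -> Cohort:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    bad = set(frame["exclusion_reason"].astype(str)) - set(EXCLUSION_VOCAB)
    if bad:
        raise ValidationError(f"unknown exclusion_reason values: {sorted(bad)}")

    records: List[PregnancyRecord] = []
    for _, row in frame.iterrows():
        ga_exam = _cell(row, "ga_exam")
        exam = None
        if ga_exam is not None:
            exam = DopplerExam(
                ga_weeks=ga_exam,
                ua_pi=tuple(float(row[f"ua_pi_{i}"]) for i in (1, 2, 3)),
                mca_pi=tuple(float(row[f"mca_pi_{i}"]) for i in (1, 2, 3)),
                uta_left_pi=tuple(float(row[f"uta_left_pi_{i}"]) for i in (1, 2, 3)),
                uta_right_pi=tuple(float(row[f"uta_right_pi_{i}"]) for i in (1, 2, 3)),
            )
        reason = str(row["exclusion_reason"])
        records.append(PregnancyRecord(
            record_id=str(row["record_id"]),
            maternal_age=float(row["maternal_age"]),
            bmi=float(row["bmi"]),
            nulliparous=bool(row["nulliparous"]),
            previous_fgr=bool(row["previous_fgr"]),
            previous_stillbirth=bool(row["previous_stillbirth"]),
            gestational_diabetes=bool(row["gestational_diabetes"]),
            liver_disease=bool(row["liver_disease"]),
            hypertensive_disease=bool(row["hypertensive_disease"]),
            preeclampsia=bool(row["preeclampsia"]),
            ga_detection=float(row["ga_detection"]),
            ga_delivery=_cell(row, "ga_delivery"),
            bpd_cm=float(row["bpd_cm"]), hc_cm=float(row["hc_cm"]),
            ac_cm=float(row["ac_cm"]), fl_cm=float(row["fl_cm"]),
            birthweight=_cell(row, "birthweight"),
            birthweight_percentile=_cell(row, "birthweight_percentile"),
            efw_percentile=float(row["efw_percentile"]),
            ac_percentile=float(row["ac_percentile"]),
            crossed_quartiles=bool(row["crossed_quartiles"]),
            exam=exam,
            stillbirth=_cell(row, "stillbirth", _parse_bool),
            emergency_cs_fetal_distress=_cell(row, "emergency_cs_fetal_distress", _parse_bool),
            nicu_admission=_cell(row, "nicu_admission", _parse_bool),
            apgar5=_cell(row, "apgar5", lambda v: int(float(v))),
            ua_ph=_cell(row, "ua_ph"),
            lost_followup=bool(row["lost_followup"]),
            malformation=bool(row["malformation"]),
            eligibility="analyzed" if reason == "none" else f"excluded:{reason}",
        ))
    return Cohort(records=records)


def read_cohort_csv(path) -> Cohort:
    frame = pd.read_csv(path, comment="#")
    return frame_to_cohort(frame)
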