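"""NONMEM-style rectangular dataset reader/writer.

One row per event: EVID=1 dose rows carry AMT and RATE (duration =
AMT/RATE), EVID=0 observation rows carry DV (``.`` when missing) with MDV=0.
Covariates repeat on every row of a patient.  SEX is coded 1=male/0=female,
RRT and BLQ as 0/1, SEPSIS 0=sepsis/1=severe sepsis or septic shock.
Numeric values are written with 10 significant digits, which makes
write -> read -> write byte-stable.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd

from .covariates import FEMALE, MALE, SEPSIS, SEVERE_SEPSIS, CovariateSet
from .errors import DesignError
from .events import DoseEvent, ObservationEvent, PatientCourse

COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "BLQ", "LABEL",
    "AGE", "SEX", "WT", "IBW", "HT", "SCR", "ALB", "APACHE", "CRP",
    "RRT", "SEPSIS", "CRCL", "EGFR", "MDRD",
]

MISSING = "."


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, (int,)) and not isinstance(value, bool):
        return str(value)
    return f"{value:.10g}"


def _cov_fields(cov: CovariateSet) -> dict:
    sepsis = None
    if cov.sepsis_level is not None:
        sepsis = 1 if cov.sepsis_level == SEVERE_SEPSIS else 0
    return {
        "AGE": cov.age,
        "SEX": None if cov.sex is None else int(cov.sex == MALE),
        "WT": cov.weight_total,
        "IBW": cov.weight_ideal,
        "HT": cov.height,
        "SCR": cov.serum_creatinine,
        "ALB": cov.albumin,
        "APACHE": cov.apache_ii,
        "CRP": cov.crp,
        "RRT": int(bool(cov.rrt)),
        "SEPSIS": sepsis,
        "CRCL": cov.crcl_cg,
        "EGFR": cov.egfr_ckdepi,
        "MDRD": cov.clcr_mdrd,
    }


def courses_to_rows(courses: Sequence[PatientCourse]) -> List[dict]:
    rows = []
    for course in courses:
        covs = _cov_fields(course.covariates)
        events = [("dose", d.time_start, d) for d in course.doses]
        events += [("obs", o.time, o) for o in course.observations]
        events.sort(key=lambda e: (e[1], e[0] == "obs"))
        for kind, t, ev in events:
            row = {"ID": course.patient_id, "TIME": t}
            if kind == "dose":
                row.update(AMT=ev.amount, RATE=ev.rate, DV=None, EVID=1, MDV=1,
                           BLQ=0, LABEL=MISSING)
            else:
                row.update(AMT=None, RATE=None, DV=ev.concentration, EVID=0,
                           MDV=0, BLQ=int(ev.below_lloq), LABEL=ev.label)
            row.update(covs)
            rows.append(row)
    return rows


def write_nonmem_csv(courses: Sequence[PatientCourse], path: Union[str, Path]) -> None:
    """Write patient courses as a NONMEM-style CSV."""
    rows = courses_to_rows(courses)
    lines = [",".join(COLUMNS)]
    for row in rows:
        fields = []
        for col in COLUMNS:
            v = row.get(col)
            fields.append(v if col == "LABEL" and isinstance(v, str) else
                          (v if col == "ID" else _fmt(v)))
        fields[0] = str(row["ID"])
        lines.append(",".join(str(f) for f in fields))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse(value: str):
    if value == MISSING or value == "":
        return None
    return float(value)


def read_nonmem_csv(path: Union[str, Path]) -> List[PatientCourse]:
    """Read a NONMEM-style CSV back into patient courses."""
    df = pd.read_csv(path, dtype=str).fillna(MISSING)
    missing = [c for c in ("ID", "TIME", "EVID") if c not in df.columns]
    if missing:
        raise DesignError(f"dataset lacks required columns: {missing}")
    courses = []
    for pid, group in df.groupby("ID", sort=False):
        first = group.iloc[0]

        def g(col):
            return _parse(first[col]) if col in group.columns else None

        sex = g("SEX")
        sepsis = g("SEPSIS")
        cov = CovariateSet(
            age=g("AGE"),
            sex=None if sex is None else (MALE if int(sex) == 1 else FEMALE),
            weight_total=g("WT"), weight_ideal=g("IBW"), height=g("HT"),
            serum_creatinine=g("SCR"), albumin=g("ALB"), apache_ii=g("APACHE"),
            crp=g("CRP"), rrt=bool(g("RRT") or 0),
            sepsis_level=None if sepsis is None else (
                SEVERE_SEPSIS if int(sepsis) == 1 else SEPSIS),
            crcl_cg=g("CRCL"), egfr_ckdepi=g("EGFR"), clcr_mdrd=g("MDRD"),
        )
        doses, observations = [], []
        for _, row in group.iterrows():
            t = float(row["TIME"])
            if int(float(row["EVID"])) == 1:
                amt = _parse(row["AMT"])
                rate = _parse(row["RATE"])
                if amt is None or rate is None or rate <= 0:
                    raise DesignError(f"dose row without AMT/RATE at ID={pid} TIME={t}")
                doses.append(DoseEvent(t, amt, amt / rate))
            else:
                dv = _parse(row["DV"]) if "DV" in group.columns else None
                if dv is None:
                    continue
                blq = bool(int(float(row["BLQ"]))) if "BLQ" in group.columns and \
                    row["BLQ"] != MISSING else False
                label = row["LABEL"] if "LABEL" in group.columns and \
                    row["LABEL"] != MISSING else "other"
                observations.append(ObservationEvent(t, dv, below_lloq=blq, label=label))
        courses.append(PatientCourse(str(pid), cov, doses, observations))
    return courses
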