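"""Delimited-file round trip for cohorts.

Schema (the reader contract for every downstream module):

* ``people.csv`` — one row per person: id, gender, ethnicity, birth_date,
  diabetes_type, diagnosis_date, imd_quintile (blank if missing), smoking.
* ``appointments.csv`` — person_id, ISO-8601 date, r_grade, m_grade,
  attended; grades blank for non-attended visits.
* ``measurements.csv`` (optional) — person_id, date, kind in
  {hba1c, sbp, dbp}, value.
"""
from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from .types import Appointment, Person, ScreeningHistory

_KINDS = ("hba1c", "sbp", "dbp")


def write_cohort(cohort: list[ScreeningHistory], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    people, appts, meas = [], [], []
    for hist in cohort:
        p = hist.person
        people.append(
            {
                "id": p.id,
                "gender": p.gender,
                "ethnicity": p.ethnicity,
                "birth_date": p.birth_date.isoformat(),
                "diabetes_type": p.diabetes_type,
                "diagnosis_date": p.diagnosis_date.isoformat(),
                "imd_quintile": "" if p.imd_quintile is None else p.imd_quintile,
                "smoking": p.smoking,
            }
        )
        for a in hist.appointments:
            appts.append(
                {
                    "person_id": p.id,
                    "date": a.date.isoformat(),
                    "r_grade": a.r_grade or "",
                    "m_grade": a.m_grade or "",
                    "attended": int(a.attended),
                }
            )
        for kind, series in zip(_KINDS, (hist.hba1c_series, hist.sbp_series, hist.dbp_series)):
            for d, v in series:
                meas.append({"person_id": p.id, "date": d.isoformat(), "kind": kind, "value": v})
    pd.DataFrame(people).to_csv(out / "people.csv", index=False)
    pd.DataFrame(appts).to_csv(out / "appointments.csv", index=False)
    if meas:
        pd.DataFrame(meas).to_csv(out / "measurements.csv", index=False)


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def read_cohort(in_dir: str | Path) -> list[ScreeningHistory]:
    src = Path(in_dir)
    people = pd.read_csv(src / "people.csv", dtype={"imd_quintile": "Int64"})
    appts = pd.read_csv(src / "appointments.csv", keep_default_na=False)
    meas_path = src / "measurements.csv"
    meas = pd.read_csv(meas_path) if meas_path.exists() else pd.DataFrame(
        columns=["person_id", "date", "kind", "value"]
    )

    appts_by_person = {pid: g for pid, g in appts.groupby("person_id")}
    meas_by_person = {pid: g for pid, g in meas.groupby("person_id")}

    cohort = []
    for row in people.itertuples(index=False):
        pid = int(row.id)
        person = Person(
            id=pid,
            gender=row.gender,
            ethnicity=None if pd.isna(row.ethnicity) else row.ethnicity,
            birth_date=_parse_date(row.birth_date),
            diabetes_type=row.diabetes_type,
            diagnosis_date=_parse_date(row.diagnosis_date),
            imd_quintile=None if pd.isna(row.imd_quintile) else int(row.imd_quintile),
            smoking=row.smoking,
        )
        appointments = []
        for a in appts_by_person.get(pid, pd.DataFrame()).itertuples(index=False):
            attended = bool(int(a.attended))
            appointments.append(
                Appointment(
                    date=_parse_date(a.date),
                    r_grade=(a.r_grade or None) if attended else None,
                    m_grade=(a.m_grade or None) if attended else None,
                    attended=attended,
                )
            )
        series: dict[str, list[tuple[dt.date, float]]] = {k: [] for k in _KINDS}
        pm = meas_by_person.get(pid)
        if pm is not None:
            for m in pm.sort_values("date").itertuples(index=False):
                series[m.kind].append((_parse_date(m.date), float(m.value)))
        cohort.append(
            ScreeningHistory(
                person=person,
                appointments=appointments,
                hba1c_series=series["hba1c"],
                sbp_series=series["sbp"],
                dbp_series=series["dbp"],
            )
        )
    return cohort
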