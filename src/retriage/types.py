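"""Core domain types for diabetic eye screening histories.

Grades follow the English national screening grading scheme: retinopathy
R0 (none) / R1 (background) / R2 (pre-proliferative) / R3 (proliferative),
maculopathy M0/M1, and U for an ungradable encounter.  Sight-threatening
diabetic retinopathy (STDR) is R2, R3 or M1 in either eye.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

ETHNICITIES = ("white", "black", "south_asian", "other_asian", "mixed", "other")
GENDERS = ("male", "female")
DIABETES_TYPES = ("type1", "type2_or_other")
SMOKING = ("current", "ex", "never", "nonsmoker_unknown_history", "vaping", "unknown")
R_GRADES = ("R0", "R1", "R2", "R3", "U")
M_GRADES = ("M0", "M1")

STDR_R_GRADES = frozenset({"R2", "R3"})


@dataclass(frozen=True)
class Person:
    """Demographics fixed at registration."""

    id: int
    gender: str
    ethnicity: str
    birth_date: dt.date
    diabetes_type: str
    diagnosis_date: dt.date
    imd_quintile: Optional[int] = None
    smoking: str = "unknown"

    def __post_init__(self) -> None:
        if self.ethnicity is not None and self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.diabetes_type not in DIABETES_TYPES:
            raise ValueError(f"unknown diabetes type {self.diabetes_type!r}")
        if self.diagnosis_date < self.birth_date:
            raise ValueError("diagnosis_date precedes birth_date")
        if self.imd_quintile is not None and not 1 <= self.imd_quintile <= 5:
            raise ValueError("imd_quintile must be 1-5 or None")

    def age_years(self, at_date: dt.date) -> float:
        return (at_date - self.birth_date).days / 365.25

    def duration_years(self, at_date: dt.date) -> float:
        return (at_date - self.diagnosis_date).days / 365.25


@dataclass(frozen=True)
class Appointment:
    """One scheduled screening visit.

    Non-attended visits carry no grade (``r_grade is None``); ungradable
    encounters grade U and carry no maculopathy grade.
    """

    date: dt.date
    r_grade: Optional[str] = None
    m_grade: Optional[str] = None
    attended: bool = True

    def __post_init__(self) -> None:
        if not self.attended:
            if self.r_grade is not None or self.m_grade is not None:
                raise ValueError("non-attended visit cannot carry a grade")
            return
        if self.r_grade not in R_GRADES:
            raise ValueError(f"unknown R grade {self.r_grade!r}")
        if self.r_grade == "U":
            if self.m_grade is not None:
                raise ValueError("ungradable encounter cannot carry an M grade")
        elif self.m_grade not in M_GRADES:
            raise ValueError(f"unknown M grade {self.m_grade!r}")

    @property
    def gradable(self) -> bool:
        return self.attended and self.r_grade != "U"

    @property
    def is_stdr(self) -> bool:
        """R2, R3 or M1 in either eye."""
        return self.gradable and (self.r_grade in STDR_R_GRADES or self.m_grade == "M1")

    @property
    def is_r0m0(self) -> bool:
        return self.gradable and self.r_grade == "R0" and self.m_grade == "M0"

    @property
    def any_dr(self) -> bool:
        """Any degree of diabetic retinopathy or maculopathy (R1+, M1)."""
        return self.gradable and (self.r_grade != "R0" or self.m_grade != "M0")


@dataclass
class ScreeningHistory:
    """One person's date-ordered appointments plus linked measurement series.

    Measurement series are (date, value) lists; HbA1c in mmol/mol, blood
    pressures in mmHg.  Series may be empty when no linked record exists.
    """

    person: Person
    appointments: list[Appointment]
    hba1c_series: list[tuple[dt.date, float]] = field(default_factory=list)
    sbp_series: list[tuple[dt.date, float]] = field(default_factory=list)
    dbp_series: list[tuple[dt.date, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dates = [a.date for a in self.appointments]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("appointment dates must be strictly increasing")
        for series in (self.hba1c_series, self.sbp_series, self.dbp_series):
            ds = [d for d, _ in series]
            if any(b < a for a, b in zip(ds, ds[1:])):
                raise ValueError("measurement dates must be non-decreasing")

    def attended_gradable(self) -> list[Appointment]:
        return [a for a in self.appointments if a.gradable]
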