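"""Synthetic screening-cohort generator.

Emulates the data structure of a large urban English diabetic eye screening
programme: roughly annual appointments with jitter and non-attendance,
grade progression R0 -> R1 -> {R2, R3, M1}, a covariate-dependent
sight-threatening retinopathy (STDR) hazard, ungradable encounters, and
linked HbA1c / blood-pressure series with occasional missingness.

The event process is a discrete-time logistic hazard per inter-appointment
interval: at each gradable visit after the second, the probability of an
STDR outcome is ``expit(base_logit + fixed effects + b_i)`` with a person
random intercept ``b_i ~ N(0, re_sd^2)``.  Fixed effects are a diabetes
duration >= 10 years indicator, an age <= 40 indicator, and ethnic-group
increments (white = 0 reference), each evaluated at the start of the
interval.  The first two gradable visits always grade R0M0, so nearly every
person with three or more gradable visits qualifies for the low-risk
biennial pathway.
"""
from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .types import ETHNICITIES, SMOKING, Appointment, Person, ScreeningHistory

_ETH_PROBS = {
    "white": 0.33,
    "black": 0.20,
    "south_asian": 0.25,
    "other_asian": 0.08,
    "mixed": 0.06,
    "other": 0.08,
}

_STDR_GRADES = [("R2", "M0"), ("R3", "M0"), ("R1", "M1")]
_STDR_GRADE_PROBS = [0.45, 0.10, 0.45]


class SimConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Hazard effects are log-odds increments on the per-interval STDR
    probability; the defaults give a marginal per-interval event rate of
    roughly 1%, of the order seen in low-risk screening populations.
    """

    n_people: int = Field(gt=0)
    seed: int = 0
    start_window: tuple[dt.date, dt.date] = (dt.date(2012, 1, 3), dt.date(2015, 1, 1))
    n_scheduled: int = Field(default=9, gt=0)
    mean_gap_days: float = 365.0
    gap_jitter_sd: float = 30.0
    p_dna: float = 0.12
    p_ungradable: float = 0.02
    base_logit: float = -4.70
    effect_duration_ge10: float = 0.69
    effects_ethnicity: dict[str, float] = Field(
        default_factory=lambda: {
            "white": 0.0,
            "black": 0.85,
            "south_asian": 0.65,
            "other_asian": 0.40,
            "mixed": 0.75,
            "other": 0.50,
        }
    )
    effect_age_le40: float = 0.90
    re_sd: float = Field(default=0.5, ge=0.0)
    p_r1_transient: float = 0.05
    frac_age_le40: float = 0.15
    hba1c_median_loc: float = 51.0
    hba1c_median_scale: float = 10.0
    dbp_loc: float = 76.0
    dbp_scale: float = 10.0
    sbp_loc: float = 130.0
    sbp_scale: float = 15.0
    p_missing_measure: float = 0.10
    truncate_after_stdr: bool = True

    @field_validator("p_dna", "p_ungradable", "p_r1_transient", "p_missing_measure", "frac_age_le40")
    @classmethod
    def _check_prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_ethnicity(self) -> "SimConfig":
        if set(self.effects_ethnicity) != set(ETHNICITIES):
            raise ValueError("effects_ethnicity must cover the six ethnic groups")
        if self.effects_ethnicity["white"] != 0.0:
            raise ValueError("white is the reference group; its effect must be 0")
        if self.start_window[1] < self.start_window[0]:
            raise ValueError("start_window end precedes start")
        return self


def _draw_person(i: int, rng: np.random.Generator, cfg: SimConfig, first_date: dt.date) -> Person:
    young = rng.random() < cfg.frac_age_le40
    if young:
        age = rng.uniform(20.0, 40.0)
    else:
        age = min(max(rng.normal(62.0, 12.0), 41.0), 95.0)
    birth = first_date - dt.timedelta(days=round(age * 365.25))
    # duration mix populates both <10y and >=10y strata
    duration = min(rng.exponential(7.0), max(age - 1.0, 1.0))
    diagnosis = first_date - dt.timedelta(days=round(duration * 365.25))
    t1 = rng.random() < (0.30 if young else 0.06)
    imd = None if rng.random() < 0.03 else int(rng.integers(1, 6))
    return Person(
        id=i,
        gender="female" if rng.random() < 0.48 else "male",
        ethnicity=str(rng.choice(list(_ETH_PROBS), p=list(_ETH_PROBS.values()))),
        birth_date=birth,
        diabetes_type="type1" if t1 else "type2_or_other",
        diagnosis_date=diagnosis,
        imd_quintile=imd,
        smoking=str(rng.choice(SMOKING)),
    )


def hazard_logit(cfg: SimConfig, person: Person, at_date: dt.date) -> float:
    """Fixed-effect linear predictor of the per-interval STDR hazard."""
    eta = cfg.base_logit
    if person.duration_years(at_date) >= 10.0:
        eta += cfg.effect_duration_ge10
    if person.age_years(at_date) <= 40.0:
        eta += cfg.effect_age_le40
    eta += cfg.effects_ethnicity[person.ethnicity]
    return eta


def _measurement_series(
    rng: np.random.Generator,
    cfg: SimConfig,
    first: dt.date,
    last: dt.date,
    loc: float,
    scale: float,
    floor: float,
) -> list[tuple[dt.date, float]]:
    if rng.random() < cfg.p_missing_measure:
        return []
    centre = rng.normal(loc, scale)
    series = []
    t = first - dt.timedelta(days=int(rng.integers(200, 420)))
    while t < last:
        value = max(centre + rng.normal(0.0, scale / 4.0), floor)
        series.append((t, round(float(value), 1)))
        t = t + dt.timedelta(days=int(rng.integers(300, 430)))
    return series


def _one_history(i: int, rng: np.random.Generator, cfg: SimConfig) -> ScreeningHistory:
    window_days = (cfg.start_window[1] - cfg.start_window[0]).days
    first_date = cfg.start_window[0] + dt.timedelta(days=int(rng.integers(0, window_days + 1)))
    person = _draw_person(i, rng, cfg, first_date)
    b_i = rng.normal(0.0, cfg.re_sd) if cfg.re_sd > 0 else 0.0

    appointments: list[Appointment] = []
    date = first_date
    n_gradable = 0
    prev_gradable_date: dt.date | None = None
    had_stdr = False
    stdr_grade: tuple[str, str] | None = None
    for k in range(cfg.n_scheduled):
        if k > 0:
            gap = max(rng.normal(cfg.mean_gap_days, cfg.gap_jitter_sd), 30.0)
            date = date + dt.timedelta(days=round(gap))
        if rng.random() < cfg.p_dna:
            appointments.append(Appointment(date=date, attended=False))
            continue
        if rng.random() < cfg.p_ungradable:
            appointments.append(Appointment(date=date, r_grade="U"))
            continue
        if had_stdr:
            # post-diagnosis grades stay at STDR level when not truncating
            r, m = stdr_grade  # type: ignore[misc]
            appointments.append(Appointment(date=date, r_grade=r, m_grade=m))
            continue
        if n_gradable < 2:
            r, m = "R0", "M0"
        else:
            eta = hazard_logit(cfg, person, prev_gradable_date) + b_i
            if rng.random() < 1.0 / (1.0 + math.exp(-eta)):
                idx = rng.choice(len(_STDR_GRADES), p=_STDR_GRADE_PROBS)
                r, m = _STDR_GRADES[idx]
                had_stdr = True
                stdr_grade = (r, m)
            elif rng.random() < cfg.p_r1_transient:
                r, m = "R1", "M0"
            else:
                r, m = "R0", "M0"
        appointments.append(Appointment(date=date, r_grade=r, m_grade=m))
        n_gradable += 1
        prev_gradable_date = date
        if had_stdr and cfg.truncate_after_stdr:
            break

    last_date = appointments[-1].date
    hist = ScreeningHistory(
        person=person,
        appointments=appointments,
        hba1c_series=_measurement_series(
            rng, cfg, first_date, last_date, cfg.hba1c_median_loc, cfg.hba1c_median_scale, 20.0
        ),
        sbp_series=_measurement_series(
            rng, cfg, first_date, last_date, cfg.sbp_loc, cfg.sbp_scale, 70.0
        ),
        dbp_series=_measurement_series(
            rng, cfg, first_date, last_date, cfg.dbp_loc, cfg.dbp_scale, 40.0
        ),
    )
    hist.random_intercept = b_i  # type: ignore[attr-defined]  # ground truth for oracle tests
    return hist


def generate_cohort(config: SimConfig) -> list[ScreeningHistory]:
    """Generate a reproducible synthetic cohort.

    The same config (including seed) always yields an identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    return [_one_history(i, rng, config) for i in range(config.n_people)]


def true_event_table(cohort: list[ScreeningHistory]) -> pd.DataFrame:
    """Ground-truth first-STDR table, one row per person.

    Includes the person's drawn random intercept so that oracle tests can
    condition on it.
    """
    rows = []
    for hist in cohort:
        first_stdr = next((a.date for a in hist.appointments if a.is_stdr), None)
        first_vis = hist.appointments[0].date
        rows.append(
            {
                "person_id": hist.person.id,
                "first_stdr_date": first_stdr,
                "ethnicity": hist.person.ethnicity,
                "age_entry": hist.person.age_years(first_vis),
                "duration_entry": hist.person.duration_years(first_vis),
                "diabetes_type": hist.person.diabetes_type,
                "random_intercept": getattr(hist, "random_intercept", 0.0),
            }
        )
    return pd.DataFrame(rows)


def hazard_intervals(cohort: list[ScreeningHistory]) -> pd.DataFrame:
    """Reconstruct the at-risk intervals exactly as the generator drew them.

    One row per gradable visit after a person's second, with the hazard
    covariates evaluated at the interval start (the previous gradable visit)
    and the binary STDR outcome at the interval end.  This is the
    ground-truth design table for parameter-recovery tests.
    """
    rows = []
    for hist in cohort:
        gradable = hist.attended_gradable()
        for prev, cur in zip(gradable[1:], gradable[2:]):
            p = hist.person
            rows.append(
                {
                    "person_id": p.id,
                    "start_date": prev.date,
                    "date": cur.date,
                    "duration_ge10": float(p.duration_years(prev.date) >= 10.0),
                    "age_le40": float(p.age_years(prev.date) <= 40.0),
                    "ethnicity": p.ethnicity,
                    "event": float(cur.is_stdr),
                }
            )
            if cur.is_stdr:
                break
    df = pd.DataFrame(rows)
    for eth in ETHNICITIES[1:]:
        df[f"eth_{eth}"] = (df["ethnicity"] == eth).astype(float)
    return df
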