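"""Integer points protocol derived from a fitted risk model.

The ethnicity-aware regression (covariate set 2) is simplified into a
clinic-usable score: the per-year age coefficient, the per-year diabetes
duration coefficient and the ethnic-group contrasts are divided by a
common scale and rounded half-away-from-zero to the nearest integer.
A person's score is the sum of the age component (per whole year of age),
the duration component (per whole year since diagnosis) and their ethnic
group's points; a score at or above the integer threshold triggers annual
rather than biennial recall.

Raw per-year log-odds are far below 1, so the scale is essential: by
default it is the smallest nonzero included coefficient magnitude, which
maps that coefficient to +/-1 point.  Age and duration components may also
be expressed as step schedules (points per N whole years) to keep the
integers small.
"""
from __future__ import annotations

import datetime as dt
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

from .eligibility import EligibleHistory
from .types import ETHNICITIES, Person

ROUNDING_RULE = "half-away-from-zero"


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass
class PointsTable:
    """Integer points per characteristic plus the annual-recall threshold.

    ``age_points`` accrue once per ``age_step_years`` whole years of age,
    and likewise for duration; white ethnicity is the zero reference.
    The threshold may be negative: when STDR risk falls with age the
    derived per-year age points are negative, dragging scores (and the
    calibrated cut) below zero.  The published reference configuration
    uses a threshold of 4.
    """

    age_points: int
    duration_points: int
    ethnicity_points: dict[str, int]
    scale: float
    threshold: int = 4
    age_step_years: int = 1
    duration_step_years: int = 1
    rounding: str = ROUNDING_RULE

    def __post_init__(self) -> None:
        if set(self.ethnicity_points) != set(ETHNICITIES):
            raise ValueError("ethnicity_points must cover the six ethnic groups")
        if self.ethnicity_points["white"] != 0:
            raise ValueError("white is the reference group; its points must be 0")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def score(self, person: Person, at_date: dt.date) -> int:
        return score_person(self, person, at_date)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "age_points": self.age_points,
                    "duration_points": self.duration_points,
                    "ethnicity_points": self.ethnicity_points,
                    "scale": self.scale,
                    "threshold": self.threshold,
                    "age_step_years": self.age_step_years,
                    "duration_step_years": self.duration_step_years,
                    "rounding": self.rounding,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PointsTable":
        return cls(**json.loads(Path(path).read_text()))


def derive_points_table(
    fit,
    scale: Optional[float] = None,
    threshold: int = 4,
) -> PointsTable:
    """Divide-and-round the age, duration and ethnicity coefficients.

    ``fit`` must carry linear ``age`` and ``duration`` terms and the five
    non-white ethnicity contrasts (a covariate-set-2 style fit); attendance
    and diabetes-type terms are dropped from the score.  The default scale
    maps the smallest-magnitude nonzero included coefficient to +/-1 point.
    """
    params = fit.params
    needed = ["age", "duration"] + [f"eth_{e}" for e in ETHNICITIES[1:]]
    missing = [n for n in needed if n not in params.index]
    if missing:
        raise ValueError(f"fit lacks the terms needed for a points score: {missing}")
    coefs = {name: float(params[name]) for name in needed}
    nonzero = [abs(c) for c in coefs.values() if c != 0.0]
    if not nonzero:
        raise ValueError("all included coefficients are zero; no score derivable")
    if scale is None:
        scale = min(nonzero)
    eth_points = {"white": 0}
    for e in ETHNICITIES[1:]:
        eth_points[e] = round_half_away(coefs[f"eth_{e}"] / scale)
    return PointsTable(
        age_points=round_half_away(coefs["age"] / scale),
        duration_points=round_half_away(coefs["duration"] / scale),
        ethnicity_points=eth_points,
        scale=float(scale),
        threshold=threshold,
    )


def score_person(points: PointsTable, person: Person, at_date: dt.date) -> int:
    """Integer score: age + duration step components plus ethnicity points."""
    if at_date < person.diagnosis_date:
        raise ValueError("at_date precedes the diabetes diagnosis date")
    if person.ethnicity not in points.ethnicity_points:
        raise ValueError(f"unknown ethnicity category {person.ethnicity!r}")
    whole_age = int(person.age_years(at_date))
    whole_dur = int(person.duration_years(at_date))
    return (
        points.age_points * (whole_age // points.age_step_years)
        + points.duration_points * (whole_dur // points.duration_step_years)
        + points.ethnicity_points[person.ethnicity]
    )


class PointsThreshold(NamedTuple):
    threshold: int
    achieved_fraction: float


def calibrate_points_threshold(
    points: PointsTable,
    cohort: Sequence[EligibleHistory] | Sequence[int],
    flag_fraction: float = 0.20,
) -> PointsThreshold:
    """Smallest integer t flagging at most ``flag_fraction`` of people.

    Scores are evaluated at pathway entry when a cohort of eligible
    histories is given; a plain sequence of integer scores is also
    accepted.  Integer granularity makes the target fraction exactly
    unattainable in general, so the achieved fraction is reported with the
    threshold.  When every threshold up to the maximum score overshoots
    (e.g. all scores equal), the maximum score is returned with a warning.
    """
    if not 0.0 < flag_fraction < 1.0:
        raise ValueError("flag_fraction must be in (0, 1)")
    scores: list[int] = []
    for item in cohort:
        if isinstance(item, EligibleHistory):
            appt = item.history.appointments[item.entry_index]
            scores.append(score_person(points, item.history.person, appt.date))
        else:
            scores.append(int(item))
    if not scores:
        raise ValueError("empty cohort")
    n = len(scores)
    for t in range(min(scores), max(scores) + 1):
        frac = sum(s >= t for s in scores) / n
        if frac <= flag_fraction:
            return PointsThreshold(t, frac)
    warnings.warn(
        "no threshold at or below the maximum score flags at most "
        f"{flag_fraction:.0%}; returning the maximum score"
    )
    return PointsThreshold(max(scores), sum(s >= max(scores) for s in scores) / n)
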