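"""Headline and equity metrics for simulated screening protocols.

Per-appointment STDR diagnosis rates (per 100,000 and percent), appointment
reductions and delayed-diagnosis fractions relative to annual screening,
subgroup risk ratios against the lowest-risk base group (white ethnicity,
age over 40, diabetes duration under 10 years), and Kaplan–Meier curves
for time to STDR diagnosis.

Conventions: each STDR diagnosis is counted once in its person's subgroup
(subgroups are fixed at pathway entry); rate denominators are seen
appointments under the protocol in question; risk-ratio confidence
intervals use the log-RR Wald formula; displayed rates round per-100k to
integer and percentages to integer, matching screening-report precision.
"""
from __future__ import annotations

import math
import warnings
from typing import Mapping, NamedTuple, Optional, Sequence

import pandas as pd
from lifelines import KaplanMeierFitter

from .eligibility import EligibleHistory
from .protocols import ProtocolResult
from .types import ETHNICITIES

BASE_GROUP = ("gt40", "lt10", "white")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


class PerAppointmentRate(NamedTuple):
    per_100k: int
    percent: float


def per_appointment_rate(n_diagnoses: int, n_appointments: int) -> PerAppointmentRate:
    """Diagnoses per 100,000 appointments (integer) and percent (1 d.p.)."""
    if n_appointments <= 0:
        raise ValueError("n_appointments must be positive")
    rate = n_diagnoses / n_appointments
    return PerAppointmentRate(_round_half_up(100_000 * rate), round(100 * rate, 1))


def percent_reduction(n_protocol: int, n_annual: int) -> int:
    """Integer percent reduction of a count relative to the annual protocol."""
    if n_annual <= 0:
        raise ValueError("n_annual must be positive")
    return _round_half_up(100.0 * (1.0 - n_protocol / n_annual))


def delayed_fraction(n_delayed: int, n_total: int) -> int:
    """Delayed diagnoses as an integer percent of all diagnoses."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_delayed > n_total:
        raise ValueError("n_delayed exceeds n_total")
    return _round_half_up(100.0 * n_delayed / n_total)


class SubgroupKey(NamedTuple):
    age_band: str  # le40 / gt40
    duration_band: Optional[str]  # lt10 / ge10; None when age_band == le40
    ethnicity: str


def subgroup_key(
    eligible: EligibleHistory, missing_ethnicity_fallback: str = "white"
) -> SubgroupKey:
    """Assign a person to an equity subgroup using age and duration at entry.

    People aged 40 or under are stratified by ethnicity only (their
    duration band is None) because the young stratum is small.
    """
    person = eligible.history.person
    entry_date = eligible.history.appointments[eligible.entry_index].date
    eth = person.ethnicity or missing_ethnicity_fallback
    if person.age_years(entry_date) <= 40.0:
        return SubgroupKey("le40", None, eth)
    band = "ge10" if person.duration_years(entry_date) >= 10.0 else "lt10"
    return SubgroupKey("gt40", band, eth)


def subgroup_stratify(
    results: Sequence[ProtocolResult],
    eligibles: Sequence[EligibleHistory],
    missing_ethnicity: str = "most_common",
) -> pd.DataFrame:
    """Seen appointments and STDR diagnoses per equity subgroup.

    Every diagnosis (delayed or not) is counted once in its person's
    subgroup, so subgroup sums reproduce the protocol totals.  Missing
    ethnicity is assigned to the cohort's most common group by default.
    """
    by_id = {e.history.person.id: e for e in eligibles}
    missing = [r.person_id for r in results if r.person_id not in by_id]
    if missing:
        raise ValueError(f"results contain people absent from the cohort: {missing[:5]}")
    if missing_ethnicity == "most_common":
        counts: dict[str, int] = {}
        for e in eligibles:
            eth = e.history.person.ethnicity
            if eth:
                counts[eth] = counts.get(eth, 0) + 1
        fallback = max(counts, key=counts.get) if counts else "white"
    else:
        fallback = missing_ethnicity

    acc: dict[SubgroupKey, dict[str, int]] = {}
    for r in results:
        key = subgroup_key(by_id[r.person_id], fallback)
        slot = acc.setdefault(key, {"seen_appointments": 0, "stdr": 0, "people": 0})
        slot["seen_appointments"] += r.n_appointments_seen
        slot["stdr"] += r.n_stdr_total
        slot["people"] += 1
    rows = [
        # None duration band (the young stratum) is written as "na" so the
        # index sorts cleanly
        {"age_band": k.age_band, "duration_band": k.duration_band or "na",
         "ethnicity": k.ethnicity, **v}
        for k, v in acc.items()
    ]
    return (
        pd.DataFrame(rows)
        .set_index(["age_band", "duration_band", "ethnicity"])
        .sort_index()
    )


class RiskRatio(NamedTuple):
    rr: float
    ci_low: float
    ci_high: float


def risk_ratio_ci(a: int, n1: int, b: int, n2: int) -> RiskRatio:
    """Risk ratio (a/n1)/(b/n2) with a log-RR Wald 95% CI.

    Zero events in the comparison group give RR 0 with the CI computed
    under a 0.5 continuity correction; zero events in the reference group
    leave the RR undefined and raise.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if b == 0:
        raise ValueError("undefined risk ratio: zero events in the reference group")
    rr = (a / n1) / (b / n2)
    a_ci = a if a > 0 else 0.5
    rr_ci = (a_ci / n1) / (b / n2)
    se = math.sqrt(1.0 / a_ci - 1.0 / n1 + 1.0 / b - 1.0 / n2)
    return RiskRatio(rr, rr_ci * math.exp(-1.96 * se), rr_ci * math.exp(1.96 * se))


def subgroup_table(
    results: Sequence[ProtocolResult],
    eligibles: Sequence[EligibleHistory],
    base_group: tuple = BASE_GROUP,
    missing_ethnicity: str = "most_common",
) -> pd.DataFrame:
    """Per-subgroup rates and risk ratios against the base group.

    The base group's RR is identically 1.
    """
    counts = subgroup_stratify(results, eligibles, missing_ethnicity)
    key = (base_group[0], base_group[1], base_group[2])
    if key not in counts.index:
        raise ValueError(f"base group {key} absent from the cohort")
    b = int(counts.loc[key, "stdr"])
    n2 = int(counts.loc[key, "seen_appointments"])
    rates, rrs, los, his = [], [], [], []
    for idx, row in counts.iterrows():
        a, n1 = int(row["stdr"]), int(row["seen_appointments"])
        rates.append(a / n1 if n1 else float("nan"))
        if idx == key:
            rr = RiskRatio(1.0, 1.0, 1.0)  # base group vs itself: degenerate CI
        else:
            rr = risk_ratio_ci(a, n1, b, n2)
        rrs.append(rr.rr)
        los.append(rr.ci_low)
        his.append(rr.ci_high)
    out = counts.copy()
    out["rate_per_appointment"] = rates
    out["rr"] = rrs
    out["rr_ci_low"] = los
    out["rr_ci_high"] = his
    return out


def km_curve(
    eligibles: Sequence[EligibleHistory], stratifier: str = "duration"
) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier survival for time from pathway entry to STDR diagnosis.

    ``stratifier`` is one of duration / ethnicity / age (bands taken at
    entry).  People without an STDR event are censored at their last
    retained appointment.  Empty strata are omitted with a warning.
    """
    if stratifier not in ("duration", "ethnicity", "age"):
        raise ValueError("stratifier must be duration, ethnicity or age")
    data: dict[str, tuple[list[float], list[int]]] = {}
    for e in eligibles:
        entry_date = e.history.appointments[e.entry_index].date
        retained = e.retained()
        stdr_date = next((a.date for a in retained if a.is_stdr), None)
        if stdr_date is not None:
            t, observed = (stdr_date - entry_date).days, 1
        else:
            t, observed = (retained[-1].date - entry_date).days, 0
        person = e.history.person
        if stratifier == "duration":
            stratum = "ge10" if person.duration_years(entry_date) >= 10.0 else "lt10"
        elif stratifier == "age":
            stratum = "le40" if person.age_years(entry_date) <= 40.0 else "gt40"
        else:
            stratum = person.ethnicity or "missing"
        data.setdefault(stratum, ([], []))[0].append(float(t))
        data[stratum][1].append(observed)

    expected = {
        "duration": ["lt10", "ge10"],
        "age": ["le40", "gt40"],
        "ethnicity": list(ETHNICITIES),
    }[stratifier]
    curves: dict[str, pd.DataFrame] = {}
    for stratum in expected:
        if stratum not in data or not data[stratum][0]:
            warnings.warn(f"stratum {stratum!r} is empty; omitted from KM output")
            continue
        durations, events = data[stratum]
        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=events, label=stratum)
        sf = kmf.survival_function_
        curves[stratum] = pd.DataFrame(
            {"time_days": sf.index.to_numpy(), "survival": sf[stratum].to_numpy()}
        )
    return curves


def render_report(
    aggregate: pd.DataFrame,
    subgroup_tables: Mapping[str, pd.DataFrame],
    out_dir,
) -> dict[str, "object"]:
    """Write a counts/percentages table and a subgroup RR table.

    ``aggregate`` is the output of :func:`retriage.protocols.aggregate_results`;
    ``subgroup_tables`` maps protocol name to :func:`subgroup_table` output.
    Emits ``table2.csv``, ``table3.csv`` and a human-readable
    ``report.txt`` under ``out_dir``; returns the two frames.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t2 = pd.DataFrame(
        {
            name: {
                "appointments": f"{int(row.appointments_seen):,} ({_round_half_up(row.pct_appointments)}%)",
                "non_delayed_stdr": f"{int(row.stdr_nondelayed):,} ({_round_half_up(row.pct_nondelayed)}%)",
                "delayed_stdr": f"{int(row.stdr_delayed):,} ({_round_half_up(row.pct_delayed)}%)",
            }
            for name, row in aggregate.iterrows()
        }
    )
    t2.to_csv(out / "table2.csv")

    t3_cols = {}
    for name, table in subgroup_tables.items():
        t3_cols[name] = {
            idx: f"{row.rr:.2f} ({row.rr_ci_low:.2f}, {row.rr_ci_high:.2f})"
            for idx, row in table.iterrows()
        }
    t3 = pd.DataFrame(t3_cols)
    t3.index.names = ["age_band", "duration_band", "ethnicity"]
    t3.to_csv(out / "table3.csv")

    text = [
        "Screening protocol comparison (counts; % relative to annual)",
        t2.to_string(),
        "",
        "Risk ratios of STDR diagnosis per appointment vs the base group",
        "(white, age >40, duration <10 y):",
        t3.to_string(),
    ]
    (out / "report.txt").write_text("\n".join(text) + "\n")
    return {"table2": t2, "table3": t3}
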