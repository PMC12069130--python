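"""Screening-recall protocol simulators.

Four recall protocols are replayed over historical (here: synthetic)
appointment sequences of pathway-eligible people:

* **annual** — every appointment is kept ("seen") as it occurred.
* **biennial** — alternate appointments occurring less than two years
  after the previous seen appointment are "hidden"; a seen visit with
  background retinopathy only (R1M0) returns the person to annual recall
  until they re-qualify with two consecutive seen R0M0 visits.
* **risk model** — at each seen qualifying appointment a fitted model's
  2-year STDR probability decides whether the next appointment is kept
  regardless of timing (high risk) or is subject to biennial hiding.
* **points** — same skeleton, with an integer points score in place of the
  model probability.

An STDR outcome (R2/R3/M1) on a hidden appointment is a *delayed*
diagnosis; on a seen appointment it is not delayed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .eligibility import EligibleHistory
from .types import Appointment

Label = Literal["seen", "hidden"]

#: days within which an alternate appointment is a hiding candidate (2 years)
DEFAULT_WINDOW_HIDE_DAYS = 730
#: days defining the binary STDR outcome window after a qualifying visit
DEFAULT_OUTCOME_WINDOW_DAYS = 590


@dataclass(frozen=True)
class AppointmentLabel:
    index: int
    date: object
    label: Label
    stdr: bool
    delayed: bool


@dataclass
class ProtocolResult:
    """Per-person seen/hidden labels and delayed-diagnosis counts."""

    person_id: int
    labels: list[AppointmentLabel] = field(default_factory=list)

    @property
    def n_appointments_seen(self) -> int:
        return sum(1 for l in self.labels if l.label == "seen")

    @property
    def n_stdr_total(self) -> int:
        return sum(1 for l in self.labels if l.stdr)

    @property
    def n_stdr_delayed(self) -> int:
        return sum(1 for l in self.labels if l.stdr and l.delayed)

    @property
    def n_stdr_nondelayed(self) -> int:
        return self.n_stdr_total - self.n_stdr_delayed


@dataclass
class TriagePolicy:
    """Protocol configuration.

    ``reentry`` controls whether two consecutive seen R0M0 visits return a
    person from annual mode to biennial hiding; ``r1_on_hidden_returns``
    controls whether an R1M0 grade on a *hidden* appointment (which the
    programme would not observe) triggers the return to annual recall —
    off by default.
    """

    kind: Literal["annual", "biennial", "risk_model", "points"] = "biennial"
    window_hide_days: int = DEFAULT_WINDOW_HIDE_DAYS
    outcome_window_days: int = DEFAULT_OUTCOME_WINDOW_DAYS
    reentry: bool = True
    r1_on_hidden_returns: bool = False

    def __post_init__(self) -> None:
        if self.window_hide_days <= 0 or self.outcome_window_days <= 0:
            raise ValueError("windows must be positive")


def _is_r1m0(a: Appointment) -> bool:
    return a.gradable and a.r_grade == "R1" and a.m_grade == "M0"


def _run_state_machine(
    eligible: EligibleHistory,
    decide_force_seen: Optional[Callable[[int, Appointment], bool]],
    policy: TriagePolicy,
) -> ProtocolResult:
    """Replay one history, labelling post-entry appointments seen/hidden.

    ``decide_force_seen(index, appointment)`` is evaluated at each *seen
    qualifying* appointment (an R0M0 whose previous seen appointment was
    R0M0) and returns True when the next appointment must be seen whenever
    it occurs; None means never force (plain biennial).
    """
    retained = eligible.retained()
    entry = eligible.entry_index
    result = ProtocolResult(person_id=eligible.history.person.id)

    def record(j: int, label: Label) -> None:
        a = retained[j]
        result.labels.append(
            AppointmentLabel(
                index=j, date=a.date, label=label, stdr=a.is_stdr,
                delayed=a.is_stdr and label == "hidden",
            )
        )

    # entry appointment is always seen; its predecessor is R0M0 by
    # construction, so the policy decision applies at entry
    record(entry, "seen")
    last_seen = entry
    prev_hidden = False
    annual_mode = False
    consec_seen_r0m0 = 1  # entry is R0M0
    prev_seen_r0m0 = True  # grade of the seen appointment before the current one
    force_next = decide_force_seen(entry, retained[entry]) if decide_force_seen else False

    for j in range(entry + 1, len(retained)):
        appt = retained[j]
        gap = (appt.date - retained[last_seen].date).days
        if prev_hidden or annual_mode or force_next:
            label: Label = "seen"
        elif gap < policy.window_hide_days:
            label = "hidden"
        else:
            label = "seen"
        record(j, label)

        if label == "hidden":
            prev_hidden = True
            if policy.r1_on_hidden_returns and _is_r1m0(appt):
                annual_mode = True
                consec_seen_r0m0 = 0
            continue

        # update observed-state machine at the seen appointment
        was_qualifying = appt.is_r0m0 and prev_seen_r0m0
        if _is_r1m0(appt):
            annual_mode = True
            consec_seen_r0m0 = 0
        elif appt.is_r0m0:
            consec_seen_r0m0 += 1
            if annual_mode and policy.reentry and consec_seen_r0m0 >= 2:
                annual_mode = False
        else:
            consec_seen_r0m0 = 0
        prev_seen_r0m0 = appt.is_r0m0
        prev_hidden = False
        last_seen = j
        if decide_force_seen is not None and was_qualifying and not annual_mode:
            force_next = decide_force_seen(j, appt)
        else:
            # non-qualifying seen appointments default to annual behaviour
            # via annual_mode; outside annual mode hiding may resume
            force_next = False
    return result


def simulate_annual(eligible: EligibleHistory) -> ProtocolResult:
    """All post-entry appointments seen; no diagnosis is delayed."""
    result = ProtocolResult(person_id=eligible.history.person.id)
    for j, a in eligible.post_entry():
        result.labels.append(
            AppointmentLabel(index=j, date=a.date, label="seen", stdr=a.is_stdr, delayed=False)
        )
    return result


def simulate_biennial(
    eligible: EligibleHistory, policy: Optional[TriagePolicy] = None
) -> ProtocolResult:
    policy = policy or TriagePolicy(kind="biennial")
    return _run_state_machine(eligible, None, policy)


def simulate_risk_triage(
    eligible: EligibleHistory,
    policy: TriagePolicy,
    model_fit,
    threshold: Optional[float] = None,
) -> ProtocolResult:
    """Hide only for people below the model's risk threshold.

    ``model_fit`` must expose ``predict_history(eligible, index) ->
    probability`` (see :mod:`retriage.risk`); ties at the threshold are
    treated as high risk (seen).
    """
    thr = model_fit.threshold_p if threshold is None else threshold

    def decide(index: int, appt: Appointment) -> bool:
        return model_fit.predict_history(eligible, index) >= thr

    return _run_state_machine(eligible, decide, policy)


def simulate_points_triage(
    eligible: EligibleHistory,
    points_table,
    policy: Optional[TriagePolicy] = None,
) -> ProtocolResult:
    """Hide only for people scoring below the integer points threshold."""
    policy = policy or TriagePolicy(kind="points")
    person = eligible.history.person

    def decide(index: int, appt: Appointment) -> bool:
        return points_table.score(person, appt.date) >= points_table.threshold

    return _run_state_machine(eligible, decide, policy)


def run_protocol(
    eligibles: Sequence[EligibleHistory],
    policy: TriagePolicy,
    model_fit=None,
    points_table=None,
) -> list[ProtocolResult]:
    """Apply one protocol across a cohort of eligible histories."""
    if policy.kind == "annual":
        return [simulate_annual(e) for e in eligibles]
    if policy.kind == "biennial":
        return [simulate_biennial(e, policy) for e in eligibles]
    if policy.kind == "risk_model":
        if model_fit is None:
            raise ValueError("risk_model protocol requires a fitted model")
        return [simulate_risk_triage(e, policy, model_fit) for e in eligibles]
    if policy.kind == "points":
        if points_table is None:
            raise ValueError("points protocol requires a points table")
        return [simulate_points_triage(e, points_table, policy) for e in eligibles]
    raise ValueError(f"unknown protocol kind {policy.kind!r}")


def results_frame(results: Sequence[ProtocolResult]) -> pd.DataFrame:
    """One row per labelled appointment: person, date, label, STDR flags."""
    rows = [
        {
            "person_id": r.person_id,
            "index": l.index,
            "date": l.date,
            "label": l.label,
            "stdr_flag": l.stdr,
            "delayed_flag": l.delayed,
        }
        for r in results
        for l in r.labels
    ]
    return pd.DataFrame(rows)


def aggregate_results(
    results_by_protocol: Mapping[str, Sequence[ProtocolResult]],
    annual_key: str = "annual",
) -> pd.DataFrame:
    """Cohort totals per protocol with percentages relative to annual.

    All protocols must cover the same people (same cohort); otherwise the
    comparison is meaningless and an error is raised.
    """
    if annual_key not in results_by_protocol:
        raise ValueError(f"need {annual_key!r} results as the 100% reference")
    person_sets = {
        name: frozenset(r.person_id for r in res)
        for name, res in results_by_protocol.items()
    }
    reference = person_sets[annual_key]
    for name, ids in person_sets.items():
        if ids != reference:
            raise ValueError(f"protocol {name!r} covers a different cohort")

    annual = results_by_protocol[annual_key]
    n_seen_annual = sum(r.n_appointments_seen for r in annual)
    n_stdr_annual = sum(r.n_stdr_total for r in annual)
    rows = []
    for name, res in results_by_protocol.items():
        n_seen = sum(r.n_appointments_seen for r in res)
        n_delayed = sum(r.n_stdr_delayed for r in res)
        n_nondelayed = sum(r.n_stdr_nondelayed for r in res)
        rows.append(
            {
                "protocol": name,
                "appointments_seen": n_seen,
                "pct_appointments": 100.0 * n_seen / n_seen_annual if n_seen_annual else float("nan"),
                "stdr_total": n_delayed + n_nondelayed,
                "stdr_nondelayed": n_nondelayed,
                "pct_nondelayed": 100.0 * n_nondelayed / n_stdr_annual if n_stdr_annual else float("nan"),
                "stdr_delayed": n_delayed,
                "pct_delayed": 100.0 * n_delayed / n_stdr_annual if n_stdr_annual else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("protocol")
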