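"""Pathway eligibility: ungradable resolution, entry detection, censoring.

A person enters the low-risk ("biennial") pathway at the second of two
consecutive gradable appointments with no detectable retinopathy or
maculopathy (R0M0), provided at least one further gradable appointment
exists.  Ungradable encounters are resolved by using the next gradable
appointment instead, and are excluded from all appointment counts; the
same applies to non-attended visits, which carry no grade.  A person is
censored at the first post-entry appointment showing any degree of
retinopathy (R1, R2, R3 or M1) — the triggering appointment is retained,
because it carries the outcome, and everything after it is excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

from .types import Appointment, ScreeningHistory


@dataclass
class EligibleHistory:
    """A pathway-eligible history with entry and censoring resolved.

    ``history`` holds only gradable appointments (U and non-attended visits
    removed); ``raw`` keeps the original record so covariates such as prior
    non-attendance can still be computed.
    """

    history: ScreeningHistory
    entry_index: int
    censor_index: Optional[int] = None
    raw: Optional[ScreeningHistory] = None

    def retained(self) -> list[Appointment]:
        """Appointments up to and including the censoring appointment."""
        appts = self.history.appointments
        if self.censor_index is None:
            return list(appts)
        return list(appts[: self.censor_index + 1])

    def post_entry(self) -> list[tuple[int, Appointment]]:
        """(index, appointment) pairs from pathway entry to censoring."""
        return [(i, a) for i, a in enumerate(self.retained()) if i >= self.entry_index]


def resolve_ungradable(history: ScreeningHistory) -> ScreeningHistory:
    """Drop ungradable and non-attended visits from the appointment sequence.

    Idempotent; ordering preserved.  An all-ungradable history yields an
    empty appointment list.
    """
    return ScreeningHistory(
        person=history.person,
        appointments=[a for a in history.appointments if a.gradable],
        hba1c_series=history.hba1c_series,
        sbp_series=history.sbp_series,
        dbp_series=history.dbp_series,
    )


def find_pathway_entry(history: ScreeningHistory) -> Optional[int]:
    """Earliest index i >= 1 with appointments i-1 and i both R0M0 and at
    least one appointment after i; None if no such index."""
    appts = history.appointments
    for i in range(1, len(appts) - 1):
        if appts[i - 1].is_r0m0 and appts[i].is_r0m0:
            return i
    return None


def censor_history(eligible: EligibleHistory) -> EligibleHistory:
    """Set censor_index at the first post-entry appointment with any DR."""
    appts = eligible.history.appointments
    censor = None
    for j in range(eligible.entry_index + 1, len(appts)):
        if appts[j].any_dr:
            censor = j
            break
    return replace(eligible, censor_index=censor)


def qualifying_appointments(eligible: EligibleHistory) -> list[int]:
    """Indices of R0M0 appointments whose immediate predecessor is R0M0.

    These are the prediction points at which 2-year STDR risk is evaluated.
    """
    appts = eligible.retained()
    return [
        j
        for j in range(1, len(appts))
        if appts[j].is_r0m0 and appts[j - 1].is_r0m0
    ]


def prepare_eligible(history: ScreeningHistory) -> Optional[EligibleHistory]:
    """Resolve ungradable visits, locate entry, and apply censoring.

    Returns None when the history never qualifies for the pathway.
    """
    resolved = resolve_ungradable(history)
    entry = find_pathway_entry(resolved)
    if entry is None:
        return None
    return censor_history(
        EligibleHistory(history=resolved, entry_index=entry, raw=history)
    )


def eligible_cohort(cohort: list[ScreeningHistory]) -> list[EligibleHistory]:
    return [e for e in (prepare_eligible(h) for h in cohort) if e is not None]


def eligibility_table(cohort: list[ScreeningHistory]) -> pd.DataFrame:
    """Per-person eligibility summary: entry date and censor date (if any)."""
    rows = []
    for hist in cohort:
        e = prepare_eligible(hist)
        appts = e.history.appointments if e else []
        rows.append(
            {
                "person_id": hist.person.id,
                "eligible": e is not None,
                "entry_date": appts[e.entry_index].date if e else None,
                "censor_date": (
                    appts[e.censor_index].date
                    if e is not None and e.censor_index is not None
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)
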