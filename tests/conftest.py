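import datetime as dt

import pytest

from retriage import SimConfig, generate_cohort
from retriage.eligibility import EligibleHistory, eligible_cohort, prepare_eligible
from retriage.types import Appointment, Person, ScreeningHistory

START = dt.date(2015, 1, 6)


def default_person(**overrides) -> Person:
    fields = dict(
        id=0,
        gender="female",
        ethnicity="white",
        birth_date=dt.date(1960, 5, 1),
        diabetes_type="type2_or_other",
        diagnosis_date=dt.date(2010, 3, 1),
        imd_quintile=3,
        smoking="never",
    )
    fields.update(overrides)
    return Person(**fields)


def make_history(grades, gaps=None, person=None, start=START, **series) -> ScreeningHistory:
    """Build a history from compact grade codes.

    Codes: 'R0M0', 'R1M0', 'R2M0', 'R3M0', 'R1M1', 'R0M1', 'U', 'DNA'.
    ``gaps[i]`` is the number of days between visit i-1 and visit i.
    """
    gaps = gaps or [365] * (len(grades) - 1)
    assert len(gaps) == len(grades) - 1
    date = start
    appts = []
    for i, code in enumerate(grades):
        if i > 0:
            date = date + dt.timedelta(days=gaps[i - 1])
        if code == "DNA":
            appts.append(Appointment(date=date, attended=False))
        elif code == "U":
            appts.append(Appointment(date=date, r_grade="U"))
        else:
            appts.append(Appointment(date=date, r_grade=code[:2], m_grade=code[2:]))
    return ScreeningHistory(person=person or default_person(), appointments=appts, **series)


def make_eligible(grades, gaps=None, person=None, start=START, censor=True) -> EligibleHistory:
    hist = make_history(grades, gaps, person, start)
    e = prepare_eligible(hist)
    assert e is not None, "fixture history must be pathway-eligible"
    if not censor:
        e.censor_index = None
    return e


@pytest.fixture(scope="session")
def cohort2000():
    return generate_cohort(SimConfig(n_people=2000, seed=7))


@pytest.fixture(scope="session")
def eligibles2000(cohort2000):
    return eligible_cohort(cohort2000)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Larger cohort for parameter-recovery checks."""
    return generate_cohort(SimConfig(n_people=5000, seed=11))


@pytest.fixture(scope="session")
def model2_fit(eligibles2000):
    from retriage import STDRRiskModel, build_training_table

    table = build_training_table(eligibles2000)
    fit = STDRRiskModel.from_training_table(table, 2).fit()
    fit.calibrate_threshold()
    return fit
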