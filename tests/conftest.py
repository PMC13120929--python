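import datetime as dt

import pytest

from ptra.cohort_io import (
    Cohort,
    MriFinding,
    MsCourse,
    PatientRecord,
    Sex,
    TreatmentEpisode,
    Visit,
)


def make_patient(
    pid="P1",
    sex=Sex.FEMALE,
    birth=dt.date(1980, 1, 1),
    visit_specs=((dt.date(2015, 1, 1), 3.0), (dt.date(2015, 7, 1), 3.0)),
    relapses=(),
    mri=(),
    treatments=(),
    courses=None,
    fss=None,
):
    """Small helper: visits from (date, edss) pairs plus optional streams."""
    visits = []
    for i, (date, edss) in enumerate(visit_specs):
        visits.append(
            Visit(
                date=date,
                edss=edss,
                fss=dict(fss[i]) if fss else {},
                ms_course=courses[i] if courses else None,
            )
        )
    return PatientRecord(
        patient_id=pid,
        sex=sex,
        birth_date=birth,
        visits=tuple(visits),
        relapses=tuple(relapses),
        mri_findings=tuple(mri),
        treatments=tuple(treatments),
    )


@pytest.fixture
def two_patient_cohort():
    p1 = make_patient(
        "P1",
        relapses=(dt.date(2015, 3, 1),),
        mri=(MriFinding(dt.date(2015, 4, 1), "BR", True),),
        treatments=(TreatmentEpisode(dt.date(2015, 5, 1), "Fingolimod"),),
    )
    p2 = make_patient(
        "P2",
        sex=Sex.MALE,
        birth=dt.date(1975, 6, 15),
        visit_specs=(
            (dt.date(2016, 1, 1), 2.0),
            (dt.date(2016, 6, 1), None),
            (dt.date(2017, 1, 1), 2.5),
        ),
    )
    return Cohort(patients=(p1, p2))
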