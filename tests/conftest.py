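import pytest

from ndd_rob.io import load_fixture
from ndd_rob.types import (
    Answer3,
    InformantType,
    Instrument,
    OutcomeMeasure,
    ScoreLevel,
    StudyGroup,
    StudyRecord,
)


@pytest.fixture(scope="session")
def worked_cohort():
    return load_fixture("worked_examples")


@pytest.fixture(scope="session")
def worked_records(worked_cohort):
    return {r.study_id: r for r in worked_cohort.studies}


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_characteristics")


def make_record(
    study_id="s1",
    *,
    n=50,
    first_age=7.0,
    length=4.0,
    n_waves=3,
    informants=frozenset({InformantType.parent}),
    informants_missing=False,
    child_rated=False,
    designed=Answer3.no,
    adapted=Answer3.no,
    overlaps=(),
    items_available=True,
    criteria_available=True,
    functioning=None,
    groups=None,
    outcomes=None,
):
    """Minimal valid study record for rule-level tests."""
    from ndd_rob.types import IntellectualFunctioning

    if groups is None:
        groups = (
            StudyGroup(
                diagnosis_label="NDD",
                n=n,
                first_wave_mean_age=first_age,
                followup_length=length,
                n_waves=n_waves,
                functioning=functioning or IntellectualFunctioning(),
            ),
        )
    if outcomes is None:
        outcomes = (
            OutcomeMeasure(
                instrument_name="Scale X",
                score_label="Scale X total",
                score_level=ScoreLevel.total,
                informants=informants,
                informants_missing=informants_missing,
                child_rated=child_rated,
            ),
        )
    return StudyRecord(
        study_id=study_id,
        groups=groups,
        outcomes=outcomes,
        instruments=(
            Instrument(
                name="Scale X",
                designed_for_ndd=designed,
                adapted_for_ndd=adapted,
                adaptation_note="note" if adapted is Answer3.yes else None,
            ),
        ),
        overlaps=tuple(overlaps),
        items_available=items_available,
        criteria_available=criteria_available,
    )
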