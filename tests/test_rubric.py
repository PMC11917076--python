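"""Decision-table and aggregation semantics of the rating engine.

Every domain rater is checked against an independently hand-coded truth
table over the full cross-product of its sub-answer values, and the overall
aggregation against a literal transcription of its three rules over all 81
rating vectors.
"""

import itertools

import pytest

from ndd_rob.rubric import (
    aggregate_overall,
    answer_q1a,
    answer_q1b,
    answer_q2c,
    answer_q3a,
    answer_q3b,
    assess_study,
    rate_domain1,
    rate_domain2,
    rate_domain3,
    rate_domain4,
    rate_finding,
    wave_mean_ages,
)
from ndd_rob.types import (
    Answer3 as A,
    FunctioningCategory,
    InformantType as I,
    Instrument,
    IntellectualFunctioning,
    OverlapFinding,
    RiskLevel as R,
    StudyGroup,
)

from conftest import make_record

ANSWERS = (A.yes, A.no, A.cant_tell)


# --------------------------------------------------------------------------
# Hand-coded truth-table oracles (kept independent of the implementation:
# transcribed from the rubric's response-option text, not from the code).

D1_ORACLE = {
    (A.yes, A.yes): R.low,
    (A.yes, A.no): R.low,
    (A.yes, A.cant_tell): R.low,
    (A.no, A.yes): R.low,
    (A.no, A.no): R.high,
    (A.no, A.cant_tell): R.unclear,
    (A.cant_tell, A.yes): R.low,
    (A.cant_tell, A.no): R.unclear,
    (A.cant_tell, A.cant_tell): R.unclear,
}

D3_ORACLE = {
    (A.yes, A.yes): R.low,
    (A.yes, A.no): R.high,
    (A.yes, A.cant_tell): R.unclear,
    (A.no, A.yes): R.low,
    (A.no, A.no): R.low,
    (A.no, A.cant_tell): R.low,
    (A.cant_tell, A.yes): R.low,
    (A.cant_tell, A.no): R.unclear,
    (A.cant_tell, A.cant_tell): R.unclear,
}


def test_domain1_truth_table():
    for (q1a, q1b), expected in D1_ORACLE.items():
        assert rate_domain1(q1a, q1b) is expected, (q1a, q1b)


def test_domain3_truth_table():
    for (q3a, q3b), expected in D3_ORACLE.items():
        assert rate_domain3(q3a, q3b) is expected, (q3a, q3b)


def _d2_record(n_informants, missing, q2c_target):
    if missing:  # informant information not extractable
        informants = frozenset()
    else:
        informants = {
            1: frozenset({I.parent}),
            2: frozenset({I.parent, I.teacher}),
        }[n_informants]
    if q2c_target is A.yes:
        first, length = 1.0, 3.0
    elif q2c_target is A.no:
        first, length = 7.0, 3.0
    else:
        first, length = None, None
    return make_record(
        informants=informants,
        informants_missing=missing,
        first_age=first,
        length=length,
        n_waves=3 if first is not None else None,
    )


@pytest.mark.parametrize(
    "n_informants,missing",
    [(1, False), (2, False), (1, True)],  # two known types excludes "missing"
)
@pytest.mark.parametrize("q2c", ANSWERS)
def test_domain2_truth_table(n_informants, missing, q2c):
    """Two informants or all-preschool waves -> low; single informant with
    school-age children -> high; missing informant or age data -> unclear."""
    record = _d2_record(n_informants, missing, q2c)
    assert answer_q2c(record) is q2c
    if n_informants >= 2 and not missing:
        expected = R.low
    elif q2c is A.yes:
        expected = R.low
    elif missing or q2c is A.cant_tell:
        expected = R.unclear
    else:
        expected = R.high
    assert rate_domain2(record) is expected


def _instrument(designed, adapted):
    return Instrument(
        name=f"i-{designed.value}-{adapted.value}",
        designed_for_ndd=designed,
        adapted_for_ndd=adapted,
        adaptation_note="note" if adapted is A.yes else None,
    )


def test_domain4_truth_table_single_and_pairs():
    """All instruments designed-or-adapted -> low; none (and none wholly
    unknown) -> high; otherwise unclear."""

    def oracle(instruments):
        passes = [
            i.designed_for_ndd is A.yes or i.adapted_for_ndd is A.yes
            for i in instruments
        ]
        if all(passes):
            return R.low
        unknown = any(
            i.designed_for_ndd is A.cant_tell and i.adapted_for_ndd is A.cant_tell
            for i in instruments
        )
        if not any(passes) and not unknown:
            return R.high
        return R.unclear

    statuses = list(itertools.product(ANSWERS, repeat=2))
    singles = [[_instrument(d, a)] for d, a in statuses]
    pairs = [
        [_instrument(*s1), _instrument(*s2)]
        for s1, s2 in itertools.combinations_with_replacement(statuses, 2)
    ]
    for instruments in singles + pairs:
        assert rate_domain4(instruments) is oracle(instruments), [
            (i.designed_for_ndd.value, i.adapted_for_ndd.value) for i in instruments
        ]


def test_domain4_empty_errors():
    with pytest.raises(ValueError):
        rate_domain4([])


# --------------------------------------------------------------------------
# Overall aggregation

def aggregation_oracle(v):
    """Literal transcription of the three published aggregation principles."""
    counts = {lvl: v.count(lvl) for lvl in (R.low, R.unclear, R.high)}
    # 1: a level assigned more frequently than any of the others wins
    for lvl, c in counts.items():
        if all(c > c2 for l2, c2 in counts.items() if l2 is not lvl):
            return lvl
    # 2: high and low twice each -> unclear
    if counts[R.high] == 2 and counts[R.low] == 2:
        return R.unclear
    # 3: two high-or-low and two unclear -> unclear
    if counts[R.high] + counts[R.low] == 2 and counts[R.unclear] == 2:
        return R.unclear
    raise AssertionError(f"rules do not cover {v}")


def test_aggregation_matches_rule_oracle_over_all_81_vectors():
    for v in itertools.product((R.low, R.unclear, R.high), repeat=4):
        assert aggregate_overall(v) is aggregation_oracle(list(v)), v


def test_aggregation_permutation_invariant_and_unanimity():
    for v in itertools.product((R.low, R.unclear, R.high), repeat=4):
        results = {aggregate_overall(p) for p in itertools.permutations(v)}
        assert len(results) == 1
    for lvl in (R.low, R.unclear, R.high):
        assert aggregate_overall([lvl] * 4) is lvl


def test_aggregation_non_monotonicity_witness():
    """Softening a low to unclear can *soften* the overall judgement: the
    2-2 definite/unclear split resolves to unclear."""
    assert aggregate_overall([R.high, R.high, R.low, R.unclear]) is R.high
    assert aggregate_overall([R.high, R.high, R.unclear, R.unclear]) is R.unclear


def test_aggregation_rejects_bad_input():
    with pytest.raises(ValueError):
        aggregate_overall([R.low, R.low, R.low])
    with pytest.raises(ValueError):
        aggregate_overall([R.low, R.low, R.low, R.no_information])


# --------------------------------------------------------------------------
# Sub-question answers

def test_q1a_no_when_overlaps_present(worked_records):
    assert answer_q1a(worked_records["anderson2011"]) is A.no


def test_q1a_yes_without_overlaps_and_cant_tell_without_items():
    assert answer_q1a(make_record()) is A.yes
    assert answer_q1a(make_record(items_available=False)) is A.cant_tell
    assert rate_domain1(
        answer_q1a(make_record(items_available=False)),
        answer_q1b(make_record(items_available=False)),
    ) is R.unclear


def _finding(addressed):
    return OverlapFinding(
        outcome_ref="Scale X total",
        item_text="item",
        criterion_text="criterion",
        addressed=addressed,
    )


@pytest.mark.parametrize(
    "statuses,expected",
    [
        ((A.cant_tell, A.no, A.no), A.no),  # worst-case rollup
        ((A.yes, A.yes), A.yes),
        ((A.cant_tell,), A.cant_tell),
        ((A.yes, A.cant_tell), A.cant_tell),
    ],
)
def test_q1b_rollup(statuses, expected):
    record = make_record(overlaps=[_finding(s) for s in statuses])
    assert answer_q1b(record) is expected


def test_finding_level_ratings(worked_records):
    anderson = worked_records["anderson2011"]
    assert [rate_finding(f.addressed) for f in anderson.overlaps] == [
        R.unclear,
        R.high,
        R.high,
    ]


def test_wave_mean_ages_interpolation():
    g = StudyGroup(diagnosis_label="CP", n=92, first_wave_mean_age=2.50,
                   followup_length=2.0, n_waves=3)
    assert wave_mean_ages(g) == pytest.approx((2.50, 3.50, 4.50))
    g2 = StudyGroup(diagnosis_label="x", n=1, first_wave_mean_age=10.0,
                    followup_length=6.0, n_waves=4)
    assert wave_mean_ages(g2) == pytest.approx((10.0, 12.0, 14.0, 16.0))
    explicit = StudyGroup(diagnosis_label="x", n=1, wave_mean_ages=(3.0, 5.5, 9.0))
    assert wave_mean_ages(explicit) == (3.0, 5.5, 9.0)
    unknown = StudyGroup(diagnosis_label="x", n=1, n_waves=3)
    assert wave_mean_ages(unknown) is None
    single = StudyGroup(diagnosis_label="x", n=1, first_wave_mean_age=4.0, n_waves=1)
    assert wave_mean_ages(single) == (4.0,)


def test_q2c_examples(worked_records):
    assert answer_q2c(worked_records["alsem2013"]) is A.yes
    assert answer_q2c(worked_records["anderson2011"]) is A.no
    assert answer_q2c(make_record(first_age=None, length=None, n_waves=None)) is A.cant_tell
    # one known wave at or past school age forces no even with unknown groups
    known = StudyGroup(diagnosis_label="a", n=10, first_wave_mean_age=7.0,
                       followup_length=2.0, n_waves=3)
    unknown = StudyGroup(diagnosis_label="b", n=10)
    assert answer_q2c(make_record(groups=(known, unknown))) is A.no


def test_q3a_functioning_and_age(worked_records):
    assert answer_q3a(worked_records["auerbach2008"]) is A.yes  # no ID, >= 9 always
    assert answer_q3a(worked_records["anderson2011"]) is A.no  # moderate/severe ID
    assert answer_q3a(worked_records["alsem2013"]) is A.no  # unknown IQ but < 9 always
    assert answer_q3a(worked_records["baribeau2021"]) is A.no  # mild ID, < 11 always
    # unknown functioning with ages past 11 cannot be forced either way
    r = make_record(first_age=12.0, length=4.0)
    assert answer_q3a(r) is A.cant_tell
    # mild ID at exactly half the waves >= 11: "at half or more" is feasible
    r2 = make_record(
        first_age=9.0, length=4.0, n_waves=2,
        functioning=IntellectualFunctioning(mean_iq=60.0),
    )
    assert answer_q3a(r2) is A.yes


def test_q3b(worked_records):
    assert answer_q3b(worked_records["baribeau2021"]) is A.no
    assert answer_q3b(make_record(child_rated=True,
                                  informants=frozenset({I.parent, I.child}))) is A.yes
    assert answer_q3b(make_record(informants=frozenset(),
                                  informants_missing=True)) is A.cant_tell


# --------------------------------------------------------------------------
# Composition

EXPECTED_RATINGS = {
    "alsem2013": (R.low, R.low, R.low, R.high),
    "anderson2011": (R.high, R.high, R.low, R.low),
    "auerbach2008": (R.high, R.high, R.high, R.high),
    "baribeau2021": (R.low, R.high, R.low, R.high),
}
EXPECTED_OVERALL = {
    "alsem2013": R.low,
    "anderson2011": R.unclear,
    "auerbach2008": R.high,
    "baribeau2021": R.unclear,
}


@pytest.mark.parametrize("study_id", sorted(EXPECTED_RATINGS))
def test_worked_examples_reproduce_published_ratings(worked_records, study_id):
    a = assess_study(worked_records[study_id])
    assert a.ratings == EXPECTED_RATINGS[study_id]
    assert a.overall is EXPECTED_OVERALL[study_id]
    assert aggregate_overall(a.ratings) is a.overall
    for d in a.domains:
        assert d.rationale, f"domain {d.domain_id} has no rationale"
        assert set(d.answers)  # every sub-question answered


def test_assess_study_is_deterministic(worked_records):
    r = worked_records["anderson2011"]
    a1, a2 = assess_study(r), assess_study(r)
    assert a1 == a2


def test_multi_group_functioning_weighting():
    """The n-weighted majority functioning category drives feasibility."""
    big_no_id = StudyGroup(diagnosis_label="a", n=400, first_wave_mean_age=10.0,
                           followup_length=4.0, n_waves=3,
                           functioning=IntellectualFunctioning(mean_iq=100.0))
    small_severe = StudyGroup(diagnosis_label="b", n=20, first_wave_mean_age=10.0,
                              followup_length=4.0, n_waves=3,
                              functioning=IntellectualFunctioning(mean_iq=40.0))
    assert answer_q3a(make_record(groups=(big_no_id, small_severe))) is A.yes
    assert answer_q3a(make_record(groups=(small_severe,))) is A.no
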