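"""The four-domain risk-of-bias rating engine.

Each domain is a small decision table over three-valued sub-question answers:

1. Conceptual overlap between outcome items and the diagnostic criteria that
   define the study group (1a: overlaps found? 1b: all addressed?).
2. Reliance on a single informant type for school-age children (2a/2b:
   how many and which informants; 2c: under six at every wave?).
3. Unwarranted omission of the child's own perspective (3a: was self-report
   feasible given age and intellectual functioning? 3b: was anything
   child-rated?).
4. Instruments neither designed for nor adapted to children with NDD
   (4a/4b per instrument).

The overall judgement aggregates the four domain ratings by strict
plurality; 2-2 ties between high and low, and two-definite/two-unclear
splits, resolve to unclear.

Everything here is a pure function of ``(StudyRecord, RubricThresholds)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .types import (
    Answer3,
    FunctioningCategory,
    InformantType,
    Instrument,
    RiskLevel,
    RubricThresholds,
    StudyGroup,
    StudyRecord,
    _SEVERITY_RANK,
    DEFAULT_THRESHOLDS,
)

__all__ = [
    "DomainAssessment",
    "StudyAssessment",
    "answer_q1a",
    "answer_q1b",
    "rate_finding",
    "rate_domain1",
    "wave_mean_ages",
    "answer_q2c",
    "rate_domain2",
    "answer_q3a",
    "answer_q3b",
    "rate_domain3",
    "rate_domain4",
    "aggregate_overall",
    "assess_study",
]


@dataclass(frozen=True)
class DomainAssessment:
    """One domain's rating plus the sub-question answers behind it."""

    domain_id: int
    rating: RiskLevel
    answers: dict[str, object] = field(default_factory=dict)
    rationale: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class StudyAssessment:
    study_id: str
    domains: tuple[DomainAssessment, ...]
    overall: RiskLevel

    def domain(self, domain_id: int) -> DomainAssessment:
        return self.domains[domain_id - 1]

    @property
    def ratings(self) -> tuple[RiskLevel, ...]:
        return tuple(d.rating for d in self.domains)


# --------------------------------------------------------------------------
# Domain 1 — conceptual overlap

def answer_q1a(record: StudyRecord) -> Answer3:
    """Were the studied mental-health problems separated from the core
    characteristics of the disability?  (yes = no overlaps identified)"""
    if record.overlaps:
        return Answer3.no
    if not (record.items_available and record.criteria_available):
        return Answer3.cant_tell
    return Answer3.yes


def answer_q1b(record: StudyRecord) -> Answer3:
    """Were the conceptual overlaps addressed in the article?

    Per-finding statuses roll up worst-case: any unaddressed finding makes
    the answer no; all addressed makes it yes; otherwise can't tell.  With no
    findings the question is vacuous: it inherits yes only when the
    comparison could actually be made (items and criteria available),
    otherwise can't tell, so an unassessable study stays unclear.
    """
    if not record.overlaps:
        return answer_q1a(record) if answer_q1a(record) is Answer3.yes else Answer3.cant_tell
    statuses = {f.addressed for f in record.overlaps}
    if Answer3.no in statuses:
        return Answer3.no
    if statuses == {Answer3.yes}:
        return Answer3.yes
    return Answer3.cant_tell


def rate_finding(addressed: Answer3) -> RiskLevel:
    """Finding-level risk: an addressed overlap is low risk, an unaddressed
    one high, an incompletely addressed one unclear."""
    return {
        Answer3.yes: RiskLevel.low,
        Answer3.no: RiskLevel.high,
        Answer3.cant_tell: RiskLevel.unclear,
    }[addressed]


def rate_domain1(q1a: Answer3, q1b: Answer3) -> RiskLevel:
    """Low = no overlaps or all addressed; high = at least one overlap that
    was not mentioned; unclear otherwise."""
    if q1a is Answer3.yes or q1b is Answer3.yes:
        return RiskLevel.low
    if q1a is Answer3.no and q1b is Answer3.no:
        return RiskLevel.high
    return RiskLevel.unclear


# --------------------------------------------------------------------------
# Domain 2 — informants

def wave_mean_ages(group: StudyGroup) -> tuple[float, ...] | None:
    """Mean participant age at each wave, in years.

    Explicit ages win; otherwise waves are assumed equally spaced between the
    first-wave age and first-wave age + follow-up length (the convention used
    when articles report only the span).  Returns ``None`` when the ages
    cannot be established (drives can't-tell answers downstream).
    """
    if group.wave_mean_ages is not None:
        return group.wave_mean_ages
    first = group.first_wave_mean_age
    if first is None:
        return None
    if group.n_waves == 1:
        return (first,)
    if group.followup_length is None or group.n_waves is None:
        return None
    k = group.n_waves
    step = group.followup_length / (k - 1)
    return tuple(first + i * step for i in range(k))


def answer_q2c(record: StudyRecord, t: RubricThresholds = DEFAULT_THRESHOLDS) -> Answer3:
    """Were participants under ``school_age`` at every data-collection point?

    A single established wave at or above the cut-off forces no even when
    other waves are unknown.
    """
    any_unknown = False
    all_known_under = True
    for g in record.groups:
        ages = wave_mean_ages(g)
        if ages is None:
            any_unknown = True
            continue
        if any(a >= t.school_age for a in ages):
            return Answer3.no
        all_known_under = all_known_under and all(a < t.school_age for a in ages)
    if any_unknown:
        return Answer3.cant_tell
    return Answer3.yes if all_known_under else Answer3.no


def _max_distinct_informants(record: StudyRecord) -> tuple[int, bool]:
    """(max distinct informant types over outcomes, any outcome missing info)."""
    missing = any(o.informants_missing for o in record.outcomes)
    best = max((len(o.informants) for o in record.outcomes), default=0)
    return best, missing


def rate_domain2(record: StudyRecord, t: RubricThresholds = DEFAULT_THRESHOLDS) -> RiskLevel:
    """Low = >= 2 informant types on some outcome, or all waves under six;
    high = a single informant with school-age children; unclear when the
    informants or the ages cannot be established."""
    n_informants, informants_missing = _max_distinct_informants(record)
    if n_informants >= t.min_informants_school_age:
        return RiskLevel.low
    q2c = answer_q2c(record, t)
    if q2c is Answer3.yes:
        return RiskLevel.low
    if informants_missing or q2c is Answer3.cant_tell:
        return RiskLevel.unclear
    return RiskLevel.high


# --------------------------------------------------------------------------
# Domain 3 — the child's perspective

def _majority_functioning(record: StudyRecord) -> FunctioningCategory:
    """n-weighted majority functioning category across groups; ties break
    toward the more severe category (the conservative reading)."""
    weights: Counter[FunctioningCategory] = Counter()
    for g in record.groups:
        weights[g.functioning.category] += g.n
    return max(weights, key=lambda c: (weights[c], _SEVERITY_RANK[c]))


def _weighted_fraction_at_least(record: StudyRecord, threshold: float) -> float | None:
    """n-weighted mean, over groups, of the fraction of waves with mean age
    >= threshold; None when any group's ages are unknown."""
    num = 0.0
    den = 0
    for g in record.groups:
        ages = wave_mean_ages(g)
        if ages is None:
            return None
        num += g.n * sum(a >= threshold for a in ages) / len(ages)
        den += g.n
    return num / den


def answer_q3a(record: StudyRecord, t: RubricThresholds = DEFAULT_THRESHOLDS) -> Answer3:
    """Was self-report theoretically plausible at a majority of waves?

    Feasibility requires mean age >= 9 (no ID) or >= 11 (mild ID) at half or
    more of the waves; moderate/severe ID is never considered feasible.  With
    unknown functioning the answer can still be forced to no by age alone
    (all-but-a-minority of waves under the lowest threshold); otherwise
    missing functioning or age data yields can't tell.
    """
    cat = _majority_functioning(record)
    if cat is FunctioningCategory.moderate_severe_id:
        return Answer3.no
    frac9 = _weighted_fraction_at_least(record, t.self_report_age_no_id)
    if frac9 is None:
        return Answer3.cant_tell
    if cat is FunctioningCategory.no_id:
        return Answer3.yes if frac9 >= t.wave_fraction_for_feasible else Answer3.no
    frac11 = _weighted_fraction_at_least(record, t.self_report_age_mild_id)
    assert frac11 is not None
    if cat is FunctioningCategory.mild_id:
        return Answer3.yes if frac11 >= t.wave_fraction_for_feasible else Answer3.no
    # Functioning unknown: below the lowest threshold at most waves the
    # answer is no regardless of IQ; otherwise it depends on the unknown.
    if frac9 < t.wave_fraction_for_feasible:
        return Answer3.no
    return Answer3.cant_tell


def answer_q3b(record: StudyRecord) -> Answer3:
    """Did the children rate their own mental health on any outcome?"""
    if any(o.child_rated for o in record.outcomes):
        return Answer3.yes
    if any(o.informants_missing for o in record.outcomes):
        return Answer3.cant_tell
    return Answer3.no


def rate_domain3(q3a: Answer3, q3b: Answer3) -> RiskLevel:
    """High = child report feasible but absent; low = child report present or
    infeasible; unclear when feasibility or presence cannot be told."""
    if q3a is Answer3.no or q3b is Answer3.yes:
        return RiskLevel.low
    if q3a is Answer3.yes and q3b is Answer3.no:
        return RiskLevel.high
    return RiskLevel.unclear


# --------------------------------------------------------------------------
# Domain 4 — instrument suitability

def _instrument_passes(i: Instrument) -> bool:
    return i.designed_for_ndd is Answer3.yes or i.adapted_for_ndd is Answer3.yes


def rate_domain4(instruments: list[Instrument] | tuple[Instrument, ...]) -> RiskLevel:
    """Low = every instrument designed for or adapted to the population;
    high = none is (and the information was extractable); unclear when only
    some are or when an instrument's status is wholly unextractable.

    Only instruments actually used for mental-health outcomes should be
    passed in (see :meth:`StudyRecord.used_instruments`).
    """
    if not instruments:
        raise ValueError("no instruments to rate (none used by an outcome)")
    passes = [_instrument_passes(i) for i in instruments]
    if all(passes):
        return RiskLevel.low
    wholly_unknown = any(
        i.designed_for_ndd is Answer3.cant_tell and i.adapted_for_ndd is Answer3.cant_tell
        for i in instruments
    )
    if not any(passes) and not wholly_unknown:
        return RiskLevel.high
    return RiskLevel.unclear


# --------------------------------------------------------------------------
# Overall aggregation

def aggregate_overall(ratings: list[RiskLevel] | tuple[RiskLevel, ...]) -> RiskLevel:
    """Aggregate the four domain ratings into an overall judgement.

    A level assigned strictly more often than each other level wins; every
    tie (high/low 2-2, definite/unclear 2-2, or any other non-strict maximum)
    resolves to unclear.  Total over all 81 rating vectors and
    permutation-invariant.  Note the aggregation is deliberately not
    monotone: (high, high, low, unclear) -> high but softening the low to
    unclear gives (high, high, unclear, unclear) -> unclear.
    """
    ratings = tuple(ratings)
    if len(ratings) != 4:
        raise ValueError("exactly four domain ratings required")
    if RiskLevel.no_information in ratings:
        raise ValueError("no_information is not a rateable level")
    counts = Counter(ratings)
    top_count = max(counts.values())
    leaders = [lvl for lvl, c in counts.items() if c == top_count]
    if len(leaders) == 1:
        return leaders[0]
    return RiskLevel.unclear


# --------------------------------------------------------------------------
# Composition

def _fmt_answers(types: set[InformantType]) -> str:
    return ";".join(sorted(t.value for t in types)) or "unknown"


def assess_study(
    record: StudyRecord, t: RubricThresholds = DEFAULT_THRESHOLDS
) -> StudyAssessment:
    """Run all four domains and the overall aggregation on one study."""
    # Domain 1
    q1a = answer_q1a(record)
    q1b = answer_q1b(record)
    d1 = rate_domain1(q1a, q1b)
    r1 = [f"1a={q1a.value}: {len(record.overlaps)} overlap finding(s)"]
    if record.overlaps:
        finding_levels = [rate_finding(f.addressed).value for f in record.overlaps]
        r1.append(f"1b={q1b.value}: finding-level ratings {finding_levels}")
    elif not (record.items_available and record.criteria_available):
        r1.append("items and/or diagnostic criteria unavailable for comparison")
    else:
        r1.append("1b vacuous: nothing to address")

    # Domain 2
    n_informants, informants_missing = _max_distinct_informants(record)
    informant_types = {it for o in record.outcomes for it in o.informants}
    q2c = answer_q2c(record, t)
    d2 = rate_domain2(record, t)
    r2 = [
        f"2a: max {n_informants} distinct informant type(s) on one outcome"
        + (" (some outcomes missing informant data)" if informants_missing else ""),
        f"2b: informants = {_fmt_answers(informant_types)}",
        f"2c={q2c.value}: under {t.school_age:g} y at all waves"
        if q2c is Answer3.yes
        else f"2c={q2c.value}",
    ]

    # Domain 3
    q3a = answer_q3a(record, t)
    q3b = answer_q3b(record)
    d3 = rate_domain3(q3a, q3b)
    cat = _majority_functioning(record)
    r3 = [
        f"3a={q3a.value}: majority functioning {cat.value} (n-weighted)",
        f"3b={q3b.value}: child-rated outcome "
        + ("present" if q3b is Answer3.yes else "absent or unknown"),
    ]

    # Domain 4
    used = record.used_instruments()
    try:
        d4 = rate_domain4(used)
    except ValueError as e:
        raise ValueError(f"{record.study_id}: {e}") from None
    designed = {i.designed_for_ndd for i in used}
    adapted = {i.adapted_for_ndd for i in used}
    q4a = (
        Answer3.yes
        if Answer3.yes in designed
        else (Answer3.no if designed == {Answer3.no} else Answer3.cant_tell)
    )
    q4b = (
        Answer3.yes
        if Answer3.yes in adapted
        else (Answer3.no if adapted == {Answer3.no} else Answer3.cant_tell)
    )
    n_pass = sum(_instrument_passes(i) for i in used)
    r4 = [f"4a={q4a.value}, 4b={q4b.value}: {n_pass}/{len(used)} instrument(s) designed for or adapted to NDD"]

    domains = (
        DomainAssessment(1, d1, {"1a": q1a, "1b": q1b}, r1),
        DomainAssessment(
            2,
            d2,
            {"2a": n_informants, "2b": _fmt_answers(informant_types), "2c": q2c},
            r2,
        ),
        DomainAssessment(3, d3, {"3a": q3a, "3b": q3b}, r3),
        DomainAssessment(4, d4, {"4a": q4a, "4b": q4b}, r4),
    )
    overall = aggregate_overall([d.rating for d in domains])
    return StudyAssessment(record.study_id, domains, overall)
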