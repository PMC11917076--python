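"""Descriptive and distributional summaries over an assessed cohort.

Implements the counting conventions used when describing a review cohort:

* A *counted scale score* is an outcome counted at the most general level
  reported for its instrument within a study — total score if any, else
  broad-band scores, else specific subscales.
* Instruments are deduplicated cohort-wide by case-insensitive name.
* Percentages are rounded half-up to one decimal at presentation; the raw
  fractions are what the rounding is applied to, never re-rounded values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .rubric import StudyAssessment, answer_q2c, answer_q3a, answer_q3b, wave_mean_ages
from .types import (
    Answer3,
    RiskLevel,
    RubricThresholds,
    ScoreLevel,
    StudyRecord,
    DEFAULT_THRESHOLDS,
)

__all__ = [
    "CohortSummary",
    "count_scale_scores",
    "counted_outcome_labels",
    "summarize_cohort",
    "descriptives",
    "summarize_characteristics",
    "pct",
]

_LEVEL_ORDER = (ScoreLevel.total, ScoreLevel.broadband, ScoreLevel.subscale)


def pct(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to one decimal (0.0 when the denominator
    is zero)."""
    if denominator == 0:
        return 0.0
    raw = Decimal(numerator) / Decimal(denominator) * 100
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def counted_outcome_labels(record: StudyRecord) -> list[str]:
    """Labels of the outcomes that count as scale scores for this study.

    Per instrument: every total score counts; else every broad-band score;
    subscales only when the instrument reports neither.
    """
    by_instrument: dict[str, list] = {}
    for o in record.outcomes:
        by_instrument.setdefault(o.instrument_name.strip().lower(), []).append(o)
    labels = []
    for outcomes in by_instrument.values():
        for level in _LEVEL_ORDER:
            at_level = [o for o in outcomes if o.score_level is level]
            if at_level:
                labels.extend(o.score_label for o in at_level)
                break
    return labels


def count_scale_scores(record: StudyRecord) -> int:
    """Number of counted scale scores in one study."""
    return len(counted_outcome_labels(record))


@dataclass
class CohortSummary:
    """Distributional and descriptive statistics over assessed studies.

    Distribution values and ``pct_*`` fields are percentages (0–100), each
    rounded half-up to one decimal.
    """

    n_studies: int
    total_children: int
    n_scale_scores: int
    n_distinct_instruments: int
    domain_distribution: dict[int, dict[RiskLevel, float]]
    overall_distribution: dict[RiskLevel, float]
    pct_outcomes_with_overlap: float
    pct_studies_with_overlap: float
    pct_overlap_studies_unaddressed: float
    pct_multi_informant: float
    pct_single_informant_justified: float
    pct_child_missing: float
    pct_feasible_among_missing: float
    pct_instruments_designed_for_ndd: float
    counts: dict[str, int] = field(default_factory=dict)


def _distribution(ratings: list[RiskLevel], n: int) -> dict[RiskLevel, float]:
    return {
        level: pct(sum(r is level for r in ratings), n)
        for level in (RiskLevel.low, RiskLevel.unclear, RiskLevel.high, RiskLevel.no_information)
    }


def summarize_cohort(
    records: list[StudyRecord],
    assessments: list[StudyAssessment],
    t: RubricThresholds = DEFAULT_THRESHOLDS,
) -> CohortSummary:
    """Fill every :class:`CohortSummary` field from aligned records and
    assessments (matched by study_id; order-insensitive)."""
    if not records:
        raise ValueError("no studies to summarize")
    by_id = {a.study_id: a for a in assessments}
    record_ids = [r.study_id for r in records]
    if len(set(record_ids)) != len(record_ids):
        raise ValueError("duplicate study_id in records")
    missing = set(record_ids) ^ set(by_id)
    if missing:
        raise ValueError(f"records and assessments do not align: {sorted(missing)}")
    records = sorted(records, key=lambda r: r.study_id)
    assessments = [by_id[r.study_id] for r in records]

    n = len(records)
    total_children = sum(g.n for r in records for g in r.groups)
    n_scores = sum(count_scale_scores(r) for r in records)

    instruments: dict[str, bool] = {}
    for r in records:
        for i in r.used_instruments():
            key = i.name.strip().lower()
            instruments[key] = instruments.get(key, False) or (
                i.designed_for_ndd is Answer3.yes
            )

    # Overlap
    scores_with_overlap = 0
    for r in records:
        counted = set(counted_outcome_labels(r))
        hit = {f.outcome_ref for f in r.overlaps}
        scores_with_overlap += len(counted & hit)
    overlap_studies = [r for r in records if r.overlaps]
    unaddressed = sum(
        any(f.addressed is Answer3.no for f in r.overlaps) for r in overlap_studies
    )

    # Informants
    multi = sum(
        any(len(o.informants) >= t.min_informants_school_age for o in r.outcomes)
        for r in records
    )
    justified_single = sum(
        not any(len(o.informants) >= t.min_informants_school_age for o in r.outcomes)
        and answer_q2c(r, t) is Answer3.yes
        for r in records
    )

    # Child perspective
    child_missing = [r for r in records if answer_q3b(r) is Answer3.no]
    feasible_among_missing = sum(
        answer_q3a(r, t) is Answer3.yes for r in child_missing
    )

    domain_distribution = {
        d: _distribution([a.domain(d).rating for a in assessments], n)
        for d in (1, 2, 3, 4)
    }
    overall_distribution = _distribution([a.overall for a in assessments], n)

    return CohortSummary(
        n_studies=n,
        total_children=total_children,
        n_scale_scores=n_scores,
        n_distinct_instruments=len(instruments),
        domain_distribution=domain_distribution,
        overall_distribution=overall_distribution,
        pct_outcomes_with_overlap=pct(scores_with_overlap, n_scores),
        pct_studies_with_overlap=pct(len(overlap_studies), n),
        pct_overlap_studies_unaddressed=pct(unaddressed, len(overlap_studies)),
        pct_multi_informant=pct(multi, n),
        pct_single_informant_justified=pct(justified_single, n),
        pct_child_missing=pct(len(child_missing), n),
        pct_feasible_among_missing=pct(feasible_among_missing, len(child_missing)),
        pct_instruments_designed_for_ndd=pct(
            sum(instruments.values()), len(instruments)
        ),
        counts={
            "studies_with_overlap": len(overlap_studies),
            "overlap_studies_unaddressed": unaddressed,
            "multi_informant_studies": multi,
            "child_missing_studies": len(child_missing),
            "feasible_among_missing": feasible_among_missing,
            "instruments_designed_for_ndd": sum(instruments.values()),
        },
    )


def summary_to_dict(summary: CohortSummary) -> dict:
    """JSON-ready mapping mirroring the CohortSummary field names."""
    out: dict = {}
    for name, value in vars(summary).items():
        if name == "domain_distribution":
            out[name] = {
                str(d): {lvl.value: v for lvl, v in dist.items()}
                for d, dist in value.items()
            }
        elif name == "overall_distribution":
            out[name] = {lvl.value: v for lvl, v in value.items()}
        else:
            out[name] = value
    return out


# --------------------------------------------------------------------------
# Descriptives

_CHARACTERISTIC_COLUMNS = [
    "study_id",
    "diagnosis_label",
    "first_wave_mean_age",
    "n",
    "percent_female",
    "followup_length",
    "n_waves",
    "last_wave_mean_age",
]


def descriptives(records: list[StudyRecord]) -> pd.DataFrame:
    """One row per (study, diagnosis group) with ages, sizes and follow-up.

    ``last_wave_mean_age`` is taken from explicit wave ages when present,
    otherwise first-wave age + follow-up length.
    """
    rows = []
    for r in records:
        for g in r.groups:
            ages = wave_mean_ages(g)
            last = ages[-1] if ages else None
            rows.append(
                {
                    "study_id": r.study_id,
                    "diagnosis_label": g.diagnosis_label,
                    "first_wave_mean_age": g.first_wave_mean_age
                    if g.first_wave_mean_age is not None
                    else (ages[0] if ages else None),
                    "n": g.n,
                    "percent_female": g.percent_female,
                    "followup_length": g.followup_length,
                    "n_waves": g.n_waves if g.n_waves is not None else (len(ages) if ages else None),
                    "last_wave_mean_age": last,
                }
            )
    return pd.DataFrame(rows, columns=_CHARACTERISTIC_COLUMNS)


def summarize_characteristics(table: pd.DataFrame) -> dict:
    """Cohort-level descriptives from a characteristics table.

    Means of waves and follow-up length are reported both over group rows
    and over studies (rows of one study averaged first); sources often leave
    the convention unstated, so both are exposed and neither is privileged.
    """
    per_study = table.groupby("study_id", sort=True)
    out = {
        "n_studies": int(per_study.ngroups),
        "n_group_rows": int(len(table)),
        "total_children": int(table["n"].sum()),
        "first_wave_age_min": float(table["first_wave_mean_age"].min()),
        "first_wave_age_max": float(table["first_wave_mean_age"].max()),
        "last_wave_age_min": float(table["last_wave_mean_age"].min()),
        "last_wave_age_max": float(table["last_wave_mean_age"].max()),
        "followup_min": float(table["followup_length"].min()),
        "followup_max": float(table["followup_length"].max()),
        "waves_min": int(table["n_waves"].min()),
        "waves_max": int(table["n_waves"].max()),
        "mean_waves_over_rows": float(table["n_waves"].mean()),
        "mean_waves_over_studies": float(per_study["n_waves"].mean().mean()),
        "mean_followup_over_rows": float(table["followup_length"].mean()),
        "mean_followup_over_studies": float(per_study["followup_length"].mean().mean()),
    }
    return out
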