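"""Typed records for risk-of-bias assessment of longitudinal NDD mental-health studies.

The unit of assessment is a *study*: one published longitudinal investigation
of mental-health problems in children with a neurodevelopmental disorder
(NDD).  A :class:`StudyRecord` holds everything the four-domain rubric needs:
the diagnosis groups (sizes, ages, intellectual functioning), the
mental-health outcome scores with their informants, the instruments those
scores come from, and any curated item/diagnostic-criterion overlap findings.

All ages and IQs are group means, matching how they are reported in study
characteristics tables; individual participants are never modelled.  Unknown
values are represented explicitly (``None`` / ``unknown``) and propagate to
"can't tell" / "unclear" judgements downstream — nothing is imputed silently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from pydantic import BaseModel, ConfigDict, Field, field_serializer, model_validator


class RiskLevel(str, enum.Enum):
    """Risk-of-bias judgement for a domain or a whole study.

    ``no_information`` exists for display (e.g. traffic-light plots of
    externally curated assessments); the rubric itself never produces it.
    """

    low = "low"
    unclear = "unclear"
    high = "high"
    no_information = "no_information"


class Answer3(str, enum.Enum):
    """Three-valued answer to a rubric sub-question."""

    yes = "yes"
    no = "no"
    cant_tell = "cant_tell"


class InformantType(str, enum.Enum):
    """Who reported on the child's mental health problems.

    ``parent`` covers mother, father and primary caregiver; ``observation``
    is direct observation by a professional or researcher.
    """

    parent = "parent"
    teacher = "teacher"
    child = "child"
    observation = "observation"


#: Raw informant labels accepted by :func:`normalize_informant`.
_INFORMANT_ALIASES = {
    "mother": InformantType.parent,
    "father": InformantType.parent,
    "primary caregiver": InformantType.parent,
    "primary_caregiver": InformantType.parent,
    "caregiver": InformantType.parent,
    "preschool teacher": InformantType.teacher,
    "schoolteacher": InformantType.teacher,
    "self": InformantType.child,
    "self-report": InformantType.child,
    "researcher": InformantType.observation,
    "observer": InformantType.observation,
}


def normalize_informant(label: str) -> InformantType:
    """Map a free-text informant label to its :class:`InformantType`."""
    key = label.strip().lower()
    if key in InformantType.__members__:
        return InformantType(key)
    try:
        return _INFORMANT_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognised informant label: {label!r}") from None


class FunctioningCategory(str, enum.Enum):
    no_id = "no_id"
    mild_id = "mild_id"
    moderate_severe_id = "moderate_severe_id"
    unknown = "unknown"


#: Severity rank used only for deterministic tie-breaking when combining
#: groups: ties resolve toward the more severe (more conservative) category.
_SEVERITY_RANK = {
    FunctioningCategory.unknown: 0,
    FunctioningCategory.no_id: 1,
    FunctioningCategory.mild_id: 2,
    FunctioningCategory.moderate_severe_id: 3,
}


class RubricThresholds(BaseModel):
    """All numeric cut-offs of the rubric, configurable but defaulting to the
    published values.

    school_age
        Age (years) from which a single informant is considered insufficient.
    self_report_age_no_id / self_report_age_mild_id
        Minimum mean age (years) at which self-report is deemed feasible for
        children without intellectual disability (ID) and with mild ID.
    iq_no_id_min / iq_mild_id_min
        Mean-IQ cut-offs: >= 70 no ID, [55, 70) mild ID, < 55 moderate/severe.
    min_informants_school_age
        Distinct informant types required for a low rating in domain 2.
    wave_fraction_for_feasible
        Fraction of waves that must meet the age threshold for self-report to
        count as feasible ("at half or more of the waves": >= comparison).
    """

    model_config = ConfigDict(frozen=True)

    school_age: float = Field(default=6.0, gt=0)
    self_report_age_no_id: float = Field(default=9.0, gt=0)
    self_report_age_mild_id: float = Field(default=11.0, gt=0)
    iq_no_id_min: float = Field(default=70.0, gt=0)
    iq_mild_id_min: float = Field(default=55.0, gt=0)
    min_informants_school_age: int = Field(default=2, gt=0)
    wave_fraction_for_feasible: float = Field(default=0.5, gt=0)

    @model_validator(mode="after")
    def _check_iq_order(self) -> "RubricThresholds":
        if not self.iq_mild_id_min < self.iq_no_id_min:
            raise ValueError("iq_mild_id_min must be below iq_no_id_min")
        return self

    def classify_iq(self, mean_iq: float) -> FunctioningCategory:
        """Half-open IQ bands: [70, inf) no ID, [55, 70) mild, (-inf, 55) mod/severe."""
        if mean_iq >= self.iq_no_id_min:
            return FunctioningCategory.no_id
        if mean_iq >= self.iq_mild_id_min:
            return FunctioningCategory.mild_id
        return FunctioningCategory.moderate_severe_id


DEFAULT_THRESHOLDS = RubricThresholds()


class IntellectualFunctioning(BaseModel):
    """Group-level intellectual functioning: a category, optionally backed by
    a mean IQ (which must agree with the category under the default bands)."""

    model_config = ConfigDict(frozen=True)

    category: FunctioningCategory = FunctioningCategory.unknown
    mean_iq: float | None = None

    @model_validator(mode="after")
    def _check_consistency(self) -> "IntellectualFunctioning":
        if self.mean_iq is not None:
            expected = DEFAULT_THRESHOLDS.classify_iq(self.mean_iq)
            if self.category is FunctioningCategory.unknown:
                object.__setattr__(self, "category", expected)
            elif self.category is not expected:
                raise ValueError(
                    f"mean_iq {self.mean_iq} implies {expected.value}, "
                    f"not {self.category.value}"
                )
        return self

    @classmethod
    def from_iq(cls, mean_iq: float) -> "IntellectualFunctioning":
        return cls(mean_iq=mean_iq)


class StudyGroup(BaseModel):
    """One diagnosis group within a study (a row of a characteristics table)."""

    model_config = ConfigDict(frozen=True)

    diagnosis_label: str
    n: int = Field(gt=0, description="number of children")
    percent_female: float | None = Field(default=None, ge=0, le=100)
    first_wave_mean_age: float | None = Field(default=None, ge=0)
    followup_length: float | None = Field(default=None, ge=0)
    n_waves: int | None = Field(default=None, ge=1)
    wave_mean_ages: tuple[float, ...] | None = None
    functioning: IntellectualFunctioning = IntellectualFunctioning()
    low_confidence_fields: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check_waves(self) -> "StudyGroup":
        ages = self.wave_mean_ages
        if ages is not None:
            if self.n_waves is not None and len(ages) != self.n_waves:
                raise ValueError("wave_mean_ages length must equal n_waves")
            if any(b < a for a, b in zip(ages, ages[1:])):
                raise ValueError("wave_mean_ages must be non-decreasing")
        return self


class ScoreLevel(str, enum.Enum):
    total = "total"
    broadband = "broadband"
    subscale = "subscale"


class OutcomeMeasure(BaseModel):
    """One reported mental-health score (instrument x scale level x label)."""

    model_config = ConfigDict(frozen=True)

    instrument_name: str
    score_label: str
    score_level: ScoreLevel
    construct_label: str = Field(
        default="", description="mental-health construct measured"
    )
    informants: frozenset[InformantType] = frozenset()
    child_rated: bool = False
    informants_missing: bool = False

    @model_validator(mode="after")
    def _check_child(self) -> "OutcomeMeasure":
        if not self.informants_missing:
            if self.child_rated != (InformantType.child in self.informants):
                raise ValueError(
                    "child_rated must be true exactly when 'child' is an informant"
                )
        if self.informants_missing and self.informants:
            raise ValueError("informants_missing requires an empty informant set")
        return self

    @field_serializer("informants")
    def _ser_informants(self, v: frozenset[InformantType]) -> list[str]:
        # sorted so serialization is byte-stable across processes
        return sorted(i.value for i in v)


class Instrument(BaseModel):
    """Instrument metadata for domain 4: was it designed for, or adapted to,
    children with NDD?"""

    model_config = ConfigDict(frozen=True)

    name: str = Field(min_length=1)
    designed_for_ndd: Answer3 = Answer3.cant_tell
    adapted_for_ndd: Answer3 = Answer3.cant_tell
    adaptation_note: str | None = None

    @model_validator(mode="after")
    def _check_note(self) -> "Instrument":
        if self.adapted_for_ndd is Answer3.yes and not self.adaptation_note:
            raise ValueError("adaptation_note required when adapted_for_ndd is yes")
        return self


class MatchCode(str, enum.Enum):
    """How an item and a diagnostic criterion overlap: identical wording,
    synonymous wording, or one a more concrete example of the other."""

    verbatim = "verbatim"
    synonym = "synonym"
    concretisation = "concretisation"


class OverlapFinding(BaseModel):
    """A curated item/diagnostic-criterion overlap within one outcome."""

    model_config = ConfigDict(frozen=True)

    outcome_ref: str = Field(description="score_label of the affected outcome")
    item_text: str = Field(min_length=1)
    criterion_text: str = Field(min_length=1)
    criterion_code: str = ""
    match_code: MatchCode = MatchCode.verbatim
    addressed: Answer3 = Answer3.no


class StudyRecord(BaseModel):
    """Everything extracted from one included study."""

    model_config = ConfigDict(frozen=True)

    study_id: str = Field(min_length=1)
    citation: str = ""
    groups: tuple[StudyGroup, ...] = Field(min_length=1)
    outcomes: tuple[OutcomeMeasure, ...] = Field(min_length=1)
    instruments: tuple[Instrument, ...] = ()
    overlaps: tuple[OverlapFinding, ...] = ()
    items_available: bool = True
    criteria_available: bool = True

    @model_validator(mode="after")
    def _check_refs(self) -> "StudyRecord":
        known = {i.name for i in self.instruments}
        for o in self.outcomes:
            if o.instrument_name not in known:
                raise ValueError(
                    f"outcome {o.score_label!r} uses instrument "
                    f"{o.instrument_name!r} not listed in instruments"
                )
        labels = {o.score_label for o in self.outcomes}
        for f in self.overlaps:
            if f.outcome_ref not in labels:
                raise ValueError(
                    f"overlap finding references unknown outcome {f.outcome_ref!r}"
                )
        return self

    def outcome_by_label(self, label: str) -> OutcomeMeasure:
        for o in self.outcomes:
            if o.score_label == label:
                return o
        raise KeyError(label)

    def used_instruments(self) -> tuple[Instrument, ...]:
        """Instruments actually used by a mental-health outcome."""
        used = {o.instrument_name for o in self.outcomes}
        return tuple(i for i in self.instruments if i.name in used)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    study_id: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


# Eligibility floor for inclusion: at least three waves spanning two or more
# years.  Deviations are warnings, not errors — curators may deliberately
# keep borderline studies.
MIN_WAVES = 3
MIN_FOLLOWUP_YEARS = 2.0


def validate_study(record: StudyRecord) -> ValidationReport:
    """Check a parsed record against the schema invariants and eligibility rules.

    Structural invariants (references, positivity, IQ/category consistency)
    are enforced at construction by pydantic; this adds cross-field checks
    that are representable but suspect, as errors, and eligibility deviations
    as warnings.  Deterministic and idempotent.
    """
    report = ValidationReport()

    def err(msg: str) -> None:
        report.issues.append(ValidationIssue("error", record.study_id, msg))

    def warn(msg: str) -> None:
        report.issues.append(ValidationIssue("warning", record.study_id, msg))

    for g in record.groups:
        label = g.diagnosis_label or "<group>"
        if g.n_waves is not None and g.n_waves < MIN_WAVES:
            warn(
                f"group {label!r}: {g.n_waves} waves is below the "
                f"{MIN_WAVES}-wave eligibility rule"
            )
        if g.followup_length is not None and g.followup_length < MIN_FOLLOWUP_YEARS:
            warn(
                f"group {label!r}: follow-up {g.followup_length} y is below "
                f"the {MIN_FOLLOWUP_YEARS}-year eligibility rule"
            )
        if (
            g.wave_mean_ages is not None
            and g.first_wave_mean_age is not None
            and abs(g.wave_mean_ages[0] - g.first_wave_mean_age) > 1e-9
        ):
            err(
                f"group {label!r}: first wave_mean_age {g.wave_mean_ages[0]} "
                f"disagrees with first_wave_mean_age {g.first_wave_mean_age}"
            )
    for o in record.outcomes:
        if not o.informants and not o.informants_missing:
            err(
                f"outcome {o.score_label!r}: empty informant set must be "
                "flagged informants_missing"
            )
    return report
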