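"""Readers and writers for the cohort schema, plus the bundled fixtures.

JSON is the canonical interchange format: a top-level object with
``schema_version`` and ``studies`` (a list of study records).  A JSON-Schema
document for it is available from :func:`cohort_json_schema`.  CSV export of
assessments is provided for spreadsheet curation; list-valued cells use
``;`` separators.  All files are UTF-8 with ``\\n`` newlines.

Bundled fixtures
----------------
``worked_examples``
    Four fully extracted studies (alsem2013, anderson2011, auerbach2008,
    baribeau2021) carrying every field needed to reproduce their published
    domain ratings.  Fixtures are read-only; copy before mutating.
``table3_characteristics``
    The 63 diagnosis-group rows of the full review's study-characteristics
    table (descriptives only — no outcome or instrument extraction), as a
    DataFrame.  Cells whose typography was ambiguous in the source are
    listed in the ``low_confidence`` column so descriptive checks can
    exclude them.
``full_review``
    Placeholder for the complete 49-study extraction (deposited at
    https://osf.io/hjrqc/).  Not bundled; loading raises until a
    transcription is installed at the reported path.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .rubric import StudyAssessment
from .types import StudyRecord

__all__ = [
    "SCHEMA_VERSION",
    "CohortFile",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "cohort_json_schema",
    "load_fixture",
    "fixture_path",
    "assessments_to_frame",
    "write_assessments_csv",
]

SCHEMA_VERSION = "1.0"
_SUPPORTED_VERSIONS = {"1.0"}


class CohortFormatError(ValueError):
    """A cohort file failed to parse or validate."""


class CohortFile(BaseModel):
    model_config = ConfigDict(frozen=True)

    schema_version: str = SCHEMA_VERSION
    studies: tuple[StudyRecord, ...] = Field(default=())

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]


def cohort_json_schema() -> dict:
    """JSON-Schema document for the cohort file format."""
    return CohortFile.model_json_schema()


def _study_context(err: ValidationError, payload: dict) -> str:
    """Best-effort study_id context for a validation error."""
    for e in err.errors():
        loc = e.get("loc", ())
        if len(loc) >= 2 and loc[0] == "studies" and isinstance(loc[1], int):
            try:
                sid = payload["studies"][loc[1]].get("study_id", f"#{loc[1]}")
            except Exception:
                sid = f"#{loc[1]}"
            field = ".".join(str(x) for x in loc[2:]) or "<record>"
            return f"study {sid!r}, field {field}: {e['msg']}"
    return str(err)


def read_cohort(path: str | Path) -> CohortFile:
    """Read and validate a cohort JSON file.

    Raises :class:`CohortFormatError` naming the offending study and field
    for unknown schema versions, malformed enum values, or duplicate ids.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise CohortFormatError(f"{path}: not valid JSON: {e}") from None
    if not isinstance(payload, dict):
        raise CohortFormatError(f"{path}: top level must be an object")
    version = payload.get("schema_version")
    if version not in _SUPPORTED_VERSIONS:
        raise CohortFormatError(
            f"{path}: unknown schema_version {version!r} "
            f"(supported: {sorted(_SUPPORTED_VERSIONS)})"
        )
    try:
        cohort = CohortFile.model_validate(payload)
    except ValidationError as e:
        raise CohortFormatError(f"{path}: {_study_context(e, payload)}") from None
    ids = cohort.study_ids
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise CohortFormatError(f"{path}: duplicate study_id {dupes}")
    return cohort


def cohort_to_json(cohort: CohortFile) -> str:
    """Canonical serialization: stable field order, 2-space indent, trailing
    newline.  Identical cohorts serialize byte-identically."""
    return (
        json.dumps(cohort.model_dump(mode="json"), indent=2, ensure_ascii=False)
        + "\n"
    )


def write_cohort(cohort: CohortFile | list[StudyRecord], path: str | Path) -> None:
    if not isinstance(cohort, CohortFile):
        cohort = CohortFile(studies=tuple(cohort))
    Path(path).write_text(cohort_to_json(cohort), encoding="utf-8", newline="\n")


# --------------------------------------------------------------------------
# Fixtures

_FIXTURES = {"worked_examples", "table3_characteristics", "full_review"}


def fixture_path(name: str) -> Path:
    ref = resources.files("ndd_rob") / "fixtures"
    with resources.as_file(ref) as p:
        return p / name


def load_fixture(name: str) -> CohortFile | pd.DataFrame:
    """Load a bundled fixture (see module docstring for the catalogue)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    if name == "worked_examples":
        return read_cohort(fixture_path("worked_examples.json"))
    if name == "table3_characteristics":
        df = pd.read_csv(fixture_path("table3_characteristics.csv"))
        df["low_confidence"] = df["low_confidence"].fillna("")
        df["last_wave_mean_age"] = df["first_wave_mean_age"] + df["followup_length"]
        return df
    p = fixture_path("full_review.json")
    if not p.exists():
        raise FileNotFoundError(
            "the full 49-study extraction is not bundled; transcribe the "
            "deposited extraction (https://osf.io/hjrqc/) into the cohort "
            f"schema and install it at {p}"
        )
    return read_cohort(p)


# --------------------------------------------------------------------------
# Assessment CSV export

_ANSWER_COLUMNS = ["1a", "1b", "2a", "2b", "2c", "3a", "3b", "4a", "4b"]


def assessments_to_frame(assessments: list[StudyAssessment]) -> pd.DataFrame:
    """One row per study: study_id, d1..d4, overall, then one column per
    sub-question answer."""
    rows = []
    for a in assessments:
        row: dict[str, object] = {"study_id": a.study_id}
        for d in a.domains:
            row[f"d{d.domain_id}"] = d.rating.value
        row["overall"] = a.overall.value
        for d in a.domains:
            for q, v in d.answers.items():
                row[f"q{q}"] = getattr(v, "value", v)
        rows.append(row)
    cols = ["study_id", "d1", "d2", "d3", "d4", "overall"] + [
        f"q{c}" for c in _ANSWER_COLUMNS
    ]
    return pd.DataFrame(rows, columns=cols)


def write_assessments_csv(assessments: list[StudyAssessment], path: str | Path) -> None:
    assessments_to_frame(assessments).to_csv(path, index=False, lineterminator="\n")
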