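"""Summary figures and reports: stacked distribution bars, a per-study
traffic-light matrix, and a markdown assessment report.

Colours follow the conventional risk-of-bias palette: green low, yellow
unclear, red high, blue no-information.  SVG is the canonical output — with
a fixed hash salt and no date metadata, identical inputs render to
byte-identical files, so figures are diffable in tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .rubric import StudyAssessment
from .stats import CohortSummary, summary_to_dict
from .types import RiskLevel

__all__ = ["FigureSpec", "render_summary_bars", "render_traffic_light", "render_report"]

DEFAULT_COLORS = {
    RiskLevel.low: "#2e7d32",
    RiskLevel.unclear: "#f9a825",
    RiskLevel.high: "#c62828",
    RiskLevel.no_information: "#1565c0",
}

_LEVEL_ORDER = (RiskLevel.low, RiskLevel.unclear, RiskLevel.high, RiskLevel.no_information)
_GLYPH = {
    RiskLevel.low: "+",
    RiskLevel.unclear: "?",
    RiskLevel.high: "−",
    RiskLevel.no_information: "",
}


class OutputFormat(str, enum.Enum):
    svg = "svg"
    png = "png"


@dataclass(frozen=True)
class FigureSpec:
    kind: str = "summary_bars"  # or "traffic_light"
    color_map: dict[RiskLevel, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))
    output_format: OutputFormat = OutputFormat.svg

    def __post_init__(self) -> None:
        missing = [l for l in RiskLevel if l not in self.color_map]
        if missing:
            raise ValueError(f"color_map missing levels: {[m.value for m in missing]}")


def _deterministic_save(fig, path: Path, spec: FigureSpec) -> None:
    plt.rcParams["svg.hashsalt"] = "ndd-rob"
    fig.savefig(path, format=spec.output_format.value, metadata={"Date": None}
                if spec.output_format is OutputFormat.svg else None)
    plt.close(fig)


def render_summary_bars(
    summary: CohortSummary, spec: FigureSpec = FigureSpec(), path: str | Path = "summary.svg"
) -> Path:
    """One horizontal stacked bar per domain plus one for the overall rating,
    segment widths proportional to the percentage of studies at each level."""
    path = Path(path)
    rows = [(f"D{d}", summary.domain_distribution[d]) for d in (1, 2, 3, 4)]
    rows.append(("Overall", summary.overall_distribution))
    fig, ax = plt.subplots(figsize=(7, 2.6))
    ys = range(len(rows), 0, -1)
    for (label, dist), y in zip(rows, ys):
        left = 0.0
        for level in _LEVEL_ORDER:
            width = dist.get(level, 0.0)
            if width:
                ax.barh(y, width, left=left, color=spec.color_map[level],
                        edgecolor="white", height=0.7)
            left += width
    ax.set_yticks(list(ys), [r[0] for r in rows])
    ax.set_xlim(0, 100)
    ax.set_xlabel("% of studies")
    handles = [plt.Rectangle((0, 0), 1, 1, color=spec.color_map[l]) for l in _LEVEL_ORDER]
    ax.legend(handles, [l.value.replace("_", " ") for l in _LEVEL_ORDER],
              loc="upper center", bbox_to_anchor=(0.5, -0.35), ncol=4, frameon=False)
    fig.tight_layout()
    _deterministic_save(fig, path, spec)
    return path


def render_traffic_light(
    assessments: list[StudyAssessment],
    spec: FigureSpec = FigureSpec(),
    path: str | Path = "traffic.svg",
) -> Path:
    """Studies x (D1–D4, Overall) matrix of coloured judgements, sorted by
    study id for a deterministic layout."""
    if not assessments:
        raise ValueError("no assessments to plot")
    path = Path(path)
    assessments = sorted(assessments, key=lambda a: a.study_id)
    cols = ["D1", "D2", "D3", "D4", "Overall"]
    fig, ax = plt.subplots(figsize=(4.5, 0.45 * len(assessments) + 1.2))
    for row, a in enumerate(assessments):
        levels = list(a.ratings) + [a.overall]
        y = len(assessments) - 1 - row
        for x, level in enumerate(levels):
            ax.add_patch(plt.Circle((x, y), 0.36, color=spec.color_map[level]))
            ax.text(x, y, _GLYPH[level], ha="center", va="center",
                    color="white", fontsize=9)
    ax.set_xlim(-0.6, len(cols) - 0.4)
    ax.set_ylim(-0.6, len(assessments) - 0.4)
    ax.set_xticks(range(len(cols)), cols)
    ax.set_yticks(range(len(assessments)),
                  [a.study_id for a in reversed(assessments)])
    ax.set_aspect("equal")
    ax.tick_params(length=0)
    for side in ax.spines.values():
        side.set_visible(False)
    fig.tight_layout()
    _deterministic_save(fig, path, spec)
    return path


def render_report(
    assessments: list[StudyAssessment],
    summary: CohortSummary,
    path: str | Path = "report.md",
) -> Path:
    """Markdown report: per-study ratings with their rationale lines, then
    the cohort summary table."""
    path = Path(path)
    lines = ["# Risk-of-bias assessment report", ""]
    for a in sorted(assessments, key=lambda x: x.study_id):
        lines.append(f"## {a.study_id}")
        lines.append("")
        lines.append("| Domain | Rating | Rationale |")
        lines.append("|---|---|---|")
        for d in a.domains:
            if not d.rationale:
                raise ValueError(
                    f"{a.study_id} domain {d.domain_id}: empty rationale"
                )
            lines.append(
                f"| D{d.domain_id} | {d.rating.value} | {'; '.join(d.rationale)} |"
            )
        lines.append(f"| Overall | {a.overall.value} | plurality of domain ratings |")
        lines.append("")
    lines.append("## Cohort summary")
    lines.append("")
    lines.append("| Quantity | Value |")
    lines.append("|---|---|")
    for key, value in summary_to_dict(summary).items():
        if isinstance(value, dict):
            continue
        lines.append(f"| {key} | {value} |")
    for d, dist in summary.domain_distribution.items():
        pretty = ", ".join(f"{l.value} {v}%" for l, v in dist.items() if v)
        lines.append(f"| domain {d} distribution | {pretty} |")
    pretty = ", ".join(f"{l.value} {v}%" for l, v in summary.overall_distribution.items() if v)
    lines.append(f"| overall distribution | {pretty} |")
    lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8", newline="\n")
    return path
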