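"""Lexical screening aid for item/diagnostic-criterion overlap.

Instrument items are compared against the diagnostic criteria defining the
study population.  Two of the three overlap kinds have a lexical footprint
and are proposed automatically for human curation:

* ``verbatim`` — the texts share most of their content words;
* ``synonym``  — a curated synonym pair bridges them (e.g. *hyperactive* /
  *overactive*).

The third kind, *concretisation* (one text a more concrete example of the
other), is a semantic judgement and is deliberately left to the human
reviewer: pairs with no lexical signal yield ``None`` and should be flagged
for manual review.  Candidates are advisory only — the rubric engine
consumes curated :class:`~ndd_rob.types.OverlapFinding` records, never raw
candidates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .types import MatchCode

__all__ = [
    "OverlapCandidate",
    "normalize_text",
    "load_lexicon",
    "default_lexicon",
    "screen_pair",
    "screen_all",
    "DEFAULT_JACCARD_CUTOFF",
]

#: Verbatim cut-off on the Jaccard index of content-token sets.  Chosen to
#: favour recall: this is a screen, a human confirms every candidate.
DEFAULT_JACCARD_CUTOFF = 0.5

_STOPWORDS = frozenset(
    """a an the and or but of to in on with for at by from as is are was were
    be been being that this these those it its their his her they he she we
    you i do does did have has had than then when while what which who whom
    how where why can could would should may might will shall over under
    about into""".split()
)

# Light suffix stripping, applied only when it leaves a stem of >= 4
# characters so short words (fixed, using) survive intact.  First match wins.
_SUFFIX_RULES = (("ies", "y"), ("ing", ""), ("ed", ""), ("es", ""), ("s", ""))

_WORD_RE = re.compile(r"[a-z]+")


def _stem(token: str) -> str:
    for suffix, repl in _SUFFIX_RULES:
        if token.endswith(suffix):
            stem = token[: -len(suffix)] + repl
            if len(stem) >= 4:
                return stem
            break
    return token


def normalize_text(s: str) -> list[str]:
    """Case-fold, strip punctuation, drop stop words, lightly stem.

    >>> normalize_text("Fixed facial expression(s)")
    ['fixed', 'facial', 'expression']
    """
    tokens = _WORD_RE.findall(s.lower())
    # single letters are orthographic debris, e.g. the "(s)" plural marker
    return [_stem(t) for t in tokens if len(t) > 1 and t not in _STOPWORDS]


@dataclass(frozen=True)
class OverlapCandidate:
    """A proposed overlap between an item and a criterion, for human review."""

    item_text: str
    criterion_text: str
    match_code: MatchCode
    matched_tokens: tuple[str, ...]
    confidence: float


class SynonymLexicon:
    """Symmetric token-pair lexicon.  Transitive closure is deliberately not
    applied: each bridge must be curated explicitly."""

    def __init__(self, pairs: list[tuple[str, str]] | None = None):
        self._pairs: set[frozenset[str]] = set()
        for a, b in pairs or []:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        sa, sb = _stem(a.strip().lower()), _stem(b.strip().lower())
        if sa and sb and sa != sb:
            self._pairs.add(frozenset((sa, sb)))

    def bridges(self, tokens_a: set[str], tokens_b: set[str]) -> list[tuple[str, str]]:
        out = []
        for pair in self._pairs:
            x, y = sorted(pair)
            if (x in tokens_a and y in tokens_b) or (y in tokens_a and x in tokens_b):
                out.append((x, y))
        return sorted(out)

    def __len__(self) -> int:
        return len(self._pairs)


def load_lexicon(path: str | Path) -> SynonymLexicon:
    """Read a lexicon file: one pair per line, comma- or tab-separated;
    ``#`` starts a comment."""
    lex = SynonymLexicon()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p for p in re.split(r"[,\t]", line) if p.strip()]
        if len(parts) != 2:
            raise ValueError(f"lexicon line must contain exactly two terms: {line!r}")
        lex.add(parts[0], parts[1])
    return lex


def default_lexicon() -> SynonymLexicon:
    """The shipped starter lexicon."""
    ref = resources.files("ndd_rob") / "fixtures" / "lexicon.txt"
    with resources.as_file(ref) as p:
        return load_lexicon(p)


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def screen_pair(
    item_text: str,
    criterion_text: str,
    lexicon: SynonymLexicon | None = None,
    jaccard_cutoff: float = DEFAULT_JACCARD_CUTOFF,
) -> OverlapCandidate | None:
    """Propose a verbatim or synonym overlap candidate, or ``None``.

    Symmetric in its two texts.  Any non-empty text paired with itself is a
    verbatim candidate with confidence 1.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    ta = set(normalize_text(item_text))
    tb = set(normalize_text(criterion_text))
    j = _jaccard(ta, tb)
    if ta and ta == tb:
        j = 1.0
    if j >= jaccard_cutoff and ta & tb:
        return OverlapCandidate(
            item_text, criterion_text, MatchCode.verbatim, tuple(sorted(ta & tb)), j
        )
    bridges = lexicon.bridges(ta, tb)
    if bridges:
        matched = tuple(f"{x}~{y}" for x, y in bridges)
        # Monotone in the token-overlap fraction, floored for the bridge.
        return OverlapCandidate(
            item_text, criterion_text, MatchCode.synonym, matched, 0.25 + 0.75 * j
        )
    return None


def screen_all(
    items: list[str],
    criteria: list[str],
    lexicon: SynonymLexicon | None = None,
    jaccard_cutoff: float = DEFAULT_JACCARD_CUTOFF,
) -> list[OverlapCandidate]:
    """Screen the full item x criterion cross product, preserving order."""
    if lexicon is None:
        lexicon = default_lexicon()
    out = []
    for item in items:
        for crit in criteria:
            cand = screen_pair(item, crit, lexicon, jaccard_cutoff)
            if cand is not None:
                out.append(cand)
    return out
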