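"""Dictionary and regular-expression entity taggers.

The dictionary tagger emits leftmost-longest, non-overlapping, token-aligned
matches of gazetteer terms (TRIVIAL, FAMILY, ABBREVIATION).  The regex tagger
matches single-token morphological patterns (FORMULA, IDENTIFIER).  Both
operate on token *cores*, so trailing sentence punctuation never leaks into a
mention span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import Document, Mention, SECTIONS
from .text_processing import tokenize

__all__ = ["Dictionary", "RegexSet", "dict_tag", "regex_tag"]

#: classes matched case-insensitively by default; abbreviations are
#: case-bearing ("DNA" is not "dna")
CASE_INSENSITIVE_CLASSES = {"TRIVIAL", "FAMILY"}


def _read_term_file(path: str | Path) -> list[str]:
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.append(line)
    return terms


@dataclass(frozen=True)
class Dictionary:
    """A gazetteer for one entity class.

    Terms are stored as tuples of space-split words, normalised according to
    the class case policy.
    """

    entity_class: str
    terms: frozenset[tuple[str, ...]]
    case_sensitive: bool

    def __post_init__(self) -> None:
        if any(not t or any(not w for w in t) for t in self.terms):
            raise ValueError("dictionary contains an empty term")

    @property
    def max_len(self) -> int:
        return max((len(t) for t in self.terms), default=1)

    def normalize(self, word: str) -> str:
        return word if self.case_sensitive else word.lower()

    @classmethod
    def from_terms(
        cls, entity_class: str, terms: Iterable[str], case_sensitive: bool | None = None
    ) -> "Dictionary":
        if case_sensitive is None:
            case_sensitive = entity_class not in CASE_INSENSITIVE_CLASSES
        norm = frozenset(
            tuple(w if case_sensitive else w.lower() for w in term.split())
            for term in terms
            if term.strip()
        )
        return cls(entity_class, norm, case_sensitive)

    @classmethod
    def from_file(
        cls, entity_class: str, path: str | Path, case_sensitive: bool | None = None
    ) -> "Dictionary":
        return cls.from_terms(entity_class, _read_term_file(path), case_sensitive)

    def __contains__(self, term: str) -> bool:
        return tuple(self.normalize(w) for w in term.split()) in self.terms


@dataclass(frozen=True)
class RegexSet:
    """Ordered token-level patterns for one entity class.

    Patterns are applied with ``fullmatch`` against token cores; surfaces in
    ``stop_words`` are never tagged (suppresses English-word collisions such
    as lone "In" or "As" parsing as element symbols).
    """

    entity_class: str
    patterns: tuple[str, ...]
    stop_words: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_compiled", tuple(re.compile(p) for p in self.patterns)
        )

    def matches(self, core: str) -> bool:
        if core in self.stop_words:
            return False
        return any(p.fullmatch(core) for p in self._compiled)

    @classmethod
    def from_file(
        cls, entity_class: str, path: str | Path, stop_words: Iterable[str] = ()
    ) -> "RegexSet":
        return cls(entity_class, tuple(_read_term_file(path)), frozenset(stop_words))


def _leftmost_longest(cores: Sequence[str], dictionary: Dictionary) -> list[tuple[int, int]]:
    """Greedy scan: at each position take the longest term match, then jump
    past it; unmatched positions advance by one."""
    spans = []
    n = len(cores)
    i = 0
    while i < n:
        best = 0
        for j in range(min(n, i + dictionary.max_len), i, -1):
            if tuple(cores[i:j]) in dictionary.terms:
                best = j
                break
        if best:
            spans.append((i, best))
            i = best
        else:
            i += 1
    return spans


def _section_mentions(doc, section, spans, tokens, entity_class, tagger_id):
    text = doc.section_text(section)
    out = []
    for i, j in spans:
        start = tokens[i].start
        end = tokens[j - 1].core_end
        out.append(
            Mention(
                doc.doc_id,
                section,
                start,
                end,
                text[start:end],
                entity_class,
                confidence=1.0,
                tagger_id=tagger_id,
            )
        )
    return out


def dict_tag(doc: Document, dictionary: Dictionary) -> list[Mention]:
    """Longest, non-overlapping, token-boundary-aligned gazetteer matches in
    both sections, sorted by (section, start)."""
    mentions: list[Mention] = []
    for section in SECTIONS:
        seq = tokenize(doc.section_text(section), doc.doc_id, section)
        cores = [dictionary.normalize(t.core) for t in seq]
        spans = _leftmost_longest(cores, dictionary)
        mentions.extend(
            _section_mentions(
                doc, section, spans, seq.tokens, dictionary.entity_class,
                f"dict:{dictionary.entity_class}",
            )
        )
    return mentions


def regex_tag(doc: Document, patterns: RegexSet) -> list[Mention]:
    """Single-token pattern matches in both sections, sorted by
    (section, start)."""
    mentions: list[Mention] = []
    for section in SECTIONS:
        seq = tokenize(doc.section_text(section), doc.doc_id, section)
        spans = [(i, i + 1) for i, t in enumerate(seq) if t.core and patterns.matches(t.core)]
        mentions.extend(
            _section_mentions(
                doc, section, spans, seq.tokens, patterns.entity_class,
                f"regex:{patterns.entity_class}",
            )
        )
    return mentions
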