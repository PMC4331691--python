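"""Corpus, annotation, and prediction file I/O plus span <-> IOB conversion.

File dialects (all tab-separated, UTF-8):

* abstracts:    ``doc_id <TAB> title <TAB> abstract`` (one document per line)
* annotations:  ``doc_id <TAB> T|A <TAB> start <TAB> end <TAB> surface <TAB> class``
* CDI output:   ``doc_id <TAB> surface <TAB> rank <TAB> confidence``
* CEM output:   ``doc_id <TAB> section:start:end <TAB> rank <TAB> confidence``

Offsets are 0-based, end-exclusive character positions counted separately
within the title and within the abstract.  Parsed annotations are verified
against the document text: ``section_text[start:end] == surface`` always.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    AnnotationMismatchError,
    CorpusFormatError,
    InvalidIOBError,
    OverlapError,
)
from .text_processing import TokenSequence, tokenize

logger = logging.getLogger(__name__)

TITLE = "T"
ABSTRACT = "A"
SECTIONS = (TITLE, ABSTRACT)

#: the six nomenclature classes the taggers predict
ENTITY_CLASSES = (
    "SYSTEMATIC",
    "TRIVIAL",
    "FAMILY",
    "FORMULA",
    "ABBREVIATION",
    "IDENTIFIER",
)
#: classes accepted on input but never trained on or predicted
EXTRA_CLASSES = ("MULTIPLE", "NO_CLASS")
ALL_CLASSES = ENTITY_CLASSES + EXTRA_CLASSES

_CLASS_ALIASES = {"NO CLASS": "NO_CLASS", "ABBREVIATIONS": "ABBREVIATION"}


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusFormatError("empty doc_id")
        for name, text in (("title", self.title), ("abstract", self.abstract)):
            if "\t" in text or "\n" in text:
                raise CorpusFormatError(
                    f"{name} of document {self.doc_id!r} contains tab/newline"
                )

    def section_text(self, section: str) -> str:
        if section == TITLE:
            return self.title
        if section == ABSTRACT:
            return self.abstract
        raise ValueError(f"unknown section flag {section!r}")


@dataclass(frozen=True)
class Mention:
    """A classed entity span in one section of one document.

    ``confidence`` and ``tagger_id`` are pipeline bookkeeping and do not
    participate in equality.
    """

    doc_id: str
    section: str
    start: int
    end: int
    surface: str
    entity_class: str
    confidence: float = field(default=1.0, compare=False)
    tagger_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad offsets [{self.start}, {self.end}) in {self.doc_id}"
            )
        if self.entity_class not in ALL_CLASSES:
            raise CorpusFormatError(
                f"unknown entity class {self.entity_class!r} in {self.doc_id}"
            )

    def validate_against(self, doc: Document) -> None:
        text = doc.section_text(self.section)
        if self.end > len(text) or text[self.start : self.end] != self.surface:
            raise AnnotationMismatchError(
                f"{self.doc_id} {self.section}:{self.start}:{self.end}: "
                f"surface {self.surface!r} != text "
                f"{text[self.start:self.end]!r}"
            )

    @property
    def span_key(self) -> tuple[str, str, int, int]:
        return (self.doc_id, self.section, self.start, self.end)


# ---------------------------------------------------------------------------
# corpus files


def read_abstracts(path: str | Path) -> list[Document]:
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            doc_id, title, abstract = fields
            if doc_id in seen:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(Document(doc_id, title, abstract))
    return docs


def write_abstracts(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def read_annotations(path: str | Path, documents: Sequence[Document]) -> list[Mention]:
    by_id = {d.doc_id: d for d in documents}
    mentions: list[Mention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 6 fields, got {len(fields)}"
                )
            doc_id, section, start, end, surface, cls = fields
            if doc_id not in by_id:
                raise CorpusFormatError(f"{path}:{lineno}: unknown doc_id {doc_id!r}")
            if section not in SECTIONS:
                raise CorpusFormatError(
                    f"{path}:{lineno}: section flag must be T or A, got {section!r}"
                )
            cls = _CLASS_ALIASES.get(cls, cls)
            if cls not in ALL_CLASSES:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown class label {cls!r}"
                )
            try:
                m = Mention(doc_id, section, int(start), int(end), surface, cls)
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
            m.validate_against(by_id[doc_id])
            mentions.append(m)
    return mentions


def write_annotations(mentions: Iterable[Mention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                f"{m.doc_id}\t{m.section}\t{m.start}\t{m.end}\t"
                f"{m.surface}\t{m.entity_class}\n"
            )


# ---------------------------------------------------------------------------
# IOB conversion

O_LABEL = "O"


def joint_labels(classes: Sequence[str] = ENTITY_CLASSES) -> tuple[str, ...]:
    labels = [O_LABEL]
    for c in classes:
        labels.extend((f"B-{c}", f"I-{c}"))
    return tuple(labels)


def single_labels(entity_class: str) -> tuple[str, ...]:
    return (O_LABEL, f"B-{entity_class}", f"I-{entity_class}")


def check_iob(labels: Sequence[str]) -> None:
    """Raise :class:`InvalidIOBError` unless I-c only follows B-c or I-c."""
    prev = O_LABEL
    for i, lab in enumerate(labels):
        if lab.startswith("I-") and prev not in (f"B-{lab[2:]}", lab):
            raise InvalidIOBError(f"position {i}: {lab} after {prev}")
        prev = lab


def mentions_to_iob(tokens: TokenSequence, mentions: Sequence[Mention]) -> list[str]:
    """Project mention spans onto token labels.

    A mention whose boundaries fall strictly inside a token is expanded to
    the full token (a warning is logged); overlapping mentions are rejected.
    """
    ms = sorted(
        (m for m in mentions if m.section == tokens.section),
        key=lambda m: (m.start, m.end),
    )
    for a, b in zip(ms, ms[1:]):
        if b.start < a.end:
            raise OverlapError(
                f"overlapping mentions {a.span_key} / {b.span_key}; merge first"
            )
    labels = [O_LABEL] * len(tokens)
    for m in ms:
        idx = [
            i
            for i, t in enumerate(tokens)
            if t.start < m.end and t.end > m.start
        ]
        if not idx:
            continue
        first, last = tokens[idx[0]], tokens[idx[-1]]
        if first.start != m.start or last.end != m.end:
            logger.warning(
                "mention %s %r expanded to token boundaries [%d, %d)",
                m.span_key,
                m.surface,
                first.start,
                last.end,
            )
        labels[idx[0]] = f"B-{m.entity_class}"
        for i in idx[1:]:
            labels[i] = f"I-{m.entity_class}"
    return labels


def iob_to_mentions(
    tokens: TokenSequence,
    labels: Sequence[str],
    section_text: str,
    confidences: Sequence[float] | None = None,
    tagger_id: str | None = None,
) -> list[Mention]:
    """Recover mentions from an IOB-valid label sequence.

    Span offsets run from the first token's start to the last token's end;
    ``section_text`` is sliced to obtain the surface (so internal spacing is
    preserved exactly).
    """
    if len(labels) != len(tokens):
        raise InvalidIOBError("labels and tokens differ in length")
    check_iob(labels)
    mentions: list[Mention] = []
    i = 0
    n = len(labels)
    while i < n:
        lab = labels[i]
        if lab.startswith("B-"):
            cls = lab[2:]
            j = i + 1
            while j < n and labels[j] == f"I-{cls}":
                j += 1
            start, end = tokens[i].start, tokens[j - 1].end
            conf = 1.0
            if confidences is not None:
                conf = float(min(confidences[i:j]))
            mentions.append(
                Mention(
                    tokens.doc_id,
                    tokens.section,
                    start,
                    end,
                    section_text[start:end],
                    cls,
                    confidence=conf,
                    tagger_id=tagger_id,
                )
            )
            i = j
        else:
            i += 1
    return mentions


def document_token_sequences(doc: Document) -> list[TokenSequence]:
    """Tokenized title and abstract (empty sections omitted)."""
    seqs = []
    for section in SECTIONS:
        text = doc.section_text(section)
        if text.strip():
            seqs.append(tokenize(text, doc.doc_id, section))
    return seqs


# ---------------------------------------------------------------------------
# prediction files

_CEM_KEY_RE = re.compile(r"^([TA]):(\d+):(\d+)$")


@dataclass(frozen=True)
class PredictionItem:
    """One line of a CDI or CEM prediction file."""

    doc_id: str
    key: tuple  # CDI: (surface,)  CEM: (section, start, end)
    rank: int
    confidence: float
    task: str  # "CDI" | "CEM"


def write_predictions(
    mentions: Sequence[Mention], task: str, path: str | Path
) -> None:
    """Serialise predictions; rank is 1-based per document in descending
    confidence, ties broken by first occurrence.

    CDI reduces to unique surface strings per document (max confidence).
    """
    task = task.upper()
    if task not in ("CDI", "CEM"):
        raise ValueError(f"task must be CDI or CEM, got {task!r}")
    per_doc: dict[str, list[tuple[tuple, float]]] = {}
    for m in mentions:
        items = per_doc.setdefault(m.doc_id, [])
        if task == "CDI":
            key: tuple = (m.surface,)
            for idx, (k, c) in enumerate(items):
                if k == key:
                    items[idx] = (k, max(c, m.confidence))
                    break
            else:
                items.append((key, m.confidence))
        else:
            items.append(((m.section, m.start, m.end), m.confidence))
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id in per_doc:
            items = per_doc[doc_id]
            order = sorted(range(len(items)), key=lambda i: (-items[i][1], i))
            for rank, i in enumerate(order, 1):
                key, conf = items[i]
                field2 = key[0] if task == "CDI" else f"{key[0]}:{key[1]}:{key[2]}"
                fh.write(f"{doc_id}\t{field2}\t{rank}\t{conf:g}\n")


def read_predictions(path: str | Path, task: str | None = None) -> list[PredictionItem]:
    """Parse a prediction file; the task is auto-detected from the second
    field unless given explicitly."""
    items: list[PredictionItem] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            doc_id, key_str, rank, conf = fields
            m = _CEM_KEY_RE.match(key_str)
            line_task = "CEM" if m else "CDI"
            if task is not None and line_task != task.upper():
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected a {task.upper()} line"
                )
            key = (m.group(1), int(m.group(2)), int(m.group(3))) if m else (key_str,)
            items.append(
                PredictionItem(doc_id, key, int(rank), float(conf), line_task)
            )
    return items


def mentions_replace_span(
    m: Mention, start: int, end: int, surface: str
) -> Mention:
    return replace(m, start=start, end=end, surface=surface)
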