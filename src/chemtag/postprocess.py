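"""Mention clean-up and multi-tagger merging.

The clean-up pipeline runs, in order: false-positive filtering (full-surface
rejection regexes), action-word detagging (strips one trailing suffix such as
"-based"), and bracket balancing (trims a single stray opener/closer, drops
mentions that remain unbalanced).  ``merge`` first resolves overlaps between
taggers -- longer span wins, then tagger priority, then leftmost -- and then
applies the pipeline, so its output is always a clean, sorted,
non-overlapping mention set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .corpus_io import Mention

__all__ = [
    "FilterSet",
    "filter_false_positives",
    "detag_action_words",
    "balance_brackets",
    "clean_mention",
    "clean_surface",
    "merge",
]

_BRACKET_PAIRS = (("(", ")"), ("[", "]"), ("{", "}"))


@dataclass(frozen=True)
class FilterSet:
    """Rejection patterns, action-word suffixes, and tagger priorities."""

    rejection_patterns: tuple[str, ...] = ()
    action_suffixes: tuple[str, ...] = (
        "-based",
        "-regulated",
        "-induced",
        "-treated",
        "-dependent",
        "-mediated",
        "-containing",
        "-derived",
    )
    priorities: tuple[str, ...] = ("crf", "dict", "regex")

    def __post_init__(self) -> None:
        for s in self.action_suffixes:
            if not s.startswith("-"):
                raise ValueError(f"action suffix {s!r} must begin with '-'")
        object.__setattr__(
            self,
            "_compiled",
            tuple(re.compile(p) for p in self.rejection_patterns),
        )

    def rejects(self, surface: str) -> bool:
        return any(p.fullmatch(surface) for p in self._compiled)

    def priority_rank(self, tagger_id: str | None) -> int:
        """Lower is better; unknown taggers rank last."""
        family = (tagger_id or "").split(":", 1)[0]
        try:
            return self.priorities.index(family)
        except ValueError:
            return len(self.priorities)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterSet":
        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(
            rejection_patterns=tuple(cfg.get("rejection_patterns", ())),
            action_suffixes=tuple(
                cfg.get("action_suffixes", cls.action_suffixes)
            ),
            priorities=tuple(cfg.get("priorities", cls.priorities)),
        )


def filter_false_positives(
    mentions: Sequence[Mention], filters: FilterSet
) -> list[Mention]:
    """Drop mentions whose *entire* surface matches a rejection pattern."""
    return [m for m in mentions if not filters.rejects(m.surface)]


def detag_action_words(
    mention: Mention, suffixes: Sequence[str]
) -> Mention | None:
    """Strip one trailing action-word suffix (e.g. "-based"), shrinking the
    span; returns None if nothing would remain."""
    for suf in suffixes:
        if mention.surface.endswith(suf) and len(mention.surface) > len(suf):
            new_surface = mention.surface[: -len(suf)]
            return replace(
                mention, end=mention.end - len(suf), surface=new_surface
            )
        if mention.surface == suf:
            return None
    return mention


def _imbalance(surface: str) -> dict[str, int]:
    return {
        op: surface.count(op) - surface.count(cl)
        for op, cl in _BRACKET_PAIRS
    }


def _balanced(surface: str) -> bool:
    return all(v == 0 for v in _imbalance(surface).values())


def balance_brackets(mention: Mention) -> Mention | None:
    """Trim a single unmatched trailing closer or leading opener; drop the
    mention if it is still unbalanced afterwards."""
    s = mention.surface
    if _balanced(s):
        return mention
    if s[-1] in ")]}" and len(s) > 1 and _balanced(s[:-1]):
        return replace(mention, end=mention.end - 1, surface=s[:-1])
    if s[0] in "([{" and len(s) > 1 and _balanced(s[1:]):
        return replace(mention, start=mention.start + 1, surface=s[1:])
    return None


def clean_mention(mention: Mention, filters: FilterSet) -> Mention | None:
    """filter -> detag -> balance, in that order."""
    if filters.rejects(mention.surface):
        return None
    m = detag_action_words(mention, filters.action_suffixes)
    if m is None:
        return None
    return balance_brackets(m)


def clean_surface(surface: str, filters: FilterSet) -> str | None:
    """Surface-only variant of :func:`clean_mention` (used for CDI items,
    which carry no offsets)."""
    if not surface or filters.rejects(surface):
        return None
    for suf in filters.action_suffixes:
        if surface.endswith(suf) and len(surface) > len(suf):
            surface = surface[: -len(suf)]
            break
        if surface == suf:
            return None
    if _balanced(surface):
        return surface
    if surface[-1] in ")]}" and len(surface) > 1 and _balanced(surface[:-1]):
        return surface[:-1]
    if surface[0] in "([{" and len(surface) > 1 and _balanced(surface[1:]):
        return surface[1:]
    return None


def _resolve_overlaps(
    candidates: list[Mention], filters: FilterSet
) -> list[Mention]:
    """Greedy selection: longer span first, then tagger priority, then
    leftmost; a candidate is kept iff it overlaps no already-kept mention."""
    order = sorted(
        candidates,
        key=lambda m: (
            -(m.end - m.start),
            filters.priority_rank(m.tagger_id),
            m.doc_id,
            m.section,
            m.start,
        ),
    )
    kept: list[Mention] = []
    by_loc: dict[tuple[str, str], list[Mention]] = {}
    for cand in order:
        loc = (cand.doc_id, cand.section)
        if any(
            cand.start < k.end and cand.end > k.start
            for k in by_loc.get(loc, ())
        ):
            continue
        kept.append(cand)
        by_loc.setdefault(loc, []).append(cand)
    return kept


def _assert_clean(mentions: Sequence[Mention]) -> None:
    prev: Mention | None = None
    for m in mentions:
        if (
            prev is not None
            and (m.doc_id, m.section) == (prev.doc_id, prev.section)
            and m.start < prev.end
        ):
            raise AssertionError(f"overlap after merge: {prev} / {m}")
        prev = m


def merge(
    tagged: Iterable[tuple[str, Sequence[Mention]]],
    filters: FilterSet | None = None,
) -> list[Mention]:
    """Union the outputs of several taggers into one clean mention set.

    ``tagged`` pairs a tagger identifier (its family prefix -- "crf",
    "dict", "regex" -- drives priority) with that tagger's own
    non-overlapping mention list.
    """
    if filters is None:
        filters = FilterSet()
    candidates: list[Mention] = []
    for tagger_id, mentions in tagged:
        for m in mentions:
            candidates.append(
                m if m.tagger_id else replace(m, tagger_id=tagger_id)
            )
    resolved = _resolve_overlaps(candidates, filters)
    cleaned = [
        c for m in resolved if (c := clean_mention(m, filters)) is not None
    ]
    cleaned.sort(key=lambda m: (m.doc_id, m.section != "T", m.start, m.end))
    _assert_clean(cleaned)
    return cleaned
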