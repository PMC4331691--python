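"""Loading of word lists, gazetteers, and pattern sets.

A resource directory holds plain-text files (one term or pattern per line,
``#`` comments allowed, UTF-8):

* ``name_segments.txt``, ``stopwords.txt`` -- feature word lists
* ``dict_trivial.txt``, ``dict_family.txt``, ``dict_abbreviation.txt``
* ``regex_formula.txt``, ``regex_identifier.txt`` -- tagger patterns
* ``regex_stop.txt`` -- surfaces the regex taggers must never tag
* ``filters.yaml`` -- post-processing configuration

The packaged defaults live in ``chemtag/data``; any directory with the same
layout can be swapped in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

from .errors import ResourceError
from .pattern_taggers import Dictionary, RegexSet

__all__ = ["Resources", "default_resource_dir", "load_resources"]

DICT_FILES = {
    "TRIVIAL": "dict_trivial.txt",
    "FAMILY": "dict_family.txt",
    "ABBREVIATION": "dict_abbreviation.txt",
}
REGEX_FILES = {
    "FORMULA": "regex_formula.txt",
    "IDENTIFIER": "regex_identifier.txt",
}
LIST_FILES = ("name_segments.txt", "stopwords.txt", "regex_stop.txt")


def default_resource_dir() -> Path:
    return Path(str(importlib_resources.files("chemtag").joinpath("data")))


def _read_list(path: Path) -> list[str]:
    if not path.is_file():
        raise ResourceError(f"missing resource file: {path}")
    out = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@dataclass
class Resources:
    """All loaded tagger/feature resources."""

    name_segments: frozenset[str]
    stopwords: frozenset[str]
    dictionaries: dict[str, Dictionary]
    regex_sets: dict[str, RegexSet]
    filters_path: Path | None = None
    segment_re: re.Pattern | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.segment_re is None and self.name_segments:
            # embedded-segment matcher: longest segments first, only those of
            # length >= 4 to avoid firing on every short function word
            longs = sorted(
                (s for s in self.name_segments if len(s) >= 4),
                key=len,
                reverse=True,
            )
            if longs:
                self.segment_re = re.compile(
                    "|".join(re.escape(s) for s in longs)
                )


def load_resources(directory: str | Path | None = None) -> Resources:
    d = Path(directory) if directory is not None else default_resource_dir()
    segments = frozenset(w.lower() for w in _read_list(d / "name_segments.txt"))
    stopwords = frozenset(w.lower() for w in _read_list(d / "stopwords.txt"))
    regex_stop = frozenset(_read_list(d / "regex_stop.txt"))
    dictionaries = {
        cls: Dictionary.from_file(cls, d / fname)
        for cls, fname in DICT_FILES.items()
    }
    regex_sets = {
        cls: RegexSet(cls, tuple(_read_list(d / fname)), regex_stop)
        for cls, fname in REGEX_FILES.items()
    }
    filters_path = d / "filters.yaml"
    return Resources(
        name_segments=segments,
        stopwords=stopwords,
        dictionaries=dictionaries,
        regex_sets=regex_sets,
        filters_path=filters_path if filters_path.is_file() else None,
    )
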