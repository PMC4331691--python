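"""Space tokenization and token-level feature extraction.

Tokens are maximal runs of non-space characters; character offsets always
refer back to the section text they were cut from.  Feature extraction works
on the token *core* -- the surface with trailing punctuation stripped -- since
end-of-token punctuation carries no information about chemical morphology.

Feature families: token length class, word-shape patterns, short prefixes and
suffixes, membership in word lists (name segments, stop words) and in
per-class dictionaries, and a battery of regular-expression predicates
(dashes, digits, capitalisation, greek letters, roman numerals,
formula/identifier/systematic morphology).  A context window copies each
neighbour's features under an offset-prefixed name ("offset conjunction").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Token",
    "TokenSequence",
    "tokenize",
    "length_class",
    "word_class",
    "affix_features",
    "resource_features",
    "regex_features",
    "token_features",
    "featurize",
    "term_match_spans",
]

#: characters stripped (repeatedly) from the end of a token to obtain its core
TRAILING_PUNCT = set(".,;:?!)]}'\"")

_GREEK_NAMES = (
    "alpha|beta|gamma|delta|epsilon|zeta|eta|theta|iota|kappa|lambda|mu|nu|"
    "xi|omicron|pi|rho|sigma|tau|upsilon|phi|chi|psi|omega"
)
_GREEK_RE = re.compile(r"(?i)(?:^|[^a-z])(?:%s)(?:$|[^a-z])|[Α-ω]" % _GREEK_NAMES)

#: strict roman numerals one through twenty, matched standalone
ROMAN_NUMERALS = frozenset(
    "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII XVIII XIX XX".split()
)

# one- and two-letter element symbols, two-letter alternatives first so the
# regex engine prefers the longer symbol ("Cl" before "C")
ELEMENT_SYMBOL = (
    "A[cglmrstu]|B[aehikr]?|C[adeflmnorsu]?|D[bsy]|E[rsu]|F[elmr]?|G[ade]|"
    "H[efgos]?|I[nr]?|Kr?|L[airuv]|M[dgnot]|N[abdeiop]?|Os?|P[abdmortu]?|"
    "R[abefghnu]|S[bcegimnr]?|T[abcehilm]|U|V|W|Xe|Yb?|Z[nr]"
)

#: molecular-formula morphology: >=2 element symbols, or one symbol with a
#: count, optional charge and hydrate decorations; case-sensitive
FORMULA_CORE_RE = re.compile(
    r"(?:(?:%(el)s)\d{0,3}){2,12}(?:\d?[+-])?(?:[.·]\d?H2O)?"
    r"|(?:%(el)s)\d{1,3}(?:\d?[+-])?" % {"el": ELEMENT_SYMBOL}
)

#: registry-style identifiers: known prefix + separator + digits, or a
#: CAS-like digit pattern
IDENTIFIER_CORE_RE = re.compile(
    r"(?:CHEBI|CHEMBL|CID|CAS|DB|EC|NSC|UNII|ZINC)[:-]\d{1,8}"
    r"|\d{2,7}-\d{2}-\d"
)

_SYSTEMATIC_SEGMENT = (
    "meth|eth|prop|but|pent|hex|hept|oct|non|dec|benz|phen|tolu|styr|napht|"
    "anthrac|hydroxy|chloro|bromo|fluoro|iodo|nitro|amino|oxo|thio|cyclo|"
    "stilben|indol|imidazol|pyridin|pyrimidin|furan|thiophen|acet|form|"
    "glycer|sulf|phosph|carb"
)
_SYSTEMATIC_SUFFIX = "ol|one|al|ane|ene|yne|ate|oate|ide|ine|amine|amide|yl|oxy|ic acid"
_MULTIPLIER = "di|tri|tetra|penta|hexa|bis|tris"

#: IUPAC-flavoured morphology: locants/multipliers/known segments plus a
#: functional suffix; used as a CRF feature, never as a standalone tagger
SYSTEMATIC_MORPH_RE = re.compile(
    r"(?i)^(?=.*[\d-])"                        # at least one digit or dash
    r"(?=.*(?:%(seg)s|%(mult)s))"              # a recognisable name segment
    r"[\w,'()\[\]-]*(?:%(suf)s)s?$"            # ends in a functional suffix
    % {"seg": _SYSTEMATIC_SEGMENT, "mult": _MULTIPLIER, "suf": _SYSTEMATIC_SUFFIX}
)

_LOCANT_RE = re.compile(r"\d+(?:,\d+)*'*-")


@dataclass(frozen=True)
class Token:
    """One space-delimited token with its section-relative character span."""

    surface: str
    start: int
    end: int
    core: str = field(default="")

    def __post_init__(self) -> None:
        if not self.core:
            object.__setattr__(self, "core", strip_trailing_punct(self.surface))

    @property
    def core_end(self) -> int:
        """End offset of the core (start + len(core))."""
        return self.start + len(self.core)


@dataclass(frozen=True)
class TokenSequence:
    """Ordered tokens cut from one section of one document."""

    doc_id: str
    section: str  # "T" or "A"
    tokens: tuple[Token, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]


def strip_trailing_punct(surface: str) -> str:
    """Remove trailing punctuation repeatedly; keep a final ')' that closes
    an opening bracket inside the token (protects e.g. "(S)-ibuprofen")."""
    core = surface
    while core and core[-1] in TRAILING_PUNCT:
        if core[-1] == ")" and core.count("(") >= core.count(")"):
            break
        if core[-1] == "]" and core.count("[") >= core.count("]"):
            break
        if core[-1] == "}" and core.count("{") >= core.count("}"):
            break
        core = core[:-1]
    return core


def tokenize(section_text: str, doc_id: str = "", section: str = "T") -> TokenSequence:
    """Split on runs of whitespace-free characters; offsets index into
    ``section_text`` so that ``section_text[t.start:t.end] == t.surface``."""
    tokens = [
        Token(m.group(0), m.start(), m.end())
        for m in re.finditer(r"\S+", section_text)
    ]
    return TokenSequence(doc_id, section, tuple(tokens))


def length_class(core: str) -> str:
    """Short (<5), Medium (5..15 inclusive), Large (>15)."""
    n = len(core)
    if n < 5:
        return "Short"
    if n <= 15:
        return "Medium"
    return "Large"


def word_class(core: str) -> tuple[str, str]:
    """Word-shape pattern and its run-collapsed variant.

    Uppercase -> 'A', lowercase -> 'a', digit -> '0', anything else kept.
    """
    out = []
    for ch in core:
        if ch.isupper():
            out.append("A")
        elif ch.islower():
            out.append("a")
        elif ch.isdigit():
            out.append("0")
        else:
            out.append(ch)
    full = "".join(out)
    collapsed = re.sub(r"(.)\1+", r"\1", full)
    return full, collapsed


def affix_features(core: str) -> set[str]:
    """Prefixes and suffixes of length 2, 3 and 4 (only those <= |core|)."""
    feats: set[str] = set()
    for n in (2, 3, 4):
        if n <= len(core):
            feats.add(f"pre{n}={core[:n]}")
            feats.add(f"suf{n}={core[-n:]}")
    return feats


def resource_features(core: str, resources) -> set[str]:
    """Word-list membership features (single-token; multi-word dictionary
    matches are handled at sequence level by :func:`featurize`)."""
    feats: set[str] = set()
    low = core.lower()
    if low and low in resources.name_segments:
        feats.add("seg")
    # a token also counts as segment-bearing if a known segment is embedded
    elif low and resources.segment_re is not None and resources.segment_re.search(low):
        feats.add("seg-in")
    if low in resources.stopwords:
        feats.add("stop")
    return feats


def regex_features(core: str) -> set[str]:
    """Pattern predicates over one token core (Table-style feature battery)."""
    feats: set[str] = set()
    if "-" in core:
        feats.add("rx=dash")
    if len(core) >= 2 and core.isupper():
        feats.add("rx=allcaps")
    if any(c.isdigit() for c in core):
        feats.add("rx=digit")
    if _GREEK_RE.search(core):
        feats.add("rx=greek")
    if core in ROMAN_NUMERALS:
        feats.add("rx=roman")
    if FORMULA_CORE_RE.fullmatch(core):
        feats.add("rx=formula")
    if IDENTIFIER_CORE_RE.fullmatch(core):
        feats.add("rx=ident")
    if SYSTEMATIC_MORPH_RE.match(core) or _LOCANT_RE.match(core):
        feats.add("rx=sysmorph")
    return feats


def token_features(core: str, resources=None) -> set[str]:
    """All intrinsic features of a single token core."""
    feats = {"b", f"w={core.lower()}", f"len={length_class(core)}"}
    full, collapsed = word_class(core)
    feats.add(f"wc={full}")
    feats.add(f"wcc={collapsed}")
    feats |= affix_features(core)
    feats |= regex_features(core)
    if resources is not None:
        feats |= resource_features(core, resources)
    return feats


def term_match_spans(
    cores: Sequence[str], terms: Iterable[tuple[str, ...]], max_len: int
) -> list[tuple[int, int]]:
    """All windows ``[i, j)`` of ``cores`` equal to some term (a tuple of
    words, already case-normalised to match ``cores``)."""
    term_set = set(terms)
    spans = []
    n = len(cores)
    for i in range(n):
        for j in range(i + 1, min(n, i + max_len) + 1):
            if tuple(cores[i:j]) in term_set:
                spans.append((i, j))
    return spans


def featurize(
    seq: TokenSequence,
    resources=None,
    offset: int = 1,
) -> list[set[str]]:
    """Per-token feature sets with an offset-conjunction window.

    Each token receives its own features plus copies of the features of the
    tokens at relative positions ``-offset .. +offset`` (excluding 0), the
    copies prefixed with e.g. ``-1:`` / ``+1:``.  Sequence boundaries simply
    omit the missing neighbours.  Multi-word dictionary terms mark every
    covered token with ``dict=<CLASS>``.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    own = [token_features(t.core, resources) for t in seq]

    if resources is not None:
        for cls, dictionary in resources.dictionaries.items():
            cores = [dictionary.normalize(t.core) for t in seq]
            for i, j in term_match_spans(cores, dictionary.terms, dictionary.max_len):
                for k in range(i, j):
                    own[k].add(f"dict={cls}")

    if offset == 0:
        return own
    out: list[set[str]] = []
    n = len(own)
    for i in range(n):
        feats = set(own[i])
        for d in range(1, offset + 1):
            if i - d >= 0:
                feats |= {f"-{d}:{f}" for f in own[i - d]}
            if i + d < n:
                feats |= {f"+{d}:{f}" for f in own[i + d]}
        out.append(feats)
    return out
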