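"""Synthetic CHEMDNER-style corpora with gold annotations.

Documents are template sentences with chemical entities spliced in at
recorded character offsets, so every gold mention satisfies the
surface/offset invariant by construction.  Entity surfaces are drawn per
class so that each class's tagger resources can recognise them: TRIVIAL,
FAMILY and ABBREVIATION terms come verbatim from the packaged gazetteers,
SYSTEMATIC names from a small IUPAC-flavoured grammar (locants, multiplier
prefixes, name segments, functional suffixes), FORMULA and IDENTIFIER tokens
from generators closed under the corresponding regex sets.

Sentences separate tokens -- including final punctuation -- by single
spaces, which keeps entity spans aligned with space-token boundaries.  Most
templates give entities a weakly informative context ("was treated with X");
a fraction are context-free so a sequence model must rely on token-shape
features.  An ``inconsistency_rate`` deletes each gold annotation (not the
text) independently, emulating incompletely annotated corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document, ENTITY_CLASSES, Mention, TITLE, ABSTRACT
from .resources import Resources, load_resources

__all__ = [
    "SynthConfig",
    "generate",
    "gen_systematic",
    "gen_formula",
    "gen_identifier",
    "gen_entity",
]

_CONTEXT_TEMPLATES = (
    "the patient was treated with {} daily .",
    "levels of {} increased after exposure .",
    "administration of {} reduced the observed symptoms .",
    "we measured the concentration of {} in serum .",
    "{} inhibited the enzyme activity in vitro .",
    "cells were incubated with {} for two hours .",
    "the effect of {} on cell growth was assessed .",
    "treatment with {} and {} showed a synergistic effect .",
    "samples spiked with {} were analysed by chromatography .",
    "exposure to {} altered the expression profile .",
    "a single dose of {} was given to each group .",
    "binding of {} to the receptor was quantified .",
    "dietary intake of {} correlated with the outcome .",
    "incubation with {} blocked the response completely .",
)
#: context-free templates stress token-shape features
_BARE_TEMPLATES = (
    "{} .",
    "{} and {} .",
)
_BARE_FRACTION = 0.2

_FILLER_SENTENCES = (
    "the control group received no treatment .",
    "results were analysed with standard statistical methods .",
    "all experiments were repeated three times .",
    "the study protocol was approved by the local committee .",
    "participants were followed for twelve months .",
    "tissue sections were examined under the microscope .",
)
_TITLE_TEMPLATES = (
    "effects of {} on cell viability",
    "analysis of {} in biological samples",
    "a study of {} and its metabolites",
    "quantification of {} by mass spectrometry",
    "the role of {} in disease progression",
)
_PLAIN_TITLES = (
    "a randomised controlled trial in two cohorts",
    "an observational study of hospital admissions",
)

_STEREO = ("trans-", "cis-")
_MULTIPLIERS = ("di", "tri", "tetra")
_SUBSTITUENTS = (
    "methyl",
    "ethyl",
    "propyl",
    "butyl",
    "phenyl",
    "hydroxy",
    "chloro",
    "bromo",
    "fluoro",
    "amino",
    "nitro",
    "methoxy",
)
_STEMS = (
    "methan",
    "ethan",
    "propan",
    "butan",
    "pentan",
    "hexan",
    "heptan",
    "octan",
    "benzen",
)
_SUFFIXES = ("ol", "one", "al", "ene", "oate", "amine")
_FORMULA_ELEMENTS = (
    "C", "H", "N", "O", "S", "P", "Na", "Cl", "Fe", "K", "Ca", "Mg", "Br", "Zn",
)
_ID_PREFIXES = ("CHEBI", "CHEMBL", "CID", "DB", "NSC", "ZINC")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one generated corpus."""

    n_documents: int = 50
    sentences_per_doc: tuple[int, int] = (2, 4)
    entity_rate: float = 0.85  # probability a body sentence carries entities
    class_weights: tuple[float, ...] = field(
        default_factory=lambda: (1 / 6,) * 6
    )
    inconsistency_rate: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_weights) != len(ENTITY_CLASSES):
            raise ValueError("need one weight per entity class")
        if any(w < 0 for w in self.class_weights):
            raise ValueError("class weights must be non-negative")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")
        if not 0 <= self.inconsistency_rate <= 1:
            raise ValueError("inconsistency_rate must be a probability")


def gen_systematic(rng: np.random.Generator) -> str:
    """Sample an IUPAC-flavoured name; always contains a digit or hyphen and
    fires the systematic-morphology feature."""
    parts = []
    if rng.random() < 0.25:
        parts.append(rng.choice(_STEREO))
    if rng.random() < 0.7:
        locs = ",".join(
            str(rng.integers(2, 7)) for _ in range(rng.integers(1, 3))
        )
        if rng.random() < 0.15:
            locs += "'"
        parts.append(locs + "-")
    if rng.random() < 0.5:
        parts.append(rng.choice(_MULTIPLIERS))
    for _ in range(rng.integers(1, 3)):
        parts.append(rng.choice(_SUBSTITUENTS))
    parts.append(rng.choice(_STEMS))
    if rng.random() < 0.5:
        parts.append(f"-{rng.integers(1, 4)}-{rng.choice(_SUFFIXES)}")
    else:
        parts.append(rng.choice(_SUFFIXES))
    name = "".join(parts)
    if not any(c.isdigit() or c == "-" for c in name):
        name = "2-" + name
    return name


def gen_formula(
    rng: np.random.Generator,
    stop: frozenset = frozenset(),
    stopwords: frozenset = frozenset(),
) -> str:
    """Element symbols with optional counts, e.g. "C6H12O6".

    Draws colliding with the regex stop list or (case-folded) with the
    stop-word list are rejected and redrawn.
    """
    while True:
        k = int(rng.integers(2, 6))
        parts = []
        for _ in range(k):
            sym = rng.choice(_FORMULA_ELEMENTS)
            parts.append(sym)
            if rng.random() < 0.6:
                parts.append(str(rng.integers(1, 13)))
        s = "".join(parts)
        if s not in stop and s.lower() not in stopwords:
            return s


def gen_identifier(rng: np.random.Generator) -> str:
    """Registry-style token: known prefix + separator + digits, or a
    CAS-like digit triple."""
    if rng.random() < 0.3:
        return (
            f"{rng.integers(50, 99999)}-{rng.integers(10, 99)}-{rng.integers(0, 9)}"
        )
    prefix = rng.choice(_ID_PREFIXES)
    sep = ":" if rng.random() < 0.8 else "-"
    return f"{prefix}{sep}{rng.integers(100, 99999)}"


def _sorted_terms(resources: Resources, cls: str) -> list[str]:
    return sorted(" ".join(t) for t in resources.dictionaries[cls].terms)


def gen_entity(
    cls: str,
    rng: np.random.Generator,
    resources: Resources,
    _cache: dict | None = None,
) -> str:
    if cls == "SYSTEMATIC":
        return gen_systematic(rng)
    if cls == "FORMULA":
        stop = resources.regex_sets["FORMULA"].stop_words
        return gen_formula(rng, stop, resources.stopwords)
    if cls == "IDENTIFIER":
        return gen_identifier(rng)
    terms = (_cache or {}).get(cls) or _sorted_terms(resources, cls)
    return str(rng.choice(terms))


def _fill_template(
    template: str,
    classes: list[str],
    rng: np.random.Generator,
    resources: Resources,
    cache: dict,
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Render one sentence; returns (text, [(start, end, surface, class)])."""
    out = []
    spans = []
    pos = 0
    pieces = template.split("{}")
    for i, piece in enumerate(pieces):
        out.append(piece)
        pos += len(piece)
        if i < len(pieces) - 1:
            cls = classes[i]
            surface = gen_entity(cls, rng, resources, cache)
            spans.append((pos, pos + len(surface), surface, cls))
            out.append(surface)
            pos += len(surface)
    return "".join(out), spans


def _sample_classes(n: int, config: SynthConfig, rng) -> list[str]:
    idx = rng.choice(len(ENTITY_CLASSES), size=n, p=config.class_weights)
    return [ENTITY_CLASSES[i] for i in np.atleast_1d(idx)]


def generate(
    config: SynthConfig, resources: Resources | None = None
) -> tuple[list[Document], list[Mention]]:
    """Generate a corpus; deterministic byte-for-byte given the seed."""
    if resources is None:
        resources = load_resources()
    rng = np.random.default_rng(config.random_seed)
    cache = {
        cls: _sorted_terms(resources, cls)
        for cls in ("TRIVIAL", "FAMILY", "ABBREVIATION")
    }
    docs: list[Document] = []
    mentions: list[Mention] = []
    for i in range(config.n_documents):
        doc_id = f"SYN{i:05d}"
        doc_mentions: list[Mention] = []
        # title
        if rng.random() < 0.7:
            tpl = str(rng.choice(_TITLE_TEMPLATES))
            cls = _sample_classes(1, config, rng)
            title, spans = _fill_template(tpl, cls, rng, resources, cache)
        else:
            title, spans = str(rng.choice(_PLAIN_TITLES)), []
        for s, e, surf, cls in spans:
            doc_mentions.append(Mention(doc_id, TITLE, s, e, surf, cls))
        # abstract
        lo, hi = config.sentences_per_doc
        n_sent = int(rng.integers(lo, hi + 1))
        sent_texts = []
        pos = 0
        for _ in range(n_sent):
            if rng.random() < config.entity_rate:
                pool = (
                    _BARE_TEMPLATES
                    if rng.random() < _BARE_FRACTION
                    else _CONTEXT_TEMPLATES
                )
                tpl = str(rng.choice(pool))
                n_slots = tpl.count("{}")
                classes = _sample_classes(n_slots, config, rng)
                text, spans = _fill_template(tpl, classes, rng, resources, cache)
            else:
                text, spans = str(rng.choice(_FILLER_SENTENCES)), []
            for s, e, surf, cls in spans:
                doc_mentions.append(
                    Mention(doc_id, ABSTRACT, pos + s, pos + e, surf, cls)
                )
            sent_texts.append(text)
            pos += len(text) + 1  # joining space
        abstract = " ".join(sent_texts)
        doc = Document(doc_id, title, abstract)
        for m in doc_mentions:
            m.validate_against(doc)
        docs.append(doc)
        mentions.extend(doc_mentions)
    if config.inconsistency_rate > 0:
        keep = rng.random(len(mentions)) >= config.inconsistency_rate
        mentions = [m for m, k in zip(mentions, keep) if k]
    return docs, mentions
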