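"""The five run architectures binding entity classes to taggers.

Run 1: CRF for SYSTEMATIC; dictionaries for TRIVIAL/FAMILY/ABBREVIATION;
       regexes for FORMULA/IDENTIFIER.
Run 2: per-class CRFs for SYSTEMATIC and TRIVIAL; dictionaries for
       FAMILY/ABBREVIATION; regexes for FORMULA/IDENTIFIER.
Run 3: one CRF per class, all six classes.
Run 4: per-class CRFs for all classes except IDENTIFIER (regex).
Run 5: a single joint CRF labelling all six classes at once.

Per-class CRFs are trained on the full corpus with every other class's
tokens relabelled O.  The dictionary terms and tagger regexes are also
available to the CRFs as token features, so a run's pattern resources inform
its sequence models too.  Each document's tagger outputs are combined by the
post-processing merge, giving a clean non-overlapping mention set.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from . import crf
from .corpus_io import (
    Document,
    ENTITY_CLASSES,
    Mention,
    document_token_sequences,
    iob_to_mentions,
    joint_labels,
    mentions_to_iob,
    single_labels,
)
from .errors import ChemtagError
from .pattern_taggers import dict_tag, regex_tag
from .postprocess import FilterSet, merge
from .resources import Resources, load_resources
from .text_processing import featurize

logger = logging.getLogger(__name__)

CRF_JOINT = "CRF_JOINT"
CRF_SINGLE = "CRF_SINGLE"
DICT = "DICT"
REGEX = "REGEX"

RUN_ARCHITECTURES: dict[int, dict[str, str]] = {
    1: {
        "SYSTEMATIC": CRF_SINGLE,
        "TRIVIAL": DICT,
        "FAMILY": DICT,
        "ABBREVIATION": DICT,
        "FORMULA": REGEX,
        "IDENTIFIER": REGEX,
    },
    2: {
        "SYSTEMATIC": CRF_SINGLE,
        "TRIVIAL": CRF_SINGLE,
        "FAMILY": DICT,
        "ABBREVIATION": DICT,
        "FORMULA": REGEX,
        "IDENTIFIER": REGEX,
    },
    3: {c: CRF_SINGLE for c in ENTITY_CLASSES},
    4: {
        **{c: CRF_SINGLE for c in ENTITY_CLASSES},
        "IDENTIFIER": REGEX,
    },
    5: {c: CRF_JOINT for c in ENTITY_CLASSES},
}


@dataclass(frozen=True)
class RunConfig:
    """One run architecture with its model locations."""

    run_id: int
    assignment: dict[str, str] = field(default_factory=dict)
    model_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.run_id not in RUN_ARCHITECTURES:
            raise ValueError(f"run_id must be 1..5, got {self.run_id}")
        if not self.assignment:
            object.__setattr__(
                self, "assignment", dict(RUN_ARCHITECTURES[self.run_id])
            )

    @property
    def crf_model_names(self) -> list[str]:
        """Model identifiers this run needs ("joint" or one per CRF class)."""
        if CRF_JOINT in self.assignment.values():
            return ["joint"]
        return [c for c, t in self.assignment.items() if t == CRF_SINGLE]

    def model_path(self, name: str) -> Path:
        if self.model_dir is None:
            raise ChemtagError("run has no model directory")
        return Path(self.model_dir) / f"run{self.run_id}_{name}.crf.npz"


def _training_sequences(docs, gold, resources, offset):
    by_doc: dict[str, list[Mention]] = {}
    for m in gold:
        by_doc.setdefault(m.doc_id, []).append(m)
    out = []
    for doc in docs:
        for seq in document_token_sequences(doc):
            feats = featurize(seq, resources, offset=offset)
            out.append((seq, feats, by_doc.get(doc.doc_id, [])))
    return out


def _labels_for(seq, mentions, classes):
    wanted = [m for m in mentions if m.entity_class in classes]
    return mentions_to_iob(seq, wanted)


def train_run(
    docs: list[Document],
    gold: list[Mention],
    run_id: int,
    out_dir: str | Path,
    resources: Resources | None = None,
    **config_overrides,
) -> dict[str, Path]:
    """Train and persist exactly the CRF models the run requires.

    MULTIPLE / NO CLASS gold mentions are accepted but excluded from the
    training targets.  Returns {model name: file path}.
    """
    if not docs:
        raise ChemtagError("empty corpus")
    if resources is None:
        resources = load_resources()
    config = RunConfig(run_id, model_dir=Path(out_dir))
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    offset = int(config_overrides.get("offset", 1))
    prepared = _training_sequences(docs, gold, resources, offset)
    paths: dict[str, Path] = {}
    for name in config.crf_model_names:
        if name == "joint":
            labels = joint_labels()
            classes = set(ENTITY_CLASSES)
        else:
            labels = single_labels(name)
            classes = {name}
        cfg = crf.CRFConfig(labels=labels, offset=offset, **{
            k: v for k, v in config_overrides.items() if k != "offset"
        })
        corpus = [
            (feats, _labels_for(seq, mentions, classes))
            for seq, feats, mentions in prepared
        ]
        model = crf.train(corpus, cfg)
        path = config.model_path(name)
        crf.save(model, path)
        paths[name] = path
        logger.info("run %d: trained model %s -> %s", run_id, name, path)
    return paths


def load_run_models(config: RunConfig) -> dict[str, crf.CRFModel]:
    """Load every CRF the run needs; fails before any tagging starts."""
    models = {}
    for name in config.crf_model_names:
        path = config.model_path(name)
        if not path.is_file():
            raise ChemtagError(f"missing model file: {path}")
        models[name] = crf.load(path)
    return models


def _crf_mentions(model, doc, seq, feats, keep_classes=None):
    labels = model.decode(feats)
    post = model.marginals(feats)
    lab_idx = {lab: i for i, lab in enumerate(model.labels)}
    confs = [float(post[t, lab_idx[lab]]) for t, lab in enumerate(labels)]
    found = iob_to_mentions(
        seq,
        labels,
        doc.section_text(seq.section),
        confidences=confs,
        tagger_id="crf",
    )
    if keep_classes is not None:
        found = [m for m in found if m.entity_class in keep_classes]
    return found


def tag_corpus(
    docs: list[Document],
    config: RunConfig | int,
    resources: Resources | None = None,
    filters: FilterSet | None = None,
    models: dict[str, crf.CRFModel] | None = None,
) -> list[Mention]:
    """Apply every tagger the run binds and merge the outputs per document."""
    if isinstance(config, int):
        config = RunConfig(config)
    if resources is None:
        resources = load_resources()
    if filters is None:
        filters = (
            FilterSet.from_yaml(resources.filters_path)
            if resources.filters_path
            else FilterSet()
        )
    if models is None:
        models = load_run_models(config) if config.crf_model_names else {}
    else:
        missing = [n for n in config.crf_model_names if n not in models]
        if missing:
            raise ChemtagError(f"missing models for run: {missing}")

    dict_classes = [c for c, t in config.assignment.items() if t == DICT]
    regex_classes = [c for c, t in config.assignment.items() if t == REGEX]
    single_classes = [c for c, t in config.assignment.items() if t == CRF_SINGLE]
    use_joint = CRF_JOINT in config.assignment.values()

    out: list[Mention] = []
    stage_counts: Counter = Counter()
    for doc in docs:
        tagged: list[tuple[str, list[Mention]]] = []
        seqs = document_token_sequences(doc)
        if use_joint or single_classes:
            for seq in seqs:
                feats = featurize(seq, resources, offset=1)
                if use_joint:
                    found = _crf_mentions(models["joint"], doc, seq, feats)
                    tagged.append(("crf", found))
                for cls in single_classes:
                    found = _crf_mentions(
                        models[cls], doc, seq, feats, keep_classes={cls}
                    )
                    tagged.append((f"crf:{cls}", found))
        for cls in dict_classes:
            tagged.append((f"dict:{cls}", dict_tag(doc, resources.dictionaries[cls])))
        for cls in regex_classes:
            tagged.append((f"regex:{cls}", regex_tag(doc, resources.regex_sets[cls])))
        for tagger_id, found in tagged:
            for m in found:
                stage_counts[f"raw/{tagger_id.split(':')[0]}/{m.entity_class}"] += 1
        merged = merge(tagged, filters)
        for m in merged:
            stage_counts[f"merged/{m.entity_class}"] += 1
        out.extend(merged)
    for key in sorted(stage_counts):
        logger.info("run %d: %s = %d", config.run_id, key, stage_counts[key])
    return out
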