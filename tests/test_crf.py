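"""CRF unit tests, including the brute-force decoding oracle.

The oracle enumerates every label sequence of a toy instance and scores it
with the same emission + transition parameterisation the model uses; the
expanded-state Viterbi path must attain the enumeration maximum and the
forward-backward log-partition must match the enumeration log-sum-exp.
"""

import itertools

import numpy as np
import pytest

from chemtag import crf
from chemtag.corpus_io import joint_labels, single_labels
from chemtag.errors import ChemtagError, ModelFormatError
from chemtag.evaluation import micro_prf


def brute_force(E, Wt, mask, order):
    """Enumerate all label sequences; return (best path, logZ)."""
    T, m = E.shape
    score = crf._score_o1 if order == 1 else crf._score_o2
    best, best_s, total = None, -np.inf, []
    for y in itertools.product(range(m), repeat=T):
        s = score(E, Wt, mask, np.array(y))
        if np.isfinite(s):
            total.append(s)
            if s > best_s:
                best, best_s = y, s
    from scipy.special import logsumexp

    return best, best_s, logsumexp(np.array(total))


@pytest.mark.parametrize("order", [1, 2])
@pytest.mark.parametrize("T", [1, 2, 3, 5])
def test_viterbi_and_partition_match_enumeration(order, T):
    """Hand-set random weights, <=5 tokens, 4 IOB labels: expanded-state
    decoding equals exhaustive search."""
    rng = np.random.default_rng(12345 + 10 * order + T)
    labels = ("O", "B-X", "I-X", "B-Y")
    mask = crf.iob_transition_mask(labels)
    m = len(labels)
    for _ in range(10):
        E = rng.normal(size=(T, m))
        shape = (m + 1, m) if order == 1 else (m + 1, m + 1, m)
        Wt = rng.normal(size=shape)
        viterbi = crf._viterbi_o1 if order == 1 else crf._viterbi_o2
        fb = crf._forward_backward_o1 if order == 1 else crf._forward_backward_o2
        score = crf._score_o1 if order == 1 else crf._score_o2
        best, best_s, logZ_bf = brute_force(E, Wt, mask, order)
        path = viterbi(E, Wt, mask)
        assert score(E, Wt, mask, path) == pytest.approx(best_s)
        logZ, _, _ = fb(E, Wt, mask)
        assert logZ == pytest.approx(logZ_bf)


def _tiny_corpus(resources, n_docs=30, seed=3):
    from chemtag.corpus_io import document_token_sequences, mentions_to_iob
    from chemtag.synthetic import SynthConfig, generate
    from chemtag.text_processing import featurize

    docs, gold = generate(SynthConfig(n_documents=n_docs, random_seed=seed), resources)
    by_doc = {}
    for m in gold:
        by_doc.setdefault(m.doc_id, []).append(m)
    corpus = []
    for doc in docs:
        for seq in document_token_sequences(doc):
            feats = featurize(seq, resources, offset=1)
            labels = mentions_to_iob(seq, by_doc.get(doc.doc_id, []))
            corpus.append((feats, labels))
    return corpus


@pytest.fixture(scope="module")
def separable(resources):
    """A small dictionary-separable corpus and a joint model trained on it."""
    corpus = _tiny_corpus(resources)
    config = crf.CRFConfig(labels=joint_labels(), max_iterations=100)
    model = crf.train(corpus, config)
    return corpus, model


class TestTrain:
    def test_training_set_f_score_high_on_separable_corpus(self, separable):
        corpus, model = separable
        gold_spans, pred_spans = set(), set()
        for k, (feats, labels) in enumerate(corpus):
            decoded = model.decode(feats)
            for t, lab in enumerate(labels):
                if lab != "O":
                    gold_spans.add((k, t, lab))
            for t, lab in enumerate(decoded):
                if lab != "O":
                    pred_spans.add((k, t, lab))
        res = micro_prf(gold_spans, pred_spans)
        assert res.fscore >= 95.0

    def test_single_class_alphabet(self, resources):
        corpus = _tiny_corpus(resources, n_docs=8)
        sys_only = []
        for feats, labels in corpus:
            labs = [l if l.endswith("SYSTEMATIC") else "O" for l in labels]
            sys_only.append((feats, labs))
        config = crf.CRFConfig(labels=single_labels("SYSTEMATIC"), max_iterations=30)
        model = crf.train(sys_only, config)
        assert set(model.labels) == {"O", "B-SYSTEMATIC", "I-SYSTEMATIC"}
        for feats, _ in corpus[:5]:
            assert set(model.decode(feats)) <= set(model.labels)

    def test_training_is_deterministic(self, resources):
        corpus = _tiny_corpus(resources, n_docs=6)
        cfg = crf.CRFConfig(labels=joint_labels(), max_iterations=25, random_seed=9)
        m1 = crf.train(corpus, cfg)
        m2 = crf.train(corpus, cfg)
        held_out = _tiny_corpus(resources, n_docs=3, seed=99)
        for feats, _ in held_out:
            assert m1.decode(feats) == m2.decode(feats)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ChemtagError):
            crf.train([], crf.CRFConfig(labels=joint_labels()))

    def test_label_outside_alphabet_rejected(self, resources):
        corpus = [([{"b"}], ["B-NOPE"])]
        with pytest.raises(ChemtagError):
            crf.train(corpus, crf.CRFConfig(labels=single_labels("SYSTEMATIC")))


class TestDecode:
    def test_decode_recovers_training_labels(self, separable):
        corpus, model = separable
        mismatches = sum(
            model.decode(feats) != labels for feats, labels in corpus[:20]
        )
        assert mismatches <= 1  # near-perfect on its own training data

    def test_empty_sequence(self, separable):
        _, model = separable
        assert model.decode([]) == []

    def test_decoded_sequences_are_iob_valid(self, separable):
        from chemtag.corpus_io import check_iob

        corpus, model = separable
        for feats, _ in corpus[:10]:
            check_iob(model.decode(feats))  # raises on violation

    def test_unknown_features_ignored(self, separable):
        _, model = separable
        feats = [{"never-seen-feature-1"}, {"never-seen-feature-2"}]
        labels = model.decode(feats)
        assert len(labels) == 2

    def test_indicative_feature_does_not_hurt_training_fit(self, resources):
        """Adding a feature present only on gold B tokens must not lower
        training-set accuracy."""
        corpus = _tiny_corpus(resources, n_docs=10)
        boosted = [
            (
                [f | {"gold-b"} if l.startswith("B-") else set(f)
                 for f, l in zip(feats, labels)],
                labels,
            )
            for feats, labels in corpus
        ]
        cfg = crf.CRFConfig(labels=joint_labels(), max_iterations=40)
        base_model = crf.train(corpus, cfg)
        boost_model = crf.train(boosted, cfg)

        def acc(model, data):
            good = total = 0
            for feats, labels in data:
                decoded = model.decode(feats)
                good += sum(d == l for d, l in zip(decoded, labels))
                total += len(labels)
            return good / total

        assert acc(boost_model, boosted) >= acc(base_model, corpus) - 1e-9


class TestPersistence:
    def test_round_trip_identical_decoding(self, separable, tmp_path, resources):
        corpus, model = separable
        path = tmp_path / "model.crf.npz"
        crf.save(model, path)
        loaded = crf.load(path)
        held_out = _tiny_corpus(resources, n_docs=10, seed=77)
        for feats, _ in held_out:
            assert loaded.decode(feats) == model.decode(feats)

    def test_truncated_file_raises_model_error(self, separable, tmp_path):
        _, model = separable
        path = tmp_path / "model.crf.npz"
        crf.save(model, path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(ModelFormatError):
            crf.load(path)

    def test_not_a_model_file(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, x=np.arange(3))
        with pytest.raises(ModelFormatError):
            crf.load(path)
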