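import pytest

from chemtag.corpus_io import (
    Document,
    Mention,
    iob_to_mentions,
    mentions_to_iob,
    read_abstracts,
    read_annotations,
    read_predictions,
    write_abstracts,
    write_annotations,
    write_predictions,
)
from chemtag.errors import (
    AnnotationMismatchError,
    CorpusFormatError,
    InvalidIOBError,
    OverlapError,
)
from chemtag.text_processing import tokenize


class TestReadAbstracts:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("D1\tAspirin study\tAspirin helps.\n")
        docs = read_abstracts(p)
        assert docs == [Document("D1", "Aspirin study", "Aspirin helps.")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("")
        assert read_abstracts(p) == []

    def test_wrong_field_count_names_line(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("D1\tonly two fields\n")
        with pytest.raises(CorpusFormatError, match=":1"):
            read_abstracts(p)

    def test_duplicate_doc_id(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("D1\ta\tb\nD1\tc\td\n")
        with pytest.raises(CorpusFormatError, match="duplicate"):
            read_abstracts(p)

    def test_round_trip(self, tmp_path, small_corpus):
        docs, _ = small_corpus
        p = tmp_path / "abs.tsv"
        write_abstracts(docs, p)
        assert read_abstracts(p) == docs


class TestReadAnnotations:
    @pytest.fixture
    def doc(self):
        return Document("D1", "Aspirin study", "Aspirin helps a lot.")

    def test_valid_mention(self, tmp_path, doc):
        p = tmp_path / "ann.tsv"
        p.write_text("D1\tT\t0\t7\tAspirin\tTRIVIAL\n")
        (m,) = read_annotations(p, [doc])
        assert m == Mention("D1", "T", 0, 7, "Aspirin", "TRIVIAL")

    def test_offset_surface_mismatch(self, tmp_path, doc):
        p = tmp_path / "ann.tsv"
        p.write_text("D1\tT\t0\t6\tAspirin\tTRIVIAL\n")
        with pytest.raises(AnnotationMismatchError, match="D1"):
            read_annotations(p, [doc])

    def test_unknown_class(self, tmp_path, doc):
        p = tmp_path / "ann.tsv"
        p.write_text("D1\tT\t0\t7\tAspirin\tWEIRD\n")
        with pytest.raises(CorpusFormatError, match="class"):
            read_annotations(p, [doc])

    def test_unknown_doc(self, tmp_path, doc):
        p = tmp_path / "ann.tsv"
        p.write_text("D9\tT\t0\t7\tAspirin\tTRIVIAL\n")
        with pytest.raises(CorpusFormatError, match="doc_id"):
            read_annotations(p, [doc])

    def test_round_trip_on_synthetic_corpus(self, tmp_path, small_corpus):
        docs, gold = small_corpus
        p = tmp_path / "ann.tsv"
        write_annotations(gold, p)
        assert read_annotations(p, docs) == gold


class TestIOBConversion:
    def test_single_token_entity(self):
        seq = tokenize("treated with trans-resveratrol daily", "D1", "A")
        m = Mention("D1", "A", 13, 30, "trans-resveratrol", "TRIVIAL")
        assert mentions_to_iob(seq, [m]) == ["O", "O", "B-TRIVIAL", "O"]

    def test_two_token_entity(self):
        text = "the sodium chloride salt"
        seq = tokenize(text, "D1", "A")
        m = Mention("D1", "A", 4, 19, "sodium chloride", "FAMILY")
        assert mentions_to_iob(seq, [m]) == ["O", "B-FAMILY", "I-FAMILY", "O"]

    def test_no_mentions_all_outside(self):
        seq = tokenize("nothing here", "D1", "A")
        assert mentions_to_iob(seq, []) == ["O", "O"]

    def test_overlap_rejected(self):
        seq = tokenize("sodium chloride salt", "D1", "A")
        a = Mention("D1", "A", 0, 15, "sodium chloride", "FAMILY")
        b = Mention("D1", "A", 7, 15, "chloride", "TRIVIAL")
        with pytest.raises(OverlapError):
            mentions_to_iob(seq, [a, b])

    def test_intra_token_boundary_expanded_with_warning(self, caplog):
        text = "aspirin-based therapy"
        seq = tokenize(text, "D1", "A")
        m = Mention("D1", "A", 0, 7, "aspirin", "TRIVIAL")
        with caplog.at_level("WARNING"):
            labels = mentions_to_iob(seq, [m])
        assert labels == ["B-TRIVIAL", "O"]
        assert "expanded" in caplog.text

    def test_round_trip_identity(self):
        text = "the sodium chloride salt helps"
        seq = tokenize(text, "D1", "A")
        m = Mention("D1", "A", 4, 19, "sodium chloride", "FAMILY")
        labels = mentions_to_iob(seq, [m])
        assert iob_to_mentions(seq, labels, text) == [m]

    def test_multi_token_formula(self):
        text = "C6H12O6 ·H2O"
        seq = tokenize(text, "D1", "A")
        got = iob_to_mentions(seq, ["B-FORMULA", "I-FORMULA"], text)
        assert got == [Mention("D1", "A", 0, 12, "C6H12O6 ·H2O", "FORMULA")]

    def test_all_outside_yields_no_mentions(self):
        text = "just words"
        seq = tokenize(text, "D1", "A")
        assert iob_to_mentions(seq, ["O", "O"], text) == []

    def test_invalid_iob_rejected(self):
        seq = tokenize("a b", "D1", "A")
        with pytest.raises(InvalidIOBError):
            iob_to_mentions(seq, ["O", "I-TRIVIAL"], "a b")

    def test_length_mismatch_rejected(self):
        seq = tokenize("a b", "D1", "A")
        with pytest.raises(InvalidIOBError):
            iob_to_mentions(seq, ["O"], "a b")


class TestPredictions:
    def test_cdi_ranks_by_confidence(self, tmp_path):
        p = tmp_path / "pred.tsv"
        ms = [
            Mention("D1", "T", 0, 4, "NaCl", "FORMULA", confidence=0.5),
            Mention("D1", "A", 0, 7, "aspirin", "TRIVIAL", confidence=0.9),
        ]
        write_predictions(ms, "CDI", p)
        lines = p.read_text().splitlines()
        assert lines[0].split("\t") == ["D1", "aspirin", "1", "0.9"]
        assert lines[1].split("\t") == ["D1", "NaCl", "2", "0.5"]

    def test_cdi_deduplicates_surfaces(self, tmp_path):
        p = tmp_path / "pred.tsv"
        ms = [
            Mention("D1", "A", 0, 7, "aspirin", "TRIVIAL", confidence=0.4),
            Mention("D1", "A", 20, 27, "aspirin", "TRIVIAL", confidence=0.8),
        ]
        write_predictions(ms, "CDI", p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].endswith("0.8")

    def test_cem_line_encodes_span(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_predictions(
            [Mention("D1", "T", 0, 7, "aspirin", "TRIVIAL")], "CEM", p
        )
        assert "T:0:7" in p.read_text()

    def test_empty_predictions_empty_file(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_predictions([], "CEM", p)
        assert p.read_text() == ""

    def test_read_round_trip_and_task_detection(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_predictions(
            [Mention("D1", "T", 0, 7, "aspirin", "TRIVIAL", confidence=0.75)],
            "CEM",
            p,
        )
        (item,) = read_predictions(p)
        assert item.task == "CEM"
        assert item.key == ("T", 0, 7)
        assert item.rank == 1 and item.confidence == 0.75
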