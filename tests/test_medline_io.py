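import io

import pytest

from crthedge import (
    Citation,
    Corpus,
    GoldLabels,
    Identifiability,
    LabelRecord,
    ValidationError,
    read_labels,
    read_medline,
    write_labels,
    write_medline,
)
from crthedge.medline_io import MedlineParseError, corpus_to_text
from crthedge.simulate import GeneratorConfig, generate_corpus


def roundtrip(corpus: Corpus) -> Corpus:
    return read_medline(io.StringIO(corpus_to_text(corpus)))


class TestReadMedline:
    def test_empty_stream_yields_empty_corpus(self):
        assert len(read_medline(io.StringIO(""))) == 0

    def test_basic_record_fields(self):
        text = (
            "PMID- 12345678\n"
            "TI  - A cluster randomised trial\n"
            "AB  - Background text\n"
            "      continued over two lines.\n"
            "JT  - Some Journal\n"
            "DP  - 2006 Mar\n"
            "MH  - Humans\n"
            "MH  - *Health Promotion/methods\n"
            "PT  - Journal Article\n"
            "PT  - Randomized Controlled Trial\n"
        )
        corpus = read_medline(io.StringIO(text))
        cit = corpus["12345678"]
        assert cit.title == "A cluster randomised trial"
        assert cit.abstract == "Background text continued over two lines."
        assert cit.mesh_terms == ["Humans", "*Health Promotion/methods"]
        assert "Randomized Controlled Trial" in cit.pub_types
        assert cit.year == 2006

    def test_unpadded_tags_accepted(self):
        text = "PMID- 12345678\nTI- Short title\nPT- Randomized Controlled Trial\n"
        corpus = read_medline(io.StringIO(text))
        cit = corpus["12345678"]
        assert cit.title == "Short title"
        assert cit.pub_types == ["Randomized Controlled Trial"]

    def test_missing_abstract_yields_empty_string(self):
        corpus = read_medline(io.StringIO("PMID- 12345678\nTI  - Title only\n"))
        assert corpus["12345678"].abstract == ""

    def test_malformed_line_names_line_number(self):
        text = "PMID- 12345678\nTI  - Title\n???bad line\n"
        with pytest.raises(MedlineParseError, match="line 3"):
            read_medline(io.StringIO(text))

    def test_duplicate_uid_rejected(self):
        text = "PMID- 12345678\nTI  - One\n\nPMID- 12345678\nTI  - Two\n"
        with pytest.raises(ValidationError, match="12345678"):
            read_medline(io.StringIO(text))

    def test_noncanonical_uid_warns_but_parses(self):
        with pytest.warns(UserWarning, match="8-digit"):
            corpus = read_medline(io.StringIO("PMID- abc\nTI  - Title\n"))
        assert corpus["abc"].title == "Title"


class TestWriteMedline:
    def test_empty_corpus_writes_nothing(self):
        buf = io.StringIO()
        assert write_medline(Corpus(), buf) == 0
        assert buf.getvalue() == ""

    def test_single_record_has_one_uid_line(self):
        corpus = Corpus([Citation(uid="12345678", title="T")])
        text = corpus_to_text(corpus)
        assert text.count("PMID") == 1

    def test_handwritten_roundtrip(self, tiny_corpus):
        assert roundtrip(tiny_corpus) == tiny_corpus

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_corpus_roundtrip(self, seed):
        corpus, _ = generate_corpus(
            GeneratorConfig(n_articles=50, crt_prevalence=0.3, seed=seed)
        )
        again = roundtrip(corpus)
        assert again == corpus
        assert len(again) == 50

    def test_biopython_reads_our_output(self, tiny_corpus):
        """Cross-check the writer against an independent parser."""
        Medline = pytest.importorskip("Bio.Medline")
        records = list(Medline.parse(io.StringIO(corpus_to_text(tiny_corpus))))
        assert len(records) == len(tiny_corpus)
        for rec, cit in zip(records, tiny_corpus):
            assert rec["PMID"] == cit.uid
            assert rec["TI"] == cit.title
            if cit.abstract:
                assert rec["AB"] == cit.abstract
            assert rec.get("MH", []) == cit.mesh_terms
            assert rec.get("PT", []) == cit.pub_types


class TestLabels:
    def test_read_basic_rows(self):
        text = (
            "uid,is_crt,identifiability,year\n"
            "12345678,true,CLEAR,2006\n"
            "12345679,false,,2006\n"
        )
        labels = read_labels(io.StringIO(text))
        assert labels["12345678"].identifiability is Identifiability.CLEAR
        assert labels["12345679"].is_crt is False
        assert labels["12345679"].identifiability is Identifiability.NA

    def test_tab_delimited_accepted(self):
        text = "uid\tis_crt\tidentifiability\tyear\n12345678\ttrue\tUNIT\t2003\n"
        labels = read_labels(io.StringIO(text))
        assert labels["12345678"].identifiability is Identifiability.UNIT

    def test_unknown_class_token_rejected(self):
        text = "uid,is_crt,identifiability,year\n12345678,true,FUZZY,2006\n"
        with pytest.raises(ValidationError, match="FUZZY"):
            read_labels(io.StringIO(text))

    def test_non_crt_with_class_rejected(self):
        text = "uid,is_crt,identifiability,year\n12345678,false,CLEAR,2006\n"
        with pytest.raises(ValidationError):
            read_labels(io.StringIO(text))

    def test_crt_without_class_rejected(self):
        text = "uid,is_crt,identifiability,year\n12345678,true,,2006\n"
        with pytest.raises(ValidationError):
            read_labels(io.StringIO(text))

    def test_roundtrip(self, gold_labels):
        buf = io.StringIO()
        write_labels(gold_labels, buf)
        buf.seek(0)
        again = read_labels(buf)
        assert len(again) == len(gold_labels)
        assert again.class_counts() == gold_labels.class_counts()

    def test_gold_standard_class_counts(self, gold_labels):
        counts = gold_labels.class_counts()
        assert counts[Identifiability.CLEAR] == 78
        assert counts[Identifiability.UNIT] == 46
        assert counts[Identifiability.NONE] == 38
        assert len(gold_labels.crt_uids()) == 162

    def test_unmatched_labels_are_reported(self, tiny_corpus):
        labels = GoldLabels()
        labels.add("11111111", LabelRecord(True, Identifiability.CLEAR, 2005))
        labels.add("99999999", LabelRecord(False, Identifiability.NA, 2005))
        assert labels.check_against(tiny_corpus) == ["99999999"]
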