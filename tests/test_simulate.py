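import io
import math

import numpy as np
import pytest

from crthedge import (
    GeneratorConfig,
    Identifiability,
    ValidationError,
    classify_identifiability,
    generate_corpus,
    sample_citation_text,
)
from crthedge.medline_io import corpus_to_text, write_labels
from crthedge.simulate import DEFAULT_PHRASE_BANK


def labels_to_text(labels) -> str:
    buf = io.StringIO()
    write_labels(labels, buf)
    return buf.getvalue()


class TestDeterminism:
    def test_same_seed_same_bytes(self):
        cfg = GeneratorConfig(n_articles=300, crt_prevalence=0.1, seed=7)
        c1, l1 = generate_corpus(cfg)
        c2, l2 = generate_corpus(cfg)
        assert corpus_to_text(c1) == corpus_to_text(c2)
        assert labels_to_text(l1) == labels_to_text(l2)

    def test_different_seed_different_corpus(self):
        a, _ = generate_corpus(GeneratorConfig(n_articles=200, seed=1))
        b, _ = generate_corpus(GeneratorConfig(n_articles=200, seed=2))
        assert corpus_to_text(a) != corpus_to_text(b)


class TestConfig:
    def test_zero_prevalence_gives_no_crts(self):
        _, labels = generate_corpus(
            GeneratorConfig(n_articles=200, crt_prevalence=0.0, seed=3)
        )
        assert len(labels.crt_uids()) == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_articles": 0},
            {"crt_prevalence": 1.5},
            {"pt_tag_sensitivity": -0.1},
            {"noncrt_mix": (0.5, 0.5, 0.5)},
            {"crt_year_weights": (1.0,)},
            {"clear_prob_by_year": {2000: 0.5}},
        ],
    )
    def test_invalid_config_rejected_before_generation(self, kwargs):
        with pytest.raises(ValidationError):
            GeneratorConfig(**kwargs).validate()

    def test_dict_roundtrip(self):
        cfg = GeneratorConfig(n_articles=123, seed=9)
        again = GeneratorConfig.from_dict(cfg.to_dict())
        assert again == cfg


class TestStatisticalStructure:
    @pytest.fixture(scope="class")
    @staticmethod
    def big():
        cfg = GeneratorConfig(n_articles=20000, seed=42)
        corpus, labels = generate_corpus(cfg)
        return cfg, corpus, labels

    def test_prevalence_within_three_sigma(self, big):
        cfg, _, labels = big
        n, p = cfg.n_articles, cfg.crt_prevalence
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(len(labels.crt_uids()) - n * p) <= 3 * sigma

    def test_pt_tag_sensitivity_within_three_sigma(self, big):
        cfg, corpus, labels = big
        crts = labels.crt_uids()
        tagged = sum(
            1 for u in crts if "Randomized Controlled Trial" in corpus[u].pub_types
        )
        p = cfg.pt_tag_sensitivity
        sigma = math.sqrt(len(crts) * p * (1 - p))
        assert abs(tagged - len(crts) * p) <= 3 * sigma

    def test_identifiability_class_proportions_within_three_sigma(self, big):
        cfg, _, labels = big
        counts = labels.class_counts()
        n_crt = sum(counts.values())
        weights = np.asarray(cfg.crt_year_weights, float)
        weights = weights / weights.sum()
        p_clear = float(
            sum(w * cfg.clear_prob_by_year[y] for w, y in zip(weights, cfg.years))
        )
        expected = {
            Identifiability.CLEAR: p_clear,
            Identifiability.UNIT: (1 - p_clear) * cfg.unit_share_of_unclear,
            Identifiability.NONE: (1 - p_clear) * (1 - cfg.unit_share_of_unclear),
        }
        for cls, p in expected.items():
            sigma = math.sqrt(n_crt * p * (1 - p))
            assert abs(counts[cls] - n_crt * p) <= 3 * sigma, cls

    def test_clear_fraction_rises_over_time(self, big):
        _, _, labels = big
        from crthedge import aggregate_trend, trend_test

        table = aggregate_trend(labels)
        assert trend_test(table, "cochran-armitage").statistic > 3


class TestLabelTextConsistency:
    def test_every_crt_classifies_as_labelled(self):
        corpus, labels = generate_corpus(
            GeneratorConfig(n_articles=3000, crt_prevalence=0.1, seed=5)
        )
        crts = 0
        for uid, rec in labels.items():
            if not rec.is_crt:
                continue
            crts += 1
            assert classify_identifiability(corpus[uid]) is rec.identifiability, uid
        assert crts > 200

    def test_labels_cover_whole_corpus(self):
        corpus, labels = generate_corpus(GeneratorConfig(n_articles=150, seed=6))
        assert len(labels) == len(corpus)
        assert labels.check_against(corpus) == []


class TestPhraseBank:
    def test_clear_samples_classify_clear(self, rng):
        for _ in range(50):
            title, abstract = sample_citation_text(
                True, Identifiability.CLEAR, 2005, rng
            )
            from crthedge import Citation

            c = Citation(uid="12345678", title=title, abstract=abstract)
            assert classify_identifiability(c) is Identifiability.CLEAR

    def test_unit_samples_classify_unit(self, rng):
        from crthedge import Citation

        for _ in range(50):
            title, abstract = sample_citation_text(
                True, Identifiability.UNIT, 2005, rng
            )
            c = Citation(uid="12345678", title=title, abstract=abstract)
            assert classify_identifiability(c) is Identifiability.UNIT

    def test_none_samples_classify_none(self, rng):
        from crthedge import Citation

        for _ in range(50):
            title, abstract = sample_citation_text(
                True, Identifiability.NONE, 2005, rng, with_intervention=True
            )
            c = Citation(uid="12345678", title=title, abstract=abstract)
            assert classify_identifiability(c) is Identifiability.NONE

    def test_distractor_templates_are_never_clear(self, rng):
        from crthedge import Citation

        cfg = GeneratorConfig(irt_distractor_rate=1.0)
        for _ in range(30):
            title, abstract = sample_citation_text(
                False, Identifiability.NA, 2005, rng, cfg, subclass="irt"
            )
            c = Citation(uid="12345678", title=title, abstract=abstract)
            assert classify_identifiability(c) is not Identifiability.CLEAR

    def test_false_clear_sentences_do_classify_clear(self):
        from crthedge import Citation

        for sentence in DEFAULT_PHRASE_BANK.false_clear:
            c = Citation(uid="12345678", title="t", abstract=sentence)
            assert classify_identifiability(c) is Identifiability.CLEAR
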