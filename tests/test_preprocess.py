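"""Cleaning, spell correction, stemming and corpus construction."""

import math

import numpy as np
import pytest

from pxinsight import (
    CorpusEmptyError,
    DictionaryResource,
    PorterStemmer,
    augment_dictionary,
    build_corpus,
    clean_text,
    correct_spelling,
    default_dictionary,
    tokenize,
)
from pxinsight.preprocess import get_stemmer, preprocess_response
import pxinsight.resources as resources


# ---------------------------------------------------------------------------
# cleaning


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("", ""),
        ("Good care!!! :-)", "good care"),
        ("GREAT   stay\t\nreally", "great stay really"),
        ("x-ray done, and don't worry", "x-ray done and don't worry"),
        ("--- ??? 123", ""),
    ],
)
def test_clean_text_rules(raw, expected):
    assert clean_text(raw) == expected


def test_clean_text_expands_abbreviations():
    assert clean_text("seen by the dr.", {"dr": "doctor"}) == "seen by the doctor"
    assert tokenize("ER visit", {"er": "emergency"}) == ["emergency", "visit"]


def test_clean_text_idempotent_on_examples():
    for raw in ["Good care!!! :-)", "x-ray done, and don't worry", "", "plain words"]:
        once = clean_text(raw)
        assert clean_text(once) == once


# ---------------------------------------------------------------------------
# spelling


def test_known_word_unchanged():
    d = DictionaryResource({"doctor": 500, "nurse": 300})
    assert correct_spelling("doctor", d) == "doctor"


def test_single_edit_correction_picks_highest_frequency():
    d = DictionaryResource({"doctor": 500, "docker": 100})
    assert correct_spelling("doctr", d) == "doctor"  # both are 1 edit away


def test_two_edit_fallback_and_no_candidate():
    d = DictionaryResource({"doctor": 500})
    assert correct_spelling("dcto", d) == "doctor"  # distance 2
    assert correct_spelling("xqzv", d) == "xqzv"
    with pytest.raises(ValueError):
        correct_spelling("", d)


def test_dictionary_rejects_nonpositive_frequency():
    with pytest.raises(ValueError):
        DictionaryResource({"bad": 0})


def test_augment_dictionary_threshold():
    d = DictionaryResource({"doctor": 500})
    added = augment_dictionary(d, {"stent": 150, "rare": 20, "doctor": 999}, threshold=100)
    assert added == ["stent"]
    assert "stent" in d and "rare" not in d


# ---------------------------------------------------------------------------
# stemming (classic algorithm pairs, hand-derived from the published rules)


@pytest.mark.parametrize(
    "word, stem",
    [
        ("caresses", "caress"),
        ("ponies", "poni"),
        ("ties", "ti"),
        ("caress", "caress"),
        ("cats", "cat"),
        ("feed", "feed"),
        ("agreed", "agre"),
        ("plastered", "plaster"),
        ("motoring", "motor"),
        ("sing", "sing"),
        ("troubled", "troubl"),
        ("hopping", "hop"),
        ("tanned", "tan"),
        ("falling", "fall"),
        ("hissing", "hiss"),
        ("failing", "fail"),
        ("filing", "file"),
        ("happy", "happi"),
        ("sky", "sky"),
        ("relational", "relat"),
        ("generalization", "gener"),
        ("oscillators", "oscil"),
        ("studying", "studi"),
        ("nurse", "nurs"),
        ("nursing", "nurs"),
        ("the", "the"),
    ],
)
def test_porter_classic_pairs(word, stem):
    assert PorterStemmer().stem(word) == stem


def test_unknown_stemmer_rejected():
    with pytest.raises(ValueError):
        get_stemmer("lancaster")


# ---------------------------------------------------------------------------
# corpus construction


def toy_corpus(**kwargs):
    docs = [
        ("r1", "Q1", "pain pain bed"),
        ("r2", "Q1", "bed"),
        ("r3", "Q1", "nurse kind"),
    ]
    d = DictionaryResource({"pain": 10, "bed": 9, "nurse": 8, "kind": 7})
    defaults = dict(
        stopwords=frozenset(), stemmer="identity", min_word_count=1,
        dictionary=d, abbreviation_map={},
    )
    defaults.update(kwargs)
    return build_corpus(docs, **defaults)


def reference_tfidf(counts):
    """Independent implementation of the documented convention:
    idf = ln((1+N)/(1+df)) + 1, L2-normalized rows."""
    counts = np.asarray(counts, dtype=float)
    n_docs = counts.shape[0]
    df = (counts > 0).sum(axis=0)
    idf = np.array([math.log((1 + n_docs) / (1 + d)) + 1.0 for d in df])
    raw = counts * idf
    out = np.zeros_like(raw)
    for i, row in enumerate(raw):
        norm = math.sqrt(float((row**2).sum()))
        if norm > 0:
            out[i] = row / norm
    return out


def test_tfidf_matches_reference_formula():
    corpus = toy_corpus()
    assert corpus.vocabulary == ["bed", "kind", "nurse", "pain"]
    expected = reference_tfidf(corpus.raw_counts.toarray())
    np.testing.assert_allclose(corpus.weights.toarray(), expected, atol=1e-10)


def test_frequency_floor_drops_rare_terms():
    docs = [("r", "Q1", "ward " * 25 + "pain " * 19)]
    d = DictionaryResource({"ward": 10, "pain": 10})
    corpus = build_corpus(
        [docs[0]], stopwords=frozenset(), stemmer="identity",
        min_word_count=20, dictionary=d, abbreviation_map={},
    )
    assert corpus.vocabulary == ["ward"]  # 19 occurrences < 20 -> dropped


def test_stopword_only_document_gets_zero_row():
    docs = [
        ("r1", "Q1", "pain pain"),
        ("r2", "Q1", "the the the"),
    ]
    d = DictionaryResource({"pain": 10, "the": 99})
    corpus = build_corpus(
        docs, stopwords=frozenset({"the"}), stemmer="identity",
        min_word_count=1, dictionary=d, abbreviation_map={},
    )
    row = corpus.weights.toarray()[1]
    assert (row == 0).all()
    assert corpus.doc_ids[1] == ("r2", "Q1")  # still present


def test_all_empty_corpus_raises():
    d = DictionaryResource({"the": 99})
    with pytest.raises(CorpusEmptyError):
        build_corpus(
            [("r1", "Q1", "the the")], stopwords=frozenset({"the"}),
            stemmer="identity", min_word_count=1, dictionary=d, abbreviation_map={},
        )


def test_weights_nonnegative_and_absent_terms_zero():
    corpus = toy_corpus()
    w = corpus.weights.toarray()
    assert (w >= 0).all()
    c = corpus.raw_counts.toarray()
    assert (w[c == 0] == 0).all()


def test_ubiquitous_term_gets_minimal_idf():
    docs = [
        ("r1", "Q1", "care pain"),
        ("r2", "Q1", "care bed"),
        ("r3", "Q1", "care nurse"),
    ]
    d = DictionaryResource({w: 10 for w in ["care", "pain", "bed", "nurse"]})
    corpus = build_corpus(
        docs, stopwords=frozenset(), stemmer="identity",
        min_word_count=1, dictionary=d, abbreviation_map={},
    )
    counts = corpus.raw_counts.toarray()
    n_docs = counts.shape[0]
    df = (counts > 0).sum(axis=0)
    idf = np.log((1 + n_docs) / (1 + df)) + 1
    assert idf[corpus.vocabulary.index("care")] == idf.min()


def test_vocabulary_shrinks_along_chain():
    """Spell correction and stemming can only merge forms, never split them."""
    table_rows = [
        ("r1", "Q1", "the nurses were caring and the doctoor was kind"),
        ("r2", "Q1", "nursing care by a kind doctor"),
        ("r3", "Q1", "carring nurse kind doctors"),
    ]
    dictionary = default_dictionary()
    raw = {t for _, _, text in table_rows for t in tokenize(text)}
    corrected = {correct_spelling(t, dictionary) for t in raw}
    stemmer = PorterStemmer()
    stemmed = {stemmer.stem(t) for t in corrected}
    assert len(corrected) <= len(raw)
    assert len(stemmed) <= len(corrected)


def test_chain_idempotent_with_identity_stemmer():
    """Re-preprocessing the clean token stream (dictionary augmented with the
    corpus vocabulary) changes nothing when stemming is the identity."""
    corpus = toy_corpus()
    d = DictionaryResource({"pain": 10, "bed": 9, "nurse": 8, "kind": 7})
    augment_dictionary(d, corpus.term_totals, threshold=0)
    stemmer = get_stemmer("identity")
    for resp in corpus.responses:
        again = preprocess_response(
            resp.respondent_id, resp.question_id, " ".join(resp.clean_tokens),
            dictionary=d, stemmer=stemmer,
            stopword_set=frozenset(), stemmed_stopwords=frozenset(),
            abbreviation_map={},
        )
        assert again.clean_tokens == resp.clean_tokens


def test_min_word_count_validation():
    with pytest.raises(ValueError):
        toy_corpus(min_word_count=0)
    with pytest.raises(ValueError):
        build_corpus([])


def test_default_dictionary_contains_resource_words():
    d = default_dictionary()
    assert "doctor" in d and "not" in d and "friendly" in d
    assert all(f > 0 for f in d.words.values())
    # stopwords sit in a higher frequency band than domain nouns
    assert d.frequency("the") > d.frequency("doctor")


def test_resource_loaders_are_consistent(lexicon):
    assert resources.nouns() >= {"nurse", "doctor", "room"}
    assert "not" in resources.negations()
    assert resources.intensifiers()["extremely"] > 1
    assert set(resources.sentiment_overrides()) == {
        "disease", "ill", "painful", "nauseous",
        "help", "remarkable", "waiting", "complicated",
    }
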