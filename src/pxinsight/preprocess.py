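"""Text reduction chain: cleaning, spell correction, stemming, filtering, tf-idf.

The chain mirrors how short survey answers are condensed before topic
modelling: clean the raw string, correct spelling against a frequency
dictionary (Norvig-style), stem, drop stopwords, drop corpus-infrequent
terms, and weight the survivors with tf-idf.  Each survey question is
modelled separately, so corpora are built per question.

tf-idf convention (documented, since several exist): smoothed
``idf = ln((1 + N) / (1 + df)) + 1`` with L2 row normalization — the
scikit-learn default, computed here by :class:`~sklearn.feature_extraction.text.TfidfTransformer`.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer

from . import resources

QUESTIONS = ("Q1", "Q2")

_ALPHABET = "abcdefghijklmnopqrstuvwxyz'-"
_NON_LETTER = re.compile(r"[^a-z'\-]+")
_DANGLING = re.compile(r"(?<![a-z])['\-]|['\-](?![a-z])")


class CorpusEmptyError(ValueError):
    """Raised when no document survives the reduction chain."""


# ---------------------------------------------------------------------------
# cleaning


def clean_text(raw: str, abbreviation_map: dict[str, str] | None = None) -> str:
    """Lowercase, strip non-letters (keeping intra-word hyphens/apostrophes),
    expand abbreviations, collapse whitespace."""
    text = raw.lower()
    text = _NON_LETTER.sub(" ", text)
    while _DANGLING.search(text):
        text = _DANGLING.sub(" ", text)
    tokens = text.split()
    if abbreviation_map:
        tokens = [abbreviation_map.get(t, t) for t in tokens]
    return " ".join(tokens)


def tokenize(raw: str, abbreviation_map: dict[str, str] | None = None) -> list[str]:
    return clean_text(raw, abbreviation_map).split()


# ---------------------------------------------------------------------------
# spelling


@dataclass
class DictionaryResource:
    """Word -> frequency map used by the spell corrector.

    Domain-specific words and abbreviation expansions can be merged in with
    :meth:`add_words`; see :func:`augment_dictionary` for the corpus-driven
    frequent-word rule.
    """

    words: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for w, f in self.words.items():
            if f <= 0:
                raise ValueError(f"dictionary frequency must be positive: {w!r} -> {f}")

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def frequency(self, word: str) -> int:
        return self.words.get(word, 0)

    def add_words(self, frequencies: dict[str, int]) -> None:
        for w, f in frequencies.items():
            if f <= 0:
                raise ValueError(f"dictionary frequency must be positive: {w!r} -> {f}")
            self.words[w] = max(self.words.get(w, 0), f)


def default_dictionary() -> DictionaryResource:
    return DictionaryResource(resources.dictionary_word_frequencies())


def augment_dictionary(
    dictionary: DictionaryResource, corpus_counts: dict[str, int], threshold: int = 100
) -> list[str]:
    """Lift corpus tokens occurring more than ``threshold`` times into the
    dictionary (domain-specific vocabulary rule).  Returns the added words."""
    added = [w for w, c in corpus_counts.items() if c > threshold and w not in dictionary]
    dictionary.add_words({w: corpus_counts[w] for w in added})
    return added


def _edits1(word: str) -> set[str]:
    splits = [(word[:i], word[i:]) for i in range(len(word) + 1)]
    deletes = [a + b[1:] for a, b in splits if b]
    transposes = [a + b[1] + b[0] + b[2:] for a, b in splits if len(b) > 1]
    substitutes = [a + c + b[1:] for a, b in splits if b for c in _ALPHABET]
    inserts = [a + c + b for a, b in splits for c in _ALPHABET]
    return set(deletes + transposes + substitutes + inserts)


def correct_spelling(token: str, dictionary: DictionaryResource) -> str:
    """Norvig-style correction: known word unchanged, else the
    highest-frequency dictionary word at edit distance 1, else 2, else the
    token itself.  Frequency ties break lexicographically."""
    if not token:
        raise ValueError("cannot spell-correct an empty token")
    if token in dictionary:
        return token
    e1 = _edits1(token)
    for candidates in (e1, {e for w in e1 for e in _edits1(w)}):
        known = [w for w in candidates if w in dictionary]
        if known:
            return min(known, key=lambda w: (-dictionary.frequency(w), w))
    return token


# ---------------------------------------------------------------------------
# stemming (classic Porter algorithm)


class PorterStemmer:
    """The 1980 Porter suffix-stripping algorithm (original rule set)."""

    def _cons(self, w: str, i: int) -> bool:
        c = w[i]
        if c in "aeiou":
            return False
        if c == "y":
            return i == 0 or not self._cons(w, i - 1)
        return True

    def _measure(self, stem: str) -> int:
        # number of VC sequences in [C](VC)^m[V]
        m, prev_vowel = 0, False
        for i in range(len(stem)):
            v = not self._cons(stem, i)
            if not v and prev_vowel:
                m += 1
            prev_vowel = v
        return m

    def _has_vowel(self, stem: str) -> bool:
        return any(not self._cons(stem, i) for i in range(len(stem)))

    def _double_cons(self, w: str) -> bool:
        return len(w) >= 2 and w[-1] == w[-2] and self._cons(w, len(w) - 1)

    def _cvc(self, w: str) -> bool:
        if len(w) < 3:
            return False
        return (
            self._cons(w, len(w) - 3)
            and not self._cons(w, len(w) - 2)
            and self._cons(w, len(w) - 1)
            and w[-1] not in "wxy"
        )

    def _rule_set(self, word: str, rules, condition) -> str:
        # longest matching suffix is the only one considered
        for suffix, repl in sorted(rules, key=lambda r: -len(r[0])):
            if word.endswith(suffix):
                stem = word[: len(word) - len(suffix)]
                if condition(stem, suffix):
                    return stem + repl
                return word
        return word

    def stem(self, word: str) -> str:
        if len(word) <= 2:
            return word
        w = word

        # step 1a
        w = self._rule_set(
            w,
            [("sses", "ss"), ("ies", "i"), ("ss", "ss"), ("s", "")],
            lambda s, suf: True,
        )

        # step 1b
        if w.endswith("eed"):
            if self._measure(w[:-3]) > 0:
                w = w[:-1]
        else:
            stripped = None
            if w.endswith("ed") and self._has_vowel(w[:-2]):
                stripped = w[:-2]
            elif w.endswith("ing") and self._has_vowel(w[:-3]):
                stripped = w[:-3]
            if stripped is not None:
                w = stripped
                if w.endswith(("at", "bl", "iz")):
                    w += "e"
                elif self._double_cons(w) and w[-1] not in "lsz":
                    w = w[:-1]
                elif self._measure(w) == 1 and self._cvc(w):
                    w += "e"

        # step 1c
        if w.endswith("y") and self._has_vowel(w[:-1]):
            w = w[:-1] + "i"

        m_pos = lambda s, suf: self._measure(s) > 0
        m_gt1 = lambda s, suf: self._measure(s) > 1

        # step 2
        w = self._rule_set(
            w,
            [
                ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
                ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
                ("alli", "al"), ("entli", "ent"), ("eli", "e"),
                ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
                ("ator", "ate"), ("alism", "al"), ("iveness", "ive"),
                ("fulness", "ful"), ("ousness", "ous"), ("aliti", "al"),
                ("iviti", "ive"), ("biliti", "ble"),
            ],
            m_pos,
        )

        # step 3
        w = self._rule_set(
            w,
            [
                ("icate", "ic"), ("ative", ""), ("alize", "al"),
                ("iciti", "ic"), ("ical", "ic"), ("ful", ""), ("ness", ""),
            ],
            m_pos,
        )

        # step 4
        w = self._rule_set(
            w,
            [
                ("al", ""), ("ance", ""), ("ence", ""), ("er", ""),
                ("ic", ""), ("able", ""), ("ible", ""), ("ant", ""),
                ("ement", ""), ("ment", ""), ("ent", ""), ("ion", ""),
                ("ou", ""), ("ism", ""), ("ate", ""), ("iti", ""),
                ("ous", ""), ("ive", ""), ("ize", ""),
            ],
            lambda s, suf: self._measure(s) > 1
            and (suf != "ion" or (s and s[-1] in "st")),
        )

        # step 5a
        if w.endswith("e"):
            stem = w[:-1]
            m = self._measure(stem)
            if m > 1 or (m == 1 and not self._cvc(stem)):
                w = stem

        # step 5b
        if self._measure(w) > 1 and self._double_cons(w) and w.endswith("l"):
            w = w[:-1]

        return w

    __call__ = stem


class IdentityStemmer:
    def stem(self, word: str) -> str:
        return word

    __call__ = stem


STEMMERS = {"porter": PorterStemmer, "identity": IdentityStemmer}


def get_stemmer(name: str):
    try:
        return STEMMERS[name]()
    except KeyError:
        raise ValueError(f"unknown stemmer {name!r}; choose from {sorted(STEMMERS)}")


# ---------------------------------------------------------------------------
# corpus


@dataclass
class SurveyResponse:
    """One respondent's answer to one question, raw plus preprocessed.

    ``clean_tokens`` are the stems surviving the full chain; ``surface_tokens``
    are the aligned spell-corrected (unstemmed) forms, kept so that n-gram
    labels can be displayed readably.
    """

    respondent_id: str
    question_id: str
    raw_text: str
    clean_tokens: list[str] = field(default_factory=list)
    surface_tokens: list[str] = field(default_factory=list)

    @property
    def doc_id(self) -> tuple[str, str]:
        return (self.respondent_id, self.question_id)


@dataclass
class Corpus:
    """Vocabulary and tf-idf weights of one question's responses."""

    vocabulary: list[str]
    doc_ids: list[tuple[str, str]]
    weights: sp.csr_matrix          # tf-idf, rows L2-normalized (zero rows stay zero)
    raw_counts: sp.csr_matrix       # integer term counts, same shape
    responses: list[SurveyResponse]

    @property
    def term_totals(self) -> dict[str, int]:
        totals = np.asarray(self.raw_counts.sum(axis=0)).ravel()
        return dict(zip(self.vocabulary, totals.astype(int)))

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)


def preprocess_response(
    respondent_id: str,
    question_id: str,
    raw_text: str,
    *,
    dictionary: DictionaryResource,
    stemmer,
    stopword_set: frozenset[str],
    stemmed_stopwords: frozenset[str],
    abbreviation_map: dict[str, str] | None,
) -> SurveyResponse:
    """Run one document through clean -> spell-correct -> stem -> stopword
    filter.  The corpus-level frequency floor is applied later in
    :func:`build_corpus`."""
    resp = SurveyResponse(respondent_id, question_id, raw_text)
    for token in tokenize(raw_text, abbreviation_map):
        corrected = correct_spelling(token, dictionary)
        stem = stemmer.stem(corrected)
        if corrected in stopword_set or stem in stemmed_stopwords:
            continue
        resp.clean_tokens.append(stem)
        resp.surface_tokens.append(corrected)
    return resp


def build_corpus(
    responses,
    stopwords: frozenset[str] | None = None,
    stemmer="porter",
    min_word_count: int = 20,
    *,
    dictionary: DictionaryResource | None = None,
    abbreviation_map: dict[str, str] | None = None,
) -> Corpus:
    """Build one question-corpus from raw responses.

    ``responses`` is an iterable of (respondent_id, question_id, text) triples
    or :class:`SurveyResponse` objects (only ``raw_text`` is used).  Documents
    that end up token-less keep an all-zero row so no response is dropped.
    """
    if min_word_count < 1:
        raise ValueError("min_word_count must be >= 1")
    responses = list(responses)
    if not responses:
        raise ValueError("no responses given")

    if stopwords is None:
        stopwords = resources.stopwords()
    if isinstance(stemmer, str):
        stemmer = get_stemmer(stemmer)
    if dictionary is None:
        dictionary = default_dictionary()
    if abbreviation_map is None:
        abbreviation_map = resources.abbreviations()
    stemmed_stop = frozenset(stemmer.stem(w) for w in stopwords)

    docs: list[SurveyResponse] = []
    for r in responses:
        if isinstance(r, SurveyResponse):
            rid, qid, text = r.respondent_id, r.question_id, r.raw_text
        else:
            rid, qid, text = r
        docs.append(
            preprocess_response(
                rid, qid, text,
                dictionary=dictionary, stemmer=stemmer,
                stopword_set=stopwords, stemmed_stopwords=stemmed_stop,
                abbreviation_map=abbreviation_map,
            )
        )

    totals = Counter(t for d in docs for t in d.clean_tokens)
    kept = {t for t, c in totals.items() if c >= min_word_count}
    for d in docs:
        pairs = [(t, s) for t, s in zip(d.clean_tokens, d.surface_tokens) if t in kept]
        d.clean_tokens = [t for t, _ in pairs]
        d.surface_tokens = [s for _, s in pairs]

    vocabulary = sorted(kept)
    if not vocabulary:
        raise CorpusEmptyError(
            "every document is empty after stopword and frequency filtering"
        )
    index = {t: j for j, t in enumerate(vocabulary)}

    rows, cols, vals = [], [], []
    for i, d in enumerate(docs):
        for t, c in Counter(d.clean_tokens).items():
            rows.append(i)
            cols.append(index[t])
            vals.append(c)
    raw_counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(vocabulary)), dtype=np.float64
    )
    weights = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False).fit_transform(
        raw_counts
    )
    return Corpus(
        vocabulary=vocabulary,
        doc_ids=[d.doc_id for d in docs],
        weights=sp.csr_matrix(weights),
        raw_counts=raw_counts,
        responses=docs,
    )


def build_question_corpora(
    table,
    questions=QUESTIONS,
    **kwargs,
) -> dict[str, Corpus]:
    """Split a (respondent_id, question_id, text) table by question and build
    each corpus independently (each question gets its own model)."""
    corpora: dict[str, Corpus] = {}
    for q in questions:
        rows = [
            (str(r), str(q_), str(t))
            for r, q_, t in zip(table["respondent_id"], table["question_id"], table["text"])
            if q_ == q
        ]
        if rows:
            corpora[q] = build_corpus(rows, **kwargs)
    return corpora
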