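"""Seeded synthetic patient-experience surveys with known ground truth.

Real survey free text is rarely shareable, so every downstream stage is
exercised on generated data instead: each response mixes words from one
planted topic (disjoint noun sets), shared stopwords and one
polarity-consistent sentiment adjective; a configurable fraction of
responses is empty or stopword-only (these become unassignable), and
single-character typos emulate the misspellings the corrector must undo.

Defaults emulate the scale of short inpatient-survey answers: ~12 words per
answer (surveys of this kind average roughly 8-25), 6 planted topics of 10
nouns each, 5% typo rate, ~15% empty/stopword-only answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import resources
from .preprocess import PorterStemmer

_EDIT_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class GroundTruth:
    """What the generator planted, keyed by (respondent_id, question_id)."""

    planted_topic_count: int
    topic_word_sets: list[set]
    doc_topic: dict = field(default_factory=dict)
    doc_polarity: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for i in range(len(self.topic_word_sets)):
            for j in range(i + 1, len(self.topic_word_sets)):
                if self.topic_word_sets[i] & self.topic_word_sets[j]:
                    raise ValueError(f"topic word sets {i} and {j} overlap")

    def topics_for(self, doc_ids) -> list:
        return [self.doc_topic.get(tuple(d), "none") for d in doc_ids]

    def to_json(self, path) -> None:
        payload = {
            "planted_topic_count": self.planted_topic_count,
            "topic_word_sets": [sorted(s) for s in self.topic_word_sets],
            "doc_topic": {f"{r}|{q}": t for (r, q), t in self.doc_topic.items()},
            "doc_polarity": {f"{r}|{q}": p for (r, q), p in self.doc_polarity.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _unique_stem_pool(words: list[str]) -> list[str]:
    """Keep one word per Porter stem so planted topics stay disjoint after
    stemming (e.g. 'nurse'/'nursing' collapse to one stem)."""
    stemmer = PorterStemmer()
    seen, pool = set(), []
    for w in words:
        s = stemmer.stem(w)
        if s not in seen:
            seen.add(s)
            pool.append(w)
    return pool


def _typo(token: str, rng: np.random.Generator) -> str:
    ops = ["insert", "delete", "substitute", "transpose"]
    if len(token) < 2:
        ops = ["insert", "substitute"]
    op = ops[rng.integers(len(ops))]
    i = int(rng.integers(len(token)))
    c = _EDIT_ALPHABET[rng.integers(len(_EDIT_ALPHABET))]
    if op == "insert":
        return token[:i] + c + token[i:]
    if op == "delete":
        return token[:i] + token[i + 1 :]
    if op == "substitute":
        return token[:i] + c + token[i + 1 :]
    i = min(i, len(token) - 2)
    return token[:i] + token[i + 1] + token[i] + token[i + 2 :]


def generate_survey(
    n_docs: int,
    n_topics: int = 6,
    vocab_size: int = 60,
    mean_words: float = 12.0,
    typo_rate: float = 0.05,
    stopword_fraction: float = 0.35,
    empty_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a (respondent_id, question_id, text) table plus its truth.

    Questions alternate between Q1 ("what went remarkably well", mostly
    positive answers) and Q2 ("what did not go as well", mostly negative).
    Identical parameters and seed give byte-identical output.
    """
    if n_docs <= 0 or n_topics < 2 or vocab_size <= 0 or mean_words <= 0:
        raise ValueError("sizes must be positive and n_topics >= 2")
    if vocab_size < 10 * n_topics:
        raise ValueError("vocab_size must be at least 10 x n_topics")
    for name, p in [("typo_rate", typo_rate), ("stopword_fraction", stopword_fraction),
                    ("empty_fraction", empty_fraction)]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")

    rng = np.random.default_rng(seed)
    noun_pool = _unique_stem_pool(resources.noun_list())
    if vocab_size > len(noun_pool):
        raise ValueError(f"vocab_size > available noun pool ({len(noun_pool)})")
    chosen = [noun_pool[i] for i in rng.permutation(len(noun_pool))[:vocab_size]]
    per_topic = vocab_size // n_topics
    topic_words = [chosen[t * per_topic : (t + 1) * per_topic] for t in range(n_topics)]

    lex = resources.sentiment_lexicon_values()
    adj = {
        "positive": sorted(w for w, v in lex.items() if v > 0.1),
        "negative": sorted(w for w, v in lex.items() if v < 0.0),
        "neutral": sorted(w for w, v in lex.items() if 0.0 <= v <= 0.1),
    }
    intensifier_pool = sorted(resources.intensifiers())
    stopword_pool = sorted(resources.stopwords())

    truth = GroundTruth(
        planted_topic_count=n_topics,
        topic_word_sets=[set(ws) for ws in topic_words],
        seed=seed,
    )
    truth.validate()

    pick = lambda pool: pool[rng.integers(len(pool))]
    rows = []
    for i in range(n_docs):
        rid, qid = f"r{i:05d}", "Q1" if i % 2 == 0 else "Q2"
        if rng.random() < empty_fraction:
            tokens = [] if rng.random() < 0.5 else [
                pick(stopword_pool) for _ in range(int(rng.integers(1, 4)))
            ]
            truth.doc_topic[(rid, qid)] = "none"
            truth.doc_polarity[(rid, qid)] = "neutral"
        else:
            topic = int(rng.integers(n_topics))
            probs = [0.7, 0.2, 0.1] if qid == "Q1" else [0.1, 0.2, 0.7]
            polarity = ["positive", "neutral", "negative"][
                int(rng.choice(3, p=[probs[0], probs[1], probs[2]]))
            ]
            length = 1 + int(rng.poisson(max(mean_words - 1.0, 0.0)))
            tokens = [pick(topic_words[topic])]
            for _ in range(length - 1):
                if rng.random() < stopword_fraction:
                    tokens.append(pick(stopword_pool))
                else:
                    tokens.append(pick(topic_words[topic]))
            phrase = [pick(adj[polarity])]
            if polarity != "neutral" and rng.random() < 0.2:
                phrase = [pick(intensifier_pool)] + phrase
            at = int(rng.integers(len(tokens) + 1))
            tokens = tokens[:at] + phrase + tokens[at:]
            truth.doc_topic[(rid, qid)] = topic
            truth.doc_polarity[(rid, qid)] = polarity
        if typo_rate > 0:
            tokens = [
                _typo(t, rng) if rng.random() < typo_rate else t for t in tokens
            ]
            tokens = [t for t in tokens if t]
        rows.append((rid, qid, " ".join(tokens)))

    table = pd.DataFrame(rows, columns=["respondent_id", "question_id", "text"])
    return table, truth


def generator_vocabulary() -> set[str]:
    """All words the generator can emit (before typo corruption)."""
    lex = resources.sentiment_lexicon_values()
    return (
        set(_unique_stem_pool(resources.noun_list()))
        | set(lex)
        | set(resources.intensifiers())
        | set(resources.stopwords())
    )


def generate_rater_panel(
    true_labels,
    n_raters: int = 3,
    error_rate: float = 0.1,
    seed: int = 0,
    categories=None,
) -> pd.DataFrame:
    """Simulate human raters: each rating equals the true label with
    probability ``1 - error_rate``, otherwise a uniformly chosen other
    category.  Returns a subjects x raters table."""
    true_labels = list(true_labels)
    if not true_labels:
        raise ValueError("true_labels must be non-empty")
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be a probability")
    if categories is None:
        categories = sorted(set(true_labels))
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")

    rng = np.random.default_rng(seed)
    data = {}
    for r in range(n_raters):
        col = []
        for label in true_labels:
            if rng.random() < error_rate:
                others = [c for c in categories if c != label]
                col.append(others[rng.integers(len(others))])
            else:
                col.append(label)
        data[f"rater_{r}"] = col
    return pd.DataFrame(data, index=pd.RangeIndex(len(true_labels), name="subject_id"))
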