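"""N-gram subtopics: contextualize one-word topic labels.

A one-word topic ("discharge") is too coarse to act on, so the responses
assigned to each topic are mined for their most common 2-, 3- and 4-grams;
only n-grams containing at least one noun are kept (interpretability), the
top 20 per topic become candidate subtopic labels, and every response is
matched to its best-fitting candidate by fuzzy string matching (best
Levenshtein similarity between the candidate and any contiguous token
window of the response, partial-ratio style).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import edlib

logger = logging.getLogger(__name__)

DEFAULT_N_VALUES = (2, 3, 4)


@dataclass
class NgramLabel:
    topic_index: int
    text: str                      # space-joined (stemmed) token sequence
    n: int
    frequency: int = 0             # responses matched to it
    count: int = 0                 # raw occurrence count in the topic's docs
    display: str = ""              # most frequent surface form

    def __post_init__(self):
        if not 2 <= self.n <= 4:
            raise ValueError("n must be in {2, 3, 4}")
        if not self.display:
            self.display = self.text


def extract_ngrams(token_sequences, n_values=DEFAULT_N_VALUES) -> Counter:
    """Count all contiguous n-token windows (space-joined keys)."""
    counts: Counter = Counter()
    for tokens in token_sequences:
        for n in n_values:
            for i in range(len(tokens) - n + 1):
                counts[" ".join(tokens[i : i + n])] += 1
    return counts


def surface_forms(stem_sequences, surface_sequences, n_values=DEFAULT_N_VALUES) -> dict[str, str]:
    """Most frequent surface rendering of each stem n-gram (for display)."""
    variants: dict[str, Counter] = {}
    for stems, surfaces in zip(stem_sequences, surface_sequences):
        for n in n_values:
            for i in range(len(stems) - n + 1):
                key = " ".join(stems[i : i + n])
                variants.setdefault(key, Counter())[" ".join(surfaces[i : i + n])] += 1
    return {
        key: min(c.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        for key, c in variants.items()
    }


def top_noun_ngrams(
    counts,
    noun_test,
    k: int = 20,
    topic_index: int = 0,
    surface_map: dict[str, str] | None = None,
) -> list[NgramLabel]:
    """Keep noun-containing n-grams, order by count desc (ties: longer n,
    then lexicographic), return the first k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = [
        (text, cnt)
        for text, cnt in counts.items()
        if any(noun_test(tok) for tok in text.split())
    ]
    if not kept:
        logger.warning("topic %d: no noun-containing n-grams", topic_index)
        return []
    kept.sort(key=lambda tc: (-tc[1], -len(tc[0].split()), tc[0]))
    surface_map = surface_map or {}
    return [
        NgramLabel(
            topic_index=topic_index,
            text=text,
            n=len(text.split()),
            count=cnt,
            display=surface_map.get(text, text),
        )
        for text, cnt in kept[:k]
    ]


def _similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity on a 0-100 scale."""
    if not a and not b:
        return 100.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - dist / max(len(a), len(b)))


def match_response_to_ngram(
    response_tokens,
    candidates,
    similarity_floor: float = 60.0,
) -> NgramLabel | None:
    """Best-fitting candidate by partial-ratio fuzzy matching.

    The score of a candidate is the maximum similarity between its text and
    any contiguous token window of the response; below the floor the
    response keeps its topic but gets no n-gram.  Ties break to the
    higher-count candidate, then lexicographically.
    """
    response_tokens = list(response_tokens)
    if not candidates or not response_tokens:
        return None
    windows = [
        " ".join(response_tokens[i:j])
        for i in range(len(response_tokens))
        for j in range(i + 1, len(response_tokens) + 1)
    ]
    scored = [
        (max(_similarity(cand.text, w) for w in windows), cand) for cand in candidates
    ]
    best_score, best = min(
        scored, key=lambda sc: (-sc[0], -sc[1].count, -sc[1].frequency, sc[1].text)
    )
    if best_score < similarity_floor:
        return None
    return best
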