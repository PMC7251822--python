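"""Lexicon-based sentiment scoring with negation and degree-adverb handling.

Each response gets one score in [-1, 1]: the mean of the (override-adjusted)
polarities of its lexicon words, where a negation within the preceding
window flips a contribution by x(-0.5) and a degree adverb (intensifier)
multiplies it.  Scores map to categories with the fixed cut-offs
negative < 0.0, 0.0 <= neutral <= 0.1, positive > 0.1.

Scoring runs on lightly cleaned but *unstemmed* tokens — stemming destroys
the adjectives the lexicon keys on — which is a deliberate divergence from
the topic-model token stream.

Because general-purpose lexicons mislabel domain words ("disease" is not a
complaint in a hospital survey), frequent high-polarity words can be flagged
for review and adjusted through an override file (word -> +/-delta, clamped
to [-1, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import resources

NEGATION_FLIP = -0.5
DEFAULT_NEGATION_WINDOW = 2

CATEGORIES = ("negative", "neutral", "positive")


@dataclass
class Lexicon:
    polarity: dict[str, float]
    negations: frozenset[str] = frozenset()
    intensifiers: dict[str, float] = field(default_factory=dict)
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for w, v in self.polarity.items():
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"polarity out of range for {w!r}: {v}")
        for w, m in self.intensifiers.items():
            if m <= 0:
                raise ValueError(f"intensifier multiplier must be > 0: {w!r}")

    def adjusted_polarity(self, word: str) -> float:
        value = self.polarity[word] + self.overrides.get(word, 0.0)
        return max(-1.0, min(1.0, value))

    def mirrored(self) -> "Lexicon":
        return Lexicon(
            polarity={w: -v for w, v in self.polarity.items()},
            negations=self.negations,
            intensifiers=dict(self.intensifiers),
            overrides={w: -v for w, v in self.overrides.items()},
        )


def default_lexicon(with_overrides: bool = False) -> Lexicon:
    return Lexicon(
        polarity=resources.sentiment_lexicon_values(),
        negations=resources.negations(),
        intensifiers=resources.intensifiers(),
        overrides=resources.sentiment_overrides() if with_overrides else {},
    )


@dataclass
class SentimentScore:
    value: float
    category: str

    def __post_init__(self):
        if self.category != categorize_sentiment(self.value):
            raise ValueError("category inconsistent with value")


def score_text(
    tokens,
    lexicon: Lexicon,
    negation_window: int = DEFAULT_NEGATION_WINDOW,
) -> float:
    """Mean contribution of the lexicon words in ``tokens`` (lowercase).

    For each lexicon word, every intensifier among the ``negation_window``
    preceding tokens multiplies its polarity, and any negation in that window
    flips it by x(-0.5) (applied once).  No lexicon words -> 0.0.
    """
    tokens = list(tokens)
    contributions = []
    for i, tok in enumerate(tokens):
        if tok not in lexicon.polarity:
            continue
        value = lexicon.adjusted_polarity(tok)
        window = tokens[max(0, i - negation_window) : i]
        for prev in window:
            if prev in lexicon.intensifiers:
                value *= lexicon.intensifiers[prev]
        if any(prev in lexicon.negations for prev in window):
            value *= NEGATION_FLIP
        contributions.append(value)
    if not contributions:
        return 0.0
    score = sum(contributions) / len(contributions)
    return max(-1.0, min(1.0, score))


def categorize_sentiment(value: float) -> str:
    """negative < 0.0; 0.0 <= neutral <= 0.1; positive > 0.1 (boundaries
    0.0 and 0.1 are neutral, making the intervals a partition)."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"sentiment value out of [-1, 1]: {value}")
    if value < 0.0:
        return "negative"
    if value <= 0.1:
        return "neutral"
    return "positive"


def score_response(tokens, lexicon: Lexicon, **kwargs) -> SentimentScore:
    value = score_text(tokens, lexicon, **kwargs)
    return SentimentScore(value=value, category=categorize_sentiment(value))


def flag_lexicon_outliers(
    corpus_counts: dict[str, int],
    lexicon: Lexicon,
    freq_floor: int = 50,
    polarity_bar: float = 0.5,
) -> list[tuple[str, int, float]]:
    """Words occurring more than ``freq_floor`` times whose |polarity|
    exceeds ``polarity_bar``, sorted by count descending — the review list
    for domain adjustment."""
    flagged = [
        (w, c, lexicon.polarity[w])
        for w, c in corpus_counts.items()
        if w in lexicon.polarity and c > freq_floor and abs(lexicon.polarity[w]) > polarity_bar
    ]
    flagged.sort(key=lambda wcp: (-wcp[1], wcp[0]))
    return flagged


def apply_overrides(lexicon: Lexicon, overrides: dict[str, float]) -> Lexicon:
    """Merge an override file into the lexicon (adjustments accumulate;
    adjusted polarities are clamped to [-1, 1] at lookup)."""
    merged = dict(lexicon.overrides)
    for w, delta in overrides.items():
        merged[w] = merged.get(w, 0.0) + delta
    return Lexicon(
        polarity=dict(lexicon.polarity),
        negations=lexicon.negations,
        intensifiers=dict(lexicon.intensifiers),
        overrides=merged,
    )
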