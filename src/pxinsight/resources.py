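"""Bundled English language resources and loaders for user-supplied ones.

Every language resource the pipeline needs (word-frequency dictionary,
stopwords, noun list, sentiment lexicon, negations, degree adverbs,
abbreviation expansions, sentiment overrides) is a plain-text file so that a
deployment can swap in another language by pointing the config at its own
files.  The bundled fixtures are English; the method itself is
language-agnostic.
"""

from __future__ import annotations

import importlib.resources as _ir
from pathlib import Path


def _bundled(name: str):
    return _ir.files("pxinsight").joinpath("data", name)


def _read_lines(source) -> list[str]:
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, (str, Path)) else source.read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def load_word_list(path=None, *, bundled: str | None = None) -> list[str]:
    """One word per line; order preserved (used for deterministic frequencies)."""
    return _read_lines(path if path is not None else _bundled(bundled))


def load_word_values(path=None, *, bundled: str | None = None) -> dict[str, float]:
    """TSV ``word<TAB>number`` -> ordered dict."""
    out: dict[str, float] = {}
    for ln in _read_lines(path if path is not None else _bundled(bundled)):
        word, value = ln.split("\t")
        out[word.strip()] = float(value)
    return out


def load_word_map(path=None, *, bundled: str | None = None) -> dict[str, str]:
    """TSV ``word<TAB>replacement`` (e.g. abbreviation expansions)."""
    out: dict[str, str] = {}
    for ln in _read_lines(path if path is not None else _bundled(bundled)):
        word, repl = ln.split("\t")
        out[word.strip()] = repl.strip()
    return out


def stopwords(path=None) -> frozenset[str]:
    return frozenset(load_word_list(path, bundled="stopwords.txt"))


def nouns(path=None) -> frozenset[str]:
    return frozenset(load_word_list(path, bundled="nouns.txt"))


def noun_list(path=None) -> list[str]:
    return load_word_list(path, bundled="nouns.txt")


def sentiment_lexicon_values(path=None) -> dict[str, float]:
    return load_word_values(path, bundled="sentiment_lexicon.tsv")


def negations(path=None) -> frozenset[str]:
    return frozenset(load_word_list(path, bundled="negations.txt"))


def intensifiers(path=None) -> dict[str, float]:
    return load_word_values(path, bundled="intensifiers.tsv")


def abbreviations(path=None) -> dict[str, str]:
    return load_word_map(path, bundled="abbreviations.tsv")


def sentiment_overrides(path=None) -> dict[str, float]:
    return load_word_values(path, bundled="overrides.tsv")


def dictionary_word_frequencies() -> dict[str, int]:
    """Compose the bundled word-frequency dictionary.

    Frequencies are synthetic but deterministic: each source list gets a base
    frequency band and words decay by position, so Norvig-style correction has
    an unambiguous highest-frequency candidate.
    """
    freqs: dict[str, int] = {}

    def add(words, base):
        for i, w in enumerate(words):
            freqs.setdefault(w, max(base - 2 * i, 10))

    add(load_word_list(bundled="stopwords.txt"), 9000)
    add(load_word_list(bundled="negations.txt"), 8500)
    add(sorted(intensifiers()), 8400)
    add(load_word_list(bundled="nouns.txt"), 2000)
    add(list(sentiment_lexicon_values()), 1200)
    add(load_word_list(bundled="extra_words.txt"), 700)
    add(sorted(abbreviations().values()), 500)
    return freqs
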