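"""End-to-end pipeline: survey CSV in, prioritized insights out.

Per question (Q1/Q2 are modelled separately): preprocess to a tf-idf corpus,
select the topic count by coherence, assign responses to topics, mine and
match noun n-grams, score sentiment, and rank the celebrate/improve/monitor
priorities.  Everything tunable sits in :class:`RunConfig`; the effective
config, a summary and all per-question tables are written to the output
directory, and runs are deterministic given the same seed and input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import resources
from .ngram_context import (
    extract_ngrams, match_response_to_ngram, surface_forms, top_noun_ngrams,
)
from .preprocess import (
    QUESTIONS, build_question_corpora, default_dictionary, get_stemmer, tokenize,
)
from .prioritize import (
    aggregate, categorize_matrix, category_shares, impact_rank, plot_matrix,
    records_frame,
)
from .sentiment import Lexicon, categorize_sentiment, score_text
from .topic_model import UNASSIGNED, assign_topics, select_k

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("respondent_id", "question_id", "text")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its documented default."""

    input: str = ""
    outdir: str = "pxinsight_out"
    # language resources (None -> bundled English fixtures)
    stopwords_path: str | None = None
    lexicon_path: str | None = None
    negations_path: str | None = None
    intensifiers_path: str | None = None
    overrides_path: str | None = None
    nouns_path: str | None = None
    abbreviations_path: str | None = None
    stemmer: str = "porter"
    apply_overrides: bool = True
    # preprocessing
    min_word_count: int = 20
    domain_freq_threshold: int = 100
    # topic model
    k_min: int = 4
    k_max: int = 100
    k_stride: int = 1
    top_n_descriptors: int = 10
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-4
    # n-grams
    ngram_top_k: int = 20
    fuzzy_floor: float = 60.0
    # sentiment
    negation_window: int = 2
    freq_floor: int = 50
    polarity_bar: float = 0.5
    # misc
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def _build_lexicon(config: RunConfig) -> Lexicon:
    lex = Lexicon(
        polarity=resources.sentiment_lexicon_values(config.lexicon_path),
        negations=resources.negations(config.negations_path),
        intensifiers=resources.intensifiers(config.intensifiers_path),
    )
    if config.apply_overrides:
        from .sentiment import apply_overrides

        lex = apply_overrides(lex, resources.sentiment_overrides(config.overrides_path))
    return lex


def load_responses(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    return frame


def run_pipeline(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Run the full flow and write the output bundle; returns the summary
    (also written to summary.json) plus in-memory artifacts under "models"."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_file = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    log_file.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pxinsight")
    root.addHandler(log_file)
    try:
        return _run(config, table, outdir)
    finally:
        root.removeHandler(log_file)
        log_file.close()


def _run(config: RunConfig, table, outdir: Path) -> dict:
    if table is None:
        table = load_responses(config.input)
    config.to_json(outdir / "config.json")
    logger.info("seed=%d, %d input rows", config.seed, len(table))

    abbreviation_map = resources.abbreviations(config.abbreviations_path)
    stopword_set = resources.stopwords(config.stopwords_path)
    stemmer = get_stemmer(config.stemmer)
    dictionary = default_dictionary()
    lexicon = _build_lexicon(config)
    stemmed_nouns = frozenset(
        stemmer.stem(w) for w in resources.noun_list(config.nouns_path)
    )
    noun_test = stemmed_nouns.__contains__

    corpora = build_question_corpora(
        table,
        questions=QUESTIONS,
        stopwords=stopword_set,
        stemmer=stemmer,
        min_word_count=config.min_word_count,
        dictionary=dictionary,
        abbreviation_map=abbreviation_map,
    )
    present = [q for q in QUESTIONS if q in corpora]
    for q in QUESTIONS:
        if q not in corpora:
            logger.warning("question %s has no responses; skipped", q)

    summary: dict = {"seed": config.seed, "questions": {}}
    models: dict = {}
    all_records = []

    for q in present:
        corpus = corpora[q]
        raw_texts = [r.raw_text for r in corpus.responses]
        raw_tokens = [tokenize(t, abbreviation_map) for t in raw_texts]
        original_vocab = len({tok for toks in raw_tokens for tok in toks})

        model = select_k(
            corpus,
            k_min=config.k_min,
            k_max=config.k_max,
            stride=config.k_stride,
            seed=config.seed,
            top_n=config.top_n_descriptors,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
        )
        assigned = assign_topics(model.W)

        # n-gram candidates per topic, then fuzzy-match each response
        stems = [r.clean_tokens for r in corpus.responses]
        surfaces = [r.surface_tokens for r in corpus.responses]
        candidates = {}
        for t in range(model.K):
            members = [i for i, a in enumerate(assigned) if a == t]
            counts = extract_ngrams([stems[i] for i in members])
            smap = surface_forms(
                [stems[i] for i in members], [surfaces[i] for i in members]
            )
            candidates[t] = top_noun_ngrams(
                counts, noun_test, k=config.ngram_top_k,
                topic_index=t, surface_map=smap,
            )
        matches = {}
        for i, r in enumerate(corpus.responses):
            label = None
            if assigned[i] != UNASSIGNED:
                label = match_response_to_ngram(
                    stems[i], candidates[assigned[i]],
                    similarity_floor=config.fuzzy_floor,
                )
            matches[r.doc_id] = label

        # sentiment on cleaned, unstemmed tokens
        scores = {
            r.doc_id: score_text(
                tokenize(r.raw_text, abbreviation_map), lexicon,
                negation_window=config.negation_window,
            )
            for r in corpus.responses
        }

        records = aggregate(matches, scores, question_id=q)
        if records:
            categorize_matrix(records)
            all_records.extend(records)

        # ---- outputs
        model.save_json(outdir / f"topics_{q}.json")
        _write_topic_terms(model, outdir / f"topic_terms_{q}.tsv")
        pd.DataFrame(
            {
                "respondent_id": [r.respondent_id for r in corpus.responses],
                "question_id": [r.question_id for r in corpus.responses],
                "topic_index": list(assigned),
                "topic_label": [
                    model.labels[a] if a != UNASSIGNED else "UNASSIGNED" for a in assigned
                ],
                "matched_ngram": [
                    (matches[r.doc_id].display if matches[r.doc_id] else "")
                    for r in corpus.responses
                ],
            }
        ).to_csv(outdir / f"assignments_{q}.csv", index=False)
        pd.DataFrame(
            [
                (model.labels[t], c.display, c.text, c.n, c.count, c.frequency)
                for t in range(model.K)
                for c in candidates[t]
            ],
            columns=["topic_label", "ngram", "ngram_stems", "n", "count", "matched_responses"],
        ).to_csv(outdir / f"ngrams_{q}.csv", index=False)
        pd.DataFrame(
            {
                "respondent_id": [r.respondent_id for r in corpus.responses],
                "question_id": [r.question_id for r in corpus.responses],
                "score": [scores[r.doc_id] for r in corpus.responses],
                "category": [categorize_sentiment(scores[r.doc_id]) for r in corpus.responses],
            }
        ).to_csv(outdir / f"sentiment_{q}.csv", index=False)

        n_unassigned = int((assigned == UNASSIGNED).sum())
        summary["questions"][q] = {
            "answers": corpus.n_docs,
            "mean_words_per_answer": float(np.mean([len(t) for t in raw_tokens])),
            "original_corpus_size": original_vocab,
            "corpus_size_after_preprocessing": len(corpus.vocabulary),
            "chosen_k": model.K,
            "mean_coherence": model.mean_coherence,
            "n_ngrams": sum(len(c) for c in candidates.values()),
            "n_matched_ngrams": len(records),
            "assigned": corpus.n_docs - n_unassigned,
            "unassigned": n_unassigned,
        }
        models[q] = {
            "corpus": corpus, "model": model, "assigned": assigned,
            "matches": matches, "scores": scores, "records": records,
        }

    if all_records:
        impact_rank(all_records)
        frame = records_frame(all_records).sort_values(
            ["question_id", "category", "rank_in_category"], kind="stable"
        )
        frame.to_csv(outdir / "priorities.csv", index=False)
        summary["category_shares"] = category_shares(all_records)
        plot_matrix(all_records, outdir / "matrix.png", outdir / "matrix_points.csv")

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8"
    )
    summary["models"] = models
    return summary


def _write_topic_terms(model, path) -> None:
    rows = []
    for k in range(model.K):
        for term in model.top_terms(k):
            j = model.vocabulary.index(term)
            rows.append((k, model.labels[k], term, model.H[k, j]))
    pd.DataFrame(rows, columns=["topic_index", "topic_label", "term", "weight"]).to_csv(
        path, sep="\t", index=False
    )
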