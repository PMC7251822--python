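import numpy as np
import pytest

from pxinsight import (
    assign_topics,
    build_corpus,
    default_lexicon,
    generate_survey,
    select_k,
)


def corpus_from_table(table, **kwargs):
    return build_corpus(list(table.itertuples(index=False, name=None)), **kwargs)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def recovery_experiment():
    """The planted-topic study: 500 responses, 6 disjoint topics, 5% typos."""
    table, truth = generate_survey(500, n_topics=6, typo_rate=0.05, seed=11)
    corpus = corpus_from_table(table)
    model = select_k(corpus, k_min=4, k_max=10, seed=11)
    assigned = assign_topics(model.W)
    return {
        "table": table,
        "truth": truth,
        "corpus": corpus,
        "model": model,
        "assigned": assigned,
        "true_topics": truth.topics_for(corpus.doc_ids),
    }


@pytest.fixture(scope="session")
def split_half_models():
    """Two models fitted on disjoint halves of one synthetic survey (same
    planted topics), for the transferability comparison."""
    table, truth = generate_survey(800, seed=21)
    rows = list(table.itertuples(index=False, name=None))
    model_a = select_k(build_corpus(rows[::2]), k_min=4, k_max=8)
    model_b = select_k(build_corpus(rows[1::2]), k_min=4, k_max=8)
    return model_a, model_b


@pytest.fixture
def rng():
    return np.random.default_rng(0)
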