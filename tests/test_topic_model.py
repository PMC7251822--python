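"""NMF factorization, NPMI coherence, K selection and topic assignment."""

import logging
from itertools import combinations

import numpy as np
import pytest
import scipy.sparse as sp

from pxinsight import assign_topics, fit_nmf, recovery_rate, topic_coherence
from pxinsight.topic_model import UNASSIGNED, _best_k, build_topic_model, select_k


# ---------------------------------------------------------------------------
# NMF


def test_rank_one_matrix_recovered_exactly():
    rng = np.random.default_rng(0)
    V = np.outer(rng.random(12) + 0.1, rng.random(9) + 0.1)
    W, H = fit_nmf(V, K=1)
    rel_err = np.linalg.norm(V - W @ H) / np.linalg.norm(V)
    assert rel_err < 1e-6


def test_factors_are_nonnegative():
    rng = np.random.default_rng(1)
    V = rng.random((15, 10))
    for init in ("nndsvda", "random"):
        W, H = fit_nmf(V, K=3, init=init, seed=4)
        assert W.min() >= 0 and H.min() >= 0


@pytest.mark.parametrize("init", ["nndsvda", "random"])
def test_multiplicative_updates_never_increase_loss(init):
    rng = np.random.default_rng(2)
    V = rng.random((20, 30))
    _, _, losses = fit_nmf(V, K=4, init=init, seed=9, tol=0.0, max_iter=200,
                           return_loss=True)
    diffs = np.diff(losses)
    assert (diffs <= 1e-9 * losses[0]).all()
    assert losses[-1] <= losses[0]


def test_seeded_random_init_reproducible():
    rng = np.random.default_rng(3)
    V = rng.random((10, 8))
    W1, H1 = fit_nmf(V, K=3, init="random", seed=5)
    W2, H2 = fit_nmf(V, K=3, init="random", seed=5)
    np.testing.assert_array_equal(W1, W2)
    np.testing.assert_array_equal(H1, H2)


def test_k_out_of_bounds_rejected():
    V = np.ones((5, 4))
    with pytest.raises(ValueError):
        fit_nmf(V, K=5)
    with pytest.raises(ValueError):
        fit_nmf(V, K=0)
    with pytest.raises(ValueError):
        fit_nmf(-V, K=2)


def test_reconstruction_competitive_with_sklearn():
    """Independent cross-check: the hand-rolled solver reaches a fit no worse
    than ~20% above scikit-learn's NMF on the same problem."""
    from sklearn.decomposition import NMF

    rng = np.random.default_rng(4)
    V = np.abs(rng.normal(size=(40, 25)))
    W, H = fit_nmf(V, K=5, max_iter=500, tol=0.0)
    mine = np.linalg.norm(V - W @ H)
    ref = NMF(n_components=5, init="nndsvda", solver="mu", max_iter=500,
              tol=1e-10, random_state=0).fit(V)
    assert mine <= 1.2 * ref.reconstruction_err_


# ---------------------------------------------------------------------------
# coherence


def npmi_oracle(X, top):
    """Brute-force pairwise NPMI from a dense binary doc-term matrix."""
    n = X.shape[0]
    scores = []
    for a, b in combinations(top, 2):
        da, db = X[:, a].sum(), X[:, b].sum()
        dab = int((X[:, a] & X[:, b]).sum())
        if dab == 0:
            scores.append(-1.0)
        elif dab == n:
            scores.append(1.0)
        else:
            pa, pb, pab = da / n, db / n, dab / n
            scores.append(np.log(pab / (pa * pb)) / -np.log(pab))
    return float(np.mean(scores))


def test_always_cooccurring_pair_scores_one():
    counts = np.array([[1, 1], [2, 3], [0, 0], [1, 1]])
    H = np.array([[1.0, 0.5]])
    assert topic_coherence(H, counts, top_n=2)[0] == pytest.approx(1.0)


def test_never_cooccurring_pair_scores_minus_one():
    counts = np.array([[1, 0], [0, 1], [1, 0]])
    H = np.array([[1.0, 0.5]])
    assert topic_coherence(H, counts, top_n=2)[0] == pytest.approx(-1.0)


def test_coherence_matches_bruteforce_npmi_oracle():
    counts = np.array(
        [
            [2, 1, 0, 0],
            [1, 1, 1, 0],
            [0, 0, 3, 1],
            [0, 1, 1, 1],
            [1, 0, 0, 2],
            [2, 2, 0, 0],
        ]
    )
    H = np.array([[0.9, 0.7, 0.5, 0.2], [0.1, 0.0, 0.8, 0.9]])
    got = topic_coherence(H, counts, top_n=3)
    X = (counts > 0).astype(int)
    # top-3 columns by H weight: topic 0 -> 0,1,2 ; topic 1 -> 3,2,0
    assert got[0] == pytest.approx(npmi_oracle(X, [0, 1, 2]), abs=1e-10)
    assert got[1] == pytest.approx(npmi_oracle(X, [3, 2, 0]), abs=1e-10)


def test_short_topic_warns_and_uses_available_terms(caplog):
    counts = np.array([[1, 1], [1, 1]])
    H = np.array([[0.5, 0.0]])  # single nonzero descriptor
    with caplog.at_level(logging.WARNING):
        scores = topic_coherence(H, counts, top_n=2)
    assert scores[0] == 0.0
    assert any("nonzero terms" in r.message for r in caplog.records)


def test_top_n_validation():
    with pytest.raises(ValueError):
        topic_coherence(np.ones((1, 3)), np.ones((2, 3)), top_n=1)


# ---------------------------------------------------------------------------
# model selection


def test_singleton_range_returns_that_k(recovery_experiment):
    model = select_k(recovery_experiment["corpus"], k_min=7, k_max=7)
    assert model.K == 7


def test_mean_coherence_tie_goes_to_smaller_k():
    assert _best_k([5, 6], [0.4, 0.4]) == 5
    assert _best_k([4, 5, 6], [0.1, 0.5, 0.5]) == 5


def test_k_max_capped_with_warning(caplog):
    rng = np.random.default_rng(5)
    corpus = _tiny_corpus(rng)
    with caplog.at_level(logging.WARNING):
        model = select_k(corpus, k_min=2, k_max=50)
    assert model.K <= min(corpus.weights.shape)
    assert any("capped" in r.message for r in caplog.records)


def test_k_min_validation(recovery_experiment):
    with pytest.raises(ValueError):
        select_k(recovery_experiment["corpus"], k_min=1, k_max=5)
    with pytest.raises(ValueError):
        select_k(recovery_experiment["corpus"], k_min=6, k_max=5)


def _tiny_corpus(rng):
    from types import SimpleNamespace

    counts = sp.csr_matrix(rng.integers(0, 3, size=(8, 5)).astype(float))
    return SimpleNamespace(
        weights=counts, raw_counts=counts,
        vocabulary=[f"w{j}" for j in range(5)],
    )


# ---------------------------------------------------------------------------
# assignment


def test_assignment_rules():
    W = np.array(
        [
            [0.0, 0.0, 0.0],   # unassigned
            [0.1, 0.9, 0.0],   # argmax
            [0.5, 0.5, 0.0],   # tie -> lowest index
        ]
    )
    out = assign_topics(W)
    assert out[0] == UNASSIGNED
    assert out[1] == 1
    assert out[2] == 0


def test_assignment_totality(recovery_experiment):
    assigned = recovery_experiment["assigned"]
    n = recovery_experiment["corpus"].n_docs
    assert ((assigned == UNASSIGNED) | (assigned >= 0)).all()
    assert len(assigned) == n


def test_unassigned_iff_zero_weight_row(recovery_experiment):
    W = recovery_experiment["model"].W
    assigned = recovery_experiment["assigned"]
    zero_rows = ~W.any(axis=1)
    np.testing.assert_array_equal(assigned == UNASSIGNED, zero_rows)


# ---------------------------------------------------------------------------
# planted-topic recovery (ground-truth experiment)


def test_selected_k_close_to_planted_count(recovery_experiment):
    assert recovery_experiment["model"].K in {5, 6, 7}


def test_planted_topics_recovered(recovery_experiment):
    rate = recovery_rate(
        recovery_experiment["assigned"], recovery_experiment["true_topics"]
    )
    assert rate >= 0.90


def test_labels_are_argmax_terms(recovery_experiment):
    model = recovery_experiment["model"]
    for k, label in enumerate(model.labels):
        j = int(np.argmax(model.H[k]))
        assert model.vocabulary[j] == label


def test_descriptor_export_roundtrip(recovery_experiment, tmp_path):
    model = recovery_experiment["model"]
    path = tmp_path / "topics.json"
    model.save_json(path)
    import json

    data = json.loads(path.read_text())
    assert data["K"] == model.K
    assert data["labels"] == model.labels
    assert len(data["descriptors"]) == model.K
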