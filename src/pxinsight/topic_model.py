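"""NMF topic modelling with coherence-based model selection.

The document-term tf-idf matrix V (n_docs x n_terms) is factorized as
V ~ W.H with W, H >= 0: W rows are document-topic weights, H rows are
topic-term weights ("H-factors").  Models are fitted for every K in a range
and the one with the highest mean topic coherence wins; coherence is the
mean pairwise NPMI of each topic's top descriptors, estimated from document
co-occurrence counts.  Each topic is labelled with its highest-weighted term
and each document is assigned its argmax topic; documents whose weight row
is all zero (empty after preprocessing) stay unassigned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

UNASSIGNED = -1

_EPS = 1e-12


def _dense(V) -> np.ndarray:
    if sp.issparse(V):
        V = V.toarray()
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2 or (V < 0).any():
        raise ValueError("input matrix must be 2-D and nonnegative")
    return V


# ---------------------------------------------------------------------------
# NMF


def _init_nndsvda(V: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization, zeros filled with the matrix
    mean (deterministic)."""
    n, m = V.shape
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    W = np.zeros((n, K))
    H = np.zeros((K, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, K):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        pos, neg = np.linalg.norm(up) * np.linalg.norm(vp), np.linalg.norm(un) * np.linalg.norm(vn)
        x, y, sigma = (up, vp, pos) if pos >= neg else (un, vn, neg)
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if sigma > 0 and nx > 0 and ny > 0:
            W[:, j] = np.sqrt(S[j] * sigma) * x / nx
            H[j, :] = np.sqrt(S[j] * sigma) * y / ny
    fill = V.mean() or _EPS
    W[W <= 0] = fill
    H[H <= 0] = fill
    return W, H


def fit_nmf(
    weights,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    init: str = "nndsvda",
    return_loss: bool = False,
):
    """Factorize a nonnegative matrix with Frobenius multiplicative updates.

    Returns ``(W, H)`` or ``(W, H, losses)``; ``losses[0]`` is the loss at
    initialization and the sequence is non-increasing.  Converged when the
    per-iteration loss decrease falls below ``tol`` times the initial loss.
    """
    V = _dense(weights)
    n, m = V.shape
    if not 1 <= K <= min(n, m):
        raise ValueError(f"K={K} must be in [1, min(n_docs, n_terms)={min(n, m)}]")

    if init == "nndsvda":
        W, H = _init_nndsvda(V, K)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(V.mean() / K) or _EPS
        W = scale * rng.random((n, K)) + _EPS
        H = scale * rng.random((K, m)) + _EPS
    else:
        raise ValueError(f"unknown init {init!r}")

    losses = [np.linalg.norm(V - W @ H)]
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        losses.append(np.linalg.norm(V - W @ H))
        if losses[-2] - losses[-1] < tol * (losses[0] or 1.0):
            break
    if return_loss:
        return W, H, losses
    return W, H


# ---------------------------------------------------------------------------
# coherence


def _npmi(d_i: int, d_j: int, d_ij: int, n_docs: int) -> float:
    """Normalized pointwise mutual information from document frequencies.

    Convention: never co-occurring pairs score exactly -1 (the epsilon-free
    limit); pairs whose words each appear in every document score +1.
    """
    if d_i == 0 or d_j == 0:
        return 0.0
    if d_ij == 0:
        return -1.0
    p_i, p_j, p_ij = d_i / n_docs, d_j / n_docs, d_ij / n_docs
    if p_ij >= 1.0:
        return 1.0
    return float(np.clip(np.log(p_ij / (p_i * p_j)) / -np.log(p_ij), -1.0, 1.0))


def topic_coherence(H, raw_counts, top_n: int = 10) -> np.ndarray:
    """Mean pairwise NPMI of each topic's ``top_n`` descriptors."""
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    H = np.asarray(H, dtype=np.float64)
    X = (sp.csc_matrix(raw_counts) > 0).astype(np.int64)
    if X.shape[1] != H.shape[1]:
        raise ValueError("raw_counts and H vocabularies differ")
    n_docs = X.shape[0]
    doc_freq = np.asarray(X.sum(axis=0)).ravel()

    scores = np.zeros(H.shape[0])
    for k, row in enumerate(H):
        nonzero = np.flatnonzero(row > 0)
        if len(nonzero) < top_n:
            logger.warning(
                "topic %d has only %d nonzero terms (< top_n=%d); using those",
                k, len(nonzero), top_n,
            )
        order = np.argsort(-row, kind="stable")
        top = [j for j in order if row[j] > 0][:top_n]
        if len(top) < 2:
            scores[k] = 0.0
            continue
        cols = X[:, top].toarray()
        pair_scores = [
            _npmi(doc_freq[top[a]], doc_freq[top[b]],
                  int((cols[:, a] & cols[:, b]).sum()), n_docs)
            for a, b in combinations(range(len(top)), 2)
        ]
        scores[k] = float(np.mean(pair_scores))
    return scores


# ---------------------------------------------------------------------------
# model selection and assignment


@dataclass
class TopicModel:
    K: int
    W: np.ndarray
    H: np.ndarray
    vocabulary: list[str]
    labels: list[str]
    coherence_per_topic: np.ndarray
    mean_coherence: float
    descriptor_top_n: int = 10

    def top_terms(self, k: int, n: int | None = None) -> list[str]:
        n = n or self.descriptor_top_n
        row = self.H[k]
        order = np.argsort(-row, kind="stable")
        return [self.vocabulary[j] for j in order if row[j] > 0][:n]

    @property
    def descriptors(self) -> list[list[str]]:
        return [self.top_terms(k) for k in range(self.K)]

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "labels": self.labels,
            "coherence_per_topic": [float(c) for c in self.coherence_per_topic],
            "mean_coherence": float(self.mean_coherence),
            "descriptors": self.descriptors,
        }

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")


def _labels_from_H(H: np.ndarray, vocabulary: list[str]) -> list[str]:
    return [vocabulary[int(np.argmax(row))] for row in H]


def build_topic_model(corpus, K: int, seed: int = 0, top_n: int = 10, **nmf_kwargs) -> TopicModel:
    W, H = fit_nmf(corpus.weights, K, seed=seed, **nmf_kwargs)
    coh = topic_coherence(H, corpus.raw_counts, top_n=top_n)
    return TopicModel(
        K=K, W=W, H=H,
        vocabulary=list(corpus.vocabulary),
        labels=_labels_from_H(H, corpus.vocabulary),
        coherence_per_topic=coh,
        mean_coherence=float(np.mean(coh)),
        descriptor_top_n=top_n,
    )


def _best_k(ks: list[int], mean_coherences: list[float]) -> int:
    """Highest mean coherence wins; exact ties go to the smaller K."""
    best = max(range(len(ks)), key=lambda i: (mean_coherences[i], -ks[i]))
    return ks[best]


def select_k(
    corpus,
    k_min: int = 4,
    k_max: int = 100,
    stride: int = 1,
    seed: int = 0,
    top_n: int = 10,
    **nmf_kwargs,
) -> TopicModel:
    """Fit NMF for every K in [k_min, k_max] (step ``stride``) and return the
    model with the highest mean topic coherence."""
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    bound = min(corpus.weights.shape)
    if k_max > bound:
        logger.warning("k_max=%d capped at min(n_docs, n_terms)=%d", k_max, bound)
        k_max = bound
    if k_min > k_max:
        raise ValueError(f"corpus too small: k_min={k_min} > usable k_max={k_max}")

    ks = list(range(k_min, k_max + 1, stride))
    models = [build_topic_model(corpus, K, seed=seed, top_n=top_n, **nmf_kwargs) for K in ks]
    chosen = _best_k(ks, [m.mean_coherence for m in models])
    return models[ks.index(chosen)]


def assign_topics(W) -> np.ndarray:
    """Argmax topic per document; all-zero rows get UNASSIGNED (-1).
    Ties break to the lowest topic index."""
    W = np.asarray(W, dtype=np.float64)
    out = np.argmax(W, axis=1).astype(np.int64)
    out[~W.any(axis=1)] = UNASSIGNED
    return out


def recovery_rate(assigned: np.ndarray, true_topics) -> float:
    """Fraction of documents with a planted topic that land in the matching
    fitted topic, after optimal (Hungarian) topic-to-truth matching.

    ``true_topics`` holds planted indices, with None/"none" for docs without
    a planted topic (those are excluded from the denominator).
    """
    truth = np.array(
        [-1 if t in (None, "none") else int(t) for t in true_topics], dtype=np.int64
    )
    mask = truth >= 0
    a, t = assigned[mask], truth[mask]
    if not len(a):
        return float("nan")
    fitted = np.unique(a[a >= 0])
    planted = np.unique(t)
    contingency = np.zeros((len(fitted), len(planted)))
    fpos = {k: i for i, k in enumerate(fitted)}
    ppos = {k: i for i, k in enumerate(planted)}
    for ai, ti in zip(a, t):
        if ai >= 0:
            contingency[fpos[ai], ppos[ti]] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return float(contingency[rows, cols].sum() / len(a))
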