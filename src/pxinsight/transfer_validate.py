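"""Transferability checks and rater-agreement validation.

When the same modelling architecture is run on a second site's surveys, two
questions arise: does a similar share of responses get a topic (chi-square
goodness of fit of the new site's assigned/unassigned counts against the
reference proportions, 2 categories, df = 1), and how much do the two topic
inventories overlap (greedy matching of topics by Jaccard similarity of
their top descriptors)?

Sentiment labels are validated against human raters with Fleiss' kappa; the
95% CI uses the asymptotic standard error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# assignment-rate chi-square


def assignment_rate_test(
    assigned_ref: int, total_ref: int, assigned_new: int, total_new: int
) -> tuple[float, float]:
    """Pearson chi-square goodness of fit of the new sample's
    assigned/unassigned split against the reference proportions (df = 1)."""
    if total_ref <= 0 or total_new <= 0:
        raise ValueError("totals must be positive")
    if not 0 <= assigned_ref <= total_ref or not 0 <= assigned_new <= total_new:
        raise ValueError("assigned counts must be within totals")
    p_ref = assigned_ref / total_ref
    expected = np.array([p_ref * total_new, (1 - p_ref) * total_new])
    if (expected == 0).any():
        raise ValueError("degenerate expectation: a reference category is empty")
    observed = np.array([assigned_new, total_new - assigned_new])
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# topic overlap


def _descriptor_sets(model, top_n: int) -> list[frozenset]:
    if hasattr(model, "top_terms"):
        sets = [frozenset(model.top_terms(k, top_n)) for k in range(model.K)]
    else:
        sets = [frozenset(list(d)[:top_n]) for d in model]
    if not sets:
        raise ValueError("empty topic model")
    return sets


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def compare_topics(model_a, model_b, similarity_floor: float = 0.2, top_n: int = 10) -> dict:
    """Greedy one-to-one matching of topics by descriptor-set Jaccard
    similarity above ``similarity_floor``.

    Accepts fitted TopicModels or bare lists of descriptor lists.  Returns
    shared/unique fractions: shared = 2*matches/(Ka+Kb); unique per model =
    unmatched topics / topics of that model.
    """
    sets_a = _descriptor_sets(model_a, top_n)
    sets_b = _descriptor_sets(model_b, top_n)
    sims = [
        (_jaccard(sa, sb), i, j)
        for i, sa in enumerate(sets_a)
        for j, sb in enumerate(sets_b)
    ]
    sims.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, pairs = set(), set(), []
    for sim, i, j in sims:
        if sim < similarity_floor:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, sim))
    ka, kb, shared = len(sets_a), len(sets_b), len(pairs)
    return {
        "matched_pairs": pairs,
        "shared_fraction": 2 * shared / (ka + kb),
        "unique_fraction_a": (ka - shared) / ka,
        "unique_fraction_b": (kb - shared) / kb,
    }


@dataclass
class TransferReport:
    assigned_a: int
    unassigned_a: int
    assigned_b: int
    unassigned_b: int
    chi2: float
    p_value: float
    shared_fraction: float
    unique_fraction_a: float
    unique_fraction_b: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")


def transfer_report(
    model_a, model_b,
    assigned_a: int, total_a: int,
    assigned_b: int, total_b: int,
    similarity_floor: float = 0.2,
) -> TransferReport:
    chi2, p = assignment_rate_test(assigned_a, total_a, assigned_b, total_b)
    overlap = compare_topics(model_a, model_b, similarity_floor=similarity_floor)
    return TransferReport(
        assigned_a=assigned_a, unassigned_a=total_a - assigned_a,
        assigned_b=assigned_b, unassigned_b=total_b - assigned_b,
        chi2=chi2, p_value=p,
        shared_fraction=overlap["shared_fraction"],
        unique_fraction_a=overlap["unique_fraction_a"],
        unique_fraction_b=overlap["unique_fraction_b"],
    )


# ---------------------------------------------------------------------------
# Fleiss' kappa


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    percent_agreement: float
    se: float
    n_subjects: int
    n_raters: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")


def _ratings_matrix(ratings) -> np.ndarray:
    """subjects x raters label array; subjects with missing ratings dropped."""
    if isinstance(ratings, pd.DataFrame):
        arr = ratings.to_numpy()
    else:
        arr = np.asarray(ratings)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a subjects x raters table with >= 2 of each")
    missing = pd.isna(arr).any(axis=1)
    if missing.any():
        logger.warning("excluding %d subjects with missing ratings", int(missing.sum()))
        arr = arr[~missing]
    if arr.shape[0] < 2:
        raise ValueError("fewer than 2 fully rated subjects")
    return arr


def fleiss_kappa(ratings, confidence: float = 0.95) -> KappaResult:
    """Fleiss' kappa for a subjects x raters table of categorical labels.

    The CI is the asymptotic normal interval kappa +/- z * SE with the
    large-sample SE of Fleiss, Nee & Landis; percent_agreement is the share
    of subjects on which all raters coincide.
    """
    arr = _ratings_matrix(ratings)
    n_subjects, n_raters = arr.shape
    categories = sorted(set(arr.ravel()))
    counts = np.zeros((n_subjects, len(categories)), dtype=np.int64)
    pos = {c: j for j, c in enumerate(categories)}
    for i, row in enumerate(arr):
        for label in row:
            counts[i, pos[label]] += 1

    p_j = counts.sum(axis=0) / (n_subjects * n_raters)
    if len(categories) == 1:
        kappa = 1.0  # total agreement on a single category: chance correction degenerates
    else:
        kappa = float(_sm_fleiss_kappa(counts, method="fleiss"))

    pq = float(np.sum(p_j * (1 - p_j)))
    if pq > 0:
        se = (
            np.sqrt(2.0 / (n_subjects * n_raters * (n_raters - 1)))
            * np.sqrt(pq**2 - float(np.sum(p_j * (1 - p_j) * (1 - 2 * p_j))))
            / pq
        )
    else:
        se = 0.0
    z = stats.norm.ppf(0.5 + confidence / 2)
    agreement = float(np.mean([len(set(row)) == 1 for row in arr]))
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(kappa - z * se),
        ci_high=float(kappa + z * se),
        percent_agreement=agreement,
        se=float(se),
        n_subjects=n_subjects,
        n_raters=n_raters,
    )


def percent_agreement(labels_a, labels_b) -> float:
    """Share of items on which two label sequences coincide (e.g. model vs
    a rater panel's individual raters)."""
    a, b = list(labels_a), list(labels_b)
    if len(a) != len(b) or not a:
        raise ValueError("label sequences must be non-empty and equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def ratings_from_long(frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (subject_id, rater_id, label) table to subjects x raters."""
    return frame.pivot(index="subject_id", columns="rater_id", values="label")
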