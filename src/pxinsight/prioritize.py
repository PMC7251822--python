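"""Celebrate / improve / monitor matrix and impact ranking.

Each n-gram subtopic is summarized by how many responses matched it
(frequency) and their mean sentiment, then placed in a matrix whose
frequency cut-offs are the median (Q2) and third quartile (Q3) of the
frequency distribution:

* improve:   frequency > Q3 and sentiment < 0.0
* celebrate: frequency > Q3 and sentiment > 0.1
* monitor:   frequency > Q3 with neutral sentiment (0.0-0.1), or
             Q2 < frequency < Q3 with sentiment < 0.0
* none:      everything else

Impact is a risk-style product of probability (frequency) and severity
(|mean sentiment|), rescaled within each question so the largest impact is
100; the top 5 per category are the suggested priorities.  The product
scorer is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ngram_context import NgramLabel

MATRIX_CATEGORIES = ("celebrate", "improve", "monitor", "none")


@dataclass
class PriorityRecord:
    ngram: NgramLabel
    question_id: str
    frequency: int
    mean_sentiment: float
    category: str = "none"
    impact: float = 0.0
    rank_in_category: int | None = None


def aggregate(matches: dict, scores: dict, question_id: str = "Q1") -> list[PriorityRecord]:
    """Collapse per-response n-gram matches and sentiment scores into one
    record per n-gram (frequency and mean sentiment filled).

    ``matches`` maps doc id -> NgramLabel or None; ``scores`` maps the same
    doc ids -> sentiment value.  Unmatched responses are excluded.
    """
    grouped: dict[str, list[float]] = {}
    labels: dict[str, NgramLabel] = {}
    for doc_id, label in matches.items():
        if label is None:
            continue
        grouped.setdefault(label.text, []).append(scores[doc_id])
        labels[label.text] = label
    records = []
    for text in sorted(grouped):
        vals = grouped[text]
        label = labels[text]
        label.frequency = len(vals)
        records.append(
            PriorityRecord(
                ngram=label,
                question_id=question_id,
                frequency=len(vals),
                mean_sentiment=float(np.mean(vals)),
            )
        )
    return records


def frequency_quartiles(records) -> tuple[float, float]:
    """(median, third quartile) of the record frequency distribution,
    linear interpolation."""
    freqs = [r.frequency for r in records]
    q2, q3 = np.percentile(freqs, [50, 75])
    return float(q2), float(q3)


def categorize_matrix(records: list[PriorityRecord]) -> list[PriorityRecord]:
    """Assign each record its matrix category (in place; returns records)."""
    if not records:
        raise ValueError("need at least one record")
    q2, q3 = frequency_quartiles(records)
    for r in records:
        f, s = r.frequency, r.mean_sentiment
        if f > q3 and s < 0.0:
            r.category = "improve"
        elif f > q3 and s > 0.1:
            r.category = "celebrate"
        elif (f > q3 and 0.0 <= s <= 0.1) or (q2 < f < q3 and s < 0.0):
            r.category = "monitor"
        else:
            r.category = "none"
    return records


def default_impact(frequency: int, mean_sentiment: float) -> float:
    return frequency * abs(mean_sentiment)


def impact_rank(
    records: list[PriorityRecord],
    scorer=default_impact,
    top_n: int = 5,
) -> dict[str, list[PriorityRecord]]:
    """Compute impact, rescale to max 100 within each question, rank within
    each category (impact desc, ties by frequency then n-gram text), and
    return the top-``top_n`` table per matrix category."""
    raw = {id(r): scorer(r.frequency, r.mean_sentiment) for r in records}
    for question in sorted({r.question_id for r in records}):
        qrecs = [r for r in records if r.question_id == question]
        peak = max(raw[id(r)] for r in qrecs)
        for r in qrecs:
            r.impact = 100.0 * raw[id(r)] / peak if peak > 0 else 0.0

    top: dict[str, list[PriorityRecord]] = {}
    for category in MATRIX_CATEGORIES:
        crecs = sorted(
            (r for r in records if r.category == category),
            key=lambda r: (-r.impact, -r.frequency, r.ngram.text),
        )
        for i, r in enumerate(crecs, start=1):
            r.rank_in_category = i
        if category != "none":
            top[category] = crecs[:top_n]
    return top


def category_shares(records) -> dict[str, float]:
    """Percentage of records per category (sums to 100)."""
    n = len(records)
    return {
        c: 100.0 * sum(r.category == c for r in records) / n
        for c in MATRIX_CATEGORIES
    }


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "question_id": [r.question_id for r in records],
            "ngram": [r.ngram.display for r in records],
            "ngram_stems": [r.ngram.text for r in records],
            "topic_index": [r.ngram.topic_index for r in records],
            "frequency": [r.frequency for r in records],
            "mean_sentiment": [r.mean_sentiment for r in records],
            "category": [r.category for r in records],
            "impact": [r.impact for r in records],
            "rank_in_category": [r.rank_in_category for r in records],
        }
    )


def plot_matrix(records, path, points_csv=None) -> None:
    """Frequency vs mean-sentiment scatter (both questions, distinct
    markers), with the sentiment cut-offs and per-question quartile lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = records_frame(records)
    colors = {"celebrate": "tab:green", "improve": "tab:red",
              "monitor": "tab:orange", "none": "tab:gray"}
    markers = {"Q1": "o", "Q2": "^"}
    fig, ax = plt.subplots(figsize=(7, 5))
    for question, sub in frame.groupby("question_id"):
        ax.scatter(
            sub["frequency"], sub["mean_sentiment"],
            c=[colors[c] for c in sub["category"]],
            marker=markers.get(question, "s"),
            label=question, alpha=0.8, edgecolors="none",
        )
        qrecs = [r for r in records if r.question_id == question]
        q2, q3 = frequency_quartiles(qrecs)
        for q, style in [(q2, ":"), (q3, "--")]:
            ax.axvline(q, linestyle=style, linewidth=0.8, color="gray")
    ax.axhline(0.0, linewidth=0.8, color="black")
    ax.axhline(0.1, linewidth=0.8, color="black", linestyle="--")
    ax.set_xlabel("frequency (matched responses)")
    ax.set_ylabel("mean sentiment")
    ax.set_title("Patient experience priority matrix")
    ax.legend(title="question")
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": None})
    plt.close(fig)
    if points_csv is not None:
        frame.to_csv(points_csv, index=False)
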