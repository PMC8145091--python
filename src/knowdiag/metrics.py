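"""Example-based multilabel ranking metrics.

All five metrics follow the standard example-based definitions: a per-record
quantity computed from the score row and the gold label set, averaged over
records.  Ranks are 1-based by descending score with ties broken by label
index (stable); ranking loss counts a tied (relevant, irrelevant) pair as
half an inversion.  Records violating a metric's precondition (no relevant
label; for ranking loss also no irrelevant label) are skipped and reported
through a warning rather than raising, because thresholded corpora can
legally contain them.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "average_precision",
    "one_error",
    "hamming_loss",
    "ranking_loss",
    "coverage",
    "evaluate_all",
]


def _check(scores: np.ndarray, gold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(gold)
    if scores.shape != gold.shape or scores.ndim != 2:
        raise ValueError("scores and gold must be 2-D arrays of identical shape")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    return scores, gold.astype(bool)


def _ranks(row: np.ndarray) -> np.ndarray:
    """1-based rank of every label: descending score, ties by label index."""
    c = row.shape[0]
    order = np.lexsort((np.arange(c), -row))  # best label first
    ranks = np.empty(c, dtype=int)
    ranks[order] = np.arange(1, c + 1)
    return ranks


def _warn_skipped(n: int, metric: str) -> None:
    if n:
        warnings.warn(
            f"{metric}: skipped {n} record(s) not meeting the metric's "
            "precondition",
            stacklevel=3,
        )


def average_precision(scores: np.ndarray, gold: np.ndarray) -> float:
    """Mean over records of the precision at each relevant label's rank."""
    scores, gold = _check(scores, gold)
    vals, skipped = [], 0
    for row, g in zip(scores, gold):
        rel = np.flatnonzero(g)
        if rel.size == 0:
            skipped += 1
            continue
        ranks = _ranks(row)
        rel_ranks = np.sort(ranks[rel])
        # precision at rank r of the i-th best relevant label is i / r
        vals.append(np.mean(np.arange(1, rel_ranks.size + 1) / rel_ranks))
    _warn_skipped(skipped, "average_precision")
    if not vals:
        raise ValueError("no record has a relevant label")
    return float(np.mean(vals))


def one_error(scores: np.ndarray, gold: np.ndarray) -> float:
    """Fraction of records whose top-ranked label is not relevant."""
    scores, gold = _check(scores, gold)
    vals, skipped = [], 0
    for row, g in zip(scores, gold):
        if not g.any():
            skipped += 1
            continue
        top = np.argmin(_ranks(row))
        vals.append(0.0 if g[top] else 1.0)
    _warn_skipped(skipped, "one_error")
    if not vals:
        raise ValueError("no record has a relevant label")
    return float(np.mean(vals))


def hamming_loss(scores: np.ndarray, gold: np.ndarray, tau: float = 0.5) -> float:
    """Fraction of record-label cells where the thresholded prediction
    (score > tau) disagrees with gold."""
    scores, gold = _check(scores, gold)
    pred = scores > tau
    return float(np.mean(pred != gold))


def ranking_loss(scores: np.ndarray, gold: np.ndarray) -> float:
    """Average fraction of mis-ordered (relevant, irrelevant) label pairs."""
    scores, gold = _check(scores, gold)
    vals, skipped = [], 0
    for row, g in zip(scores, gold):
        rel = row[g]
        irr = row[~g]
        if rel.size == 0 or irr.size == 0:
            skipped += 1
            continue
        diff = rel[:, None] - irr[None, :]
        bad = np.sum(diff < 0) + 0.5 * np.sum(diff == 0)
        vals.append(bad / (rel.size * irr.size))
    _warn_skipped(skipped, "ranking_loss")
    if not vals:
        raise ValueError("no record has both a relevant and an irrelevant label")
    return float(np.mean(vals))


def coverage(scores: np.ndarray, gold: np.ndarray) -> float:
    """Average (max rank among relevant labels) - 1: how far down the ranked
    list one must go to cover every true label."""
    scores, gold = _check(scores, gold)
    vals, skipped = [], 0
    for row, g in zip(scores, gold):
        rel = np.flatnonzero(g)
        if rel.size == 0:
            skipped += 1
            continue
        vals.append(np.max(_ranks(row)[rel]) - 1)
    _warn_skipped(skipped, "coverage")
    if not vals:
        raise ValueError("no record has a relevant label")
    return float(np.mean(vals))


def evaluate_all(scores: np.ndarray, gold: np.ndarray, tau: float = 0.5) -> dict[str, float]:
    """All five metrics in the conventional reporting order."""
    return {
        "average_precision": average_precision(scores, gold),
        "one_error": one_error(scores, gold),
        "hamming_loss": hamming_loss(scores, gold, tau),
        "ranking_loss": ranking_loss(scores, gold),
        "coverage": coverage(scores, gold),
    }
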