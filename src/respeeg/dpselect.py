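"""Discriminative-power (DP) feature ranking.

The DP of a single feature is the best true-positive rate any
single-feature threshold rule can reach while producing *zero* false
positives on the training sample.  With two classes ``a`` and ``b`` it
is the maximum over the four one-sided rules

    |{a < min b}| / |a|,   |{a > max b}| / |a|,
    |{b < min a}| / |b|,   |{b > max a}| / |b|,

with strict inequalities, so values tied with the opposing extreme
count as false positives and are excluded.  The symmetric maximum is
used because neither the positive class nor the threshold direction is
privileged.  DP lies in [0, 1], is invariant under any strictly
increasing transform applied to both classes, and is 0 whenever the
class supports' extremes interleave completely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = ["DPRanking", "discriminative_power", "rank_features", "select_top"]


@dataclass(frozen=True)
class DPRanking:
    """Per-feature DP scores and the descending-score feature order."""

    scores: np.ndarray  # in [0, 1], one per feature column
    order: np.ndarray  # permutation of feature indices, stable ties by index
    index: list[tuple[str, float]] | None = None  # optional (channel, Hz) labels

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, j in enumerate(self.order):
            name = (
                f"{self.index[j][0]}:{self.index[j][1]:g}" if self.index else str(j)
            )
            rows.append((rank, int(j), name, float(self.scores[j])))
        return pd.DataFrame(rows, columns=["rank", "feature", "name", "dp_score"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def discriminative_power(a, b) -> float:
    """DP score of one feature given its values in the two classes."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    rules = (
        np.mean(a < b.min()),
        np.mean(a > b.max()),
        np.mean(b < a.min()),
        np.mean(b > a.max()),
    )
    return float(max(rules))


def rank_features(features: FeatureMatrix | np.ndarray, labels=None) -> DPRanking:
    """Rank every feature column by DP, descending; ties break by index.

    Accepts a :class:`FeatureMatrix` (labels taken from it) or a plain
    matrix plus a label sequence with exactly two distinct values.
    """
    if isinstance(features, FeatureMatrix):
        values = features.values
        labels = features.labels if labels is None else np.asarray(labels, dtype=object)
        index = features.index
    else:
        values = np.asarray(features, dtype=float)
        if labels is None:
            raise ValueError("labels are required with a plain matrix")
        labels = np.asarray(labels, dtype=object)
        index = None
    classes = np.unique(labels.astype(str))
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    mask = labels.astype(str) == classes[0]
    a, b = values[mask], values[~mask]

    # vectorized four-rule maximum across all columns
    a_min, a_max = a.min(axis=0), a.max(axis=0)
    b_min, b_max = b.min(axis=0), b.max(axis=0)
    scores = np.max(
        [
            (a < b_min).mean(axis=0),
            (a > b_max).mean(axis=0),
            (b < a_min).mean(axis=0),
            (b > a_max).mean(axis=0),
        ],
        axis=0,
    )
    # stable descending sort with ascending-index tie-break
    order = np.lexsort((np.arange(scores.size), -scores))
    return DPRanking(scores, order.astype(np.int64), index)


def select_top(ranking: DPRanking, k: int = 60) -> np.ndarray:
    """First ``min(k, n)`` feature indices of the ranking order."""
    if k < 1:
        raise ValueError("k must be at least 1")
    n = ranking.order.size
    if k > n:
        warnings.warn(
            f"requested {k} features but only {n} exist; returning all", stacklevel=2
        )
    return ranking.order[: min(k, n)].copy()
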