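"""Fisher-coefficient feature selection and KNN leave-one-out classification.

The Fisher coefficient of a feature is the ratio of between-class to
within-class variance; for two classes it reduces to ``F = (mu_a -
mu_b)^2 / (s_a^2 + s_b^2)`` with population variances. Features with
``F > 3`` are conventionally considered to have good discriminatory
potential, and the ten highest-F features form the selected set.

Classification uses k-nearest-neighbour with leave-one-out evaluation:
each lesion is classified by the majority label of its k nearest
neighbours in z-scored feature space, with the z-scores recomputed
without the held-out lesion so no information leaks into the fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["KNNConfig", "fisher_coefficient", "rank_and_select", "knn_loo_accuracy"]


@dataclass(frozen=True)
class KNNConfig:
    """Neighbour count, metric and scaling for the LOO classifier."""

    k: int = 1
    metric: str = "euclidean"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 1, got {self.k}")
        if self.metric != "euclidean":
            raise ValueError(f"unsupported metric {self.metric!r}")


def fisher_coefficient(values_a, values_b, weighted: bool = False) -> float:
    """Two-class Fisher coefficient of a single feature.

    With ``weighted=True`` the within-class term is the class-size
    weighted pooled variance ``(n_a v_a + n_b v_b) / (n_a + n_b)``
    instead of the plain sum ``v_a + v_b``. Returns ``inf`` (a perfect
    separator) when both variances vanish but the means differ, and 0
    when the means coincide.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs at least 2 values")
    d2 = (a.mean() - b.mean()) ** 2
    if weighted:
        within = (a.size * a.var() + b.size * b.var()) / (a.size + b.size)
    else:
        within = a.var() + b.var()
    if within == 0.0:
        return math.inf if d2 > 0 else 0.0
    return float(d2 / within)


def rank_and_select(
    features: pd.DataFrame,
    labels,
    top_k: int = 10,
    cutoff: float = 3.0,
    weighted: bool = False,
) -> pd.DataFrame:
    """Rank features by Fisher coefficient and flag the selected set.

    Returns a DataFrame indexed by feature name with columns ``F``,
    ``rank``, ``selected_top_k`` and ``passes_cutoff``, sorted by
    descending F with ties broken by feature name. Features with any
    missing value are excluded (their count is logged).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    mask_a = labels == classes[0]
    mask_b = labels == classes[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each class needs at least 2 lesions")
    if top_k > features.shape[1]:
        raise ValueError("top_k exceeds the number of features")

    complete = features.columns[features.notna().all(axis=0)]
    n_dropped = features.shape[1] - len(complete)
    if n_dropped:
        logger.info("excluding %d features with missing values from Fisher ranking", n_dropped)

    f_values = {
        name: fisher_coefficient(
            features.loc[mask_a, name], features.loc[mask_b, name], weighted=weighted
        )
        for name in complete
    }
    ranking = pd.DataFrame({"F": pd.Series(f_values)})
    ranking.index.name = "feature"
    # descending F, ties broken lexicographically by feature name
    order = np.lexsort((ranking.index.to_numpy(), -ranking["F"].to_numpy()))
    ranking = ranking.iloc[order]
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    ranking["selected_top_k"] = ranking["rank"] <= top_k
    ranking["passes_cutoff"] = ranking["F"] > cutoff
    return ranking


def knn_loo_accuracy(features: pd.DataFrame, labels, config: KNNConfig = KNNConfig()):
    """Leave-one-out KNN accuracy on a (selected) feature table.

    For each held-out lesion, the remaining lesions are z-scored, the
    held-out lesion is projected with the same statistics, and the
    majority label of the k nearest Euclidean neighbours is predicted.
    Distance ties at the neighbourhood boundary and voting ties are both
    broken toward the lower class label, making the result deterministic.

    Returns a dict with overall accuracy (fraction and percent),
    per-class misclassification counts, and the per-lesion predictions.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n != labels.size:
        raise ValueError("features and labels length mismatch")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if config.k >= n:
        raise ValueError(f"k={config.k} must be smaller than the cohort size {n}")

    preds = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        Xt = X[train]
        if config.standardize:
            mu = Xt.mean(axis=0)
            sd = Xt.std(axis=0)
            sd[sd == 0] = 1.0
            Xt = (Xt - mu) / sd
            xi = (X[i] - mu) / sd
        else:
            xi = X[i]
        d = np.sqrt(((Xt - xi) ** 2).sum(axis=1))
        lab = labels[train]
        # sort by distance, then by class label so equidistant ties
        # prefer the lower label deterministically
        lab_codes = np.searchsorted(classes, lab)
        order = np.lexsort((lab_codes, d))
        top = lab[order[: config.k]]
        votes = {c: int((top == c).sum()) for c in classes}
        best = max(votes.values())
        preds[i] = min(c for c, v in votes.items() if v == best)

    correct = preds == labels
    misclassified = {
        str(c): int(((labels == c) & ~correct).sum()) for c in classes
    }
    acc = float(correct.mean())
    return {
        "accuracy": acc,
        "accuracy_pct": 100.0 * acc,
        "n": int(n),
        "n_correct": int(correct.sum()),
        "misclassified_per_class": misclassified,
        "predictions": preds,
    }
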