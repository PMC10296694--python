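"""Minimum-redundancy-maximum-relevance (mRMR) feature ranking.

Greedy MID (mutual-information difference) variant: the first feature
maximises relevance MI(f; y); each subsequent pick maximises

    MI(f; y) - (1/|S|) * sum_{s in S} MI(f; f_s)

over the not-yet-selected features, where S is the selected set. Mutual
information uses the plug-in estimate from the joint histogram in bits
(log base 2) after quantile discretisation of continuous features. Ties
break toward the lower column index, so the ranking is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RankedFeatures", "mutual_information", "discretize", "rank_features"]


@dataclass
class RankedFeatures:
    """mRMR ordering with selection-time criterion scores."""

    order: list[int]     # 0-based column indices, best first
    scores: list[float]  # criterion value at selection time
    n_bins: int
    variant: str = "MID"

    def named(self, names: list[str] | None = None) -> list[tuple[str, float]]:
        names = names or [f"f{i + 1}" for i in range(len(self.order))]
        return [(names[i], s) for i, s in zip(self.order, self.scores)]


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size == 0 or x.size != y.size:
        raise ValueError("x and y must be equal-length nonempty vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def discretize(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile binning into ids 0..n_bins-1; constant vectors map to bin 0.

    Rank-based, so any strictly monotone transform of ``x`` yields the
    identical bin assignment.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0 or np.ptp(x) == 0:
        return np.zeros(x.size, dtype=np.int64)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(x, edges).astype(np.int64)


def rank_features(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
) -> RankedFeatures:
    """Rank feature columns by greedy mRMR (MID) against a binary label.

    Requires at least 2 samples in each class. Returns 0-based column
    indices ordered best-first with the selection-time criterion scores.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature_matrix must be 2-D (samples x features)")
    y = np.asarray(labels).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class; mRMR needs two")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")

    n_feat = X.shape[1]
    disc = [discretize(X[:, j], n_bins) for j in range(n_feat)]
    relevance = np.array([mutual_information(disc[j], y) for j in range(n_feat)])

    # pairwise redundancies computed lazily
    red = np.full((n_feat, n_feat), np.nan)

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_feat))
    while remaining:
        best_j, best_score = None, -np.inf
        for j in remaining:
            if selected:
                for s in selected:
                    if np.isnan(red[j, s]):
                        red[j, s] = red[s, j] = mutual_information(disc[j], disc[s])
                crit = relevance[j] - float(np.mean([red[j, s] for s in selected]))
            else:
                crit = relevance[j]
            # ties (within float tolerance) keep the lower feature index
            if crit > best_score + 1e-12:
                best_j, best_score = j, crit
        selected.append(best_j)
        scores.append(float(best_score))
        remaining.remove(best_j)
    return RankedFeatures(order=selected, scores=scores, n_bins=n_bins)
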