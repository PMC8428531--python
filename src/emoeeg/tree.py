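"""A C4.5-style decision tree: binary numeric splits chosen by information
gain ratio.

Most library trees (CART) split on Gini or plain information gain; the gain
*ratio* divides the gain by the split information, penalising splits that
fragment the data. This grower implements that criterion directly on
numeric features with threshold splits; growth stops on purity, depth, or
minimum node size. No pruning — the deliberately overfitting behaviour of an
unpruned tree (train accuracy far above test) is part of what the analysis
compares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) along the last axis of count vectors."""
    n = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, counts / n, 0.0)
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=-1)


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    prediction: int = 0
    is_leaf: bool = False


class GainRatioTree:
    """Decision tree with information-gain-ratio threshold splits.

    sklearn-like interface: fit(X, y) / predict(X) / score(X, y).
    Deterministic: ties between features break toward the lowest index.
    """

    def __init__(
        self,
        max_depth: int = 25,
        min_samples_split: int = 4,
        min_samples_leaf: int = 1,
    ):
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GainRatioTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self._n_classes = len(self.classes_)
        self._root = self._grow(X, y_enc, depth=0)
        return self

    def _best_split(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[int, float, float] | None:
        """Return (feature, threshold, gain_ratio) of the best split, or None.

        Gain ratio alone favours near-degenerate cuts (tiny split info), so
        candidates are first restricted to those with at least the average
        information gain over all candidate cuts — the classic C4.5 guard.
        """
        n = len(y)
        parent_counts = np.bincount(y, minlength=self._n_classes)
        h_parent = float(_entropy_from_counts(parent_counts))
        if h_parent <= _EPS:
            return None
        onehot = np.eye(self._n_classes)[y]
        candidates = []  # (feature, thresholds, gains, ratios)
        gain_sum, gain_count = 0.0, 0
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xs = X[order, j]
            cum = np.cumsum(onehot[order], axis=0)  # class counts left of cut
            # candidate cuts between distinct consecutive values
            distinct = np.nonzero(np.diff(xs) > 0)[0]
            if len(distinct) == 0:
                continue
            nl = distinct + 1
            valid = (nl >= self.min_samples_leaf) & (
                n - nl >= self.min_samples_leaf
            )
            distinct = distinct[valid]
            if len(distinct) == 0:
                continue
            nl = distinct + 1
            left_counts = cum[distinct]
            right_counts = parent_counts - left_counts
            wl = nl / n
            wr = 1.0 - wl
            h_children = wl * _entropy_from_counts(left_counts) + wr * _entropy_from_counts(right_counts)
            gain = h_parent - h_children
            split_info = -(wl * np.log(wl) + wr * np.log(wr))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(
                    (gain > _EPS) & (split_info > _EPS), gain / split_info, -np.inf
                )
            thresholds = 0.5 * (xs[distinct] + xs[distinct + 1])
            candidates.append((j, thresholds, gain, ratio))
            gain_sum += float(gain[gain > _EPS].sum())
            gain_count += int((gain > _EPS).sum())
        if gain_count == 0:
            return None
        mean_gain = gain_sum / gain_count
        best = None
        for j, thresholds, gain, ratio in candidates:
            ok = gain >= mean_gain - _EPS
            if not ok.any():
                continue
            masked = np.where(ok, ratio, -np.inf)
            k = int(np.argmax(masked))
            if np.isfinite(masked[k]) and (best is None or masked[k] > best[2]):
                best = (j, float(thresholds[k]), float(masked[k]))
        return best

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> _Node:
        counts = np.bincount(y, minlength=self._n_classes)
        node = _Node(prediction=int(np.argmax(counts)), is_leaf=True)
        if (
            depth >= self.max_depth
            or len(y) < self.min_samples_split
            or counts.max() == len(y)
        ):
            return node
        split = self._best_split(X, y)
        if split is None:
            return node
        j, thr, _ = split
        mask = X[:, j] <= thr
        if not mask.any() or mask.all():
            return node
        node.is_leaf = False
        node.feature = j
        node.threshold = thr
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(X):
            node = self._root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return self.classes_[out]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # minimal sklearn-compat surface
    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_depth": self.max_depth,
            "min_samples_split": self.min_samples_split,
            "min_samples_leaf": self.min_samples_leaf,
        }

    def set_params(self, **params) -> "GainRatioTree":
        for k, v in params.items():
            setattr(self, k, v)
        return self
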