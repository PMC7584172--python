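"""Regression-forest variable screening with path-proportion importance.

An ensemble of small regression trees ranks community variables by their
importance for predicting the hospital standardized readmission ratio.
Each tree draws a fresh random half-sample for training (the other half
validates), samples a small set of candidate variables (3 by default),
and grows greedy variance-reduction splits restricted to those
variables.  A variable's importance is the proportion of root-to-leaf
decision paths, pooled over the forest, that pass through a split on it;
a path through several distinct variables credits each once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TreeNode:
    """A node of a regression tree; leaves have ``var is None``."""

    value: float
    n: int
    var: int | None = None  # column index into the full feature matrix
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None


@dataclass
class RegressionTree:
    """One tree: its root, sampled variables, and half-sample bookkeeping."""

    root: TreeNode
    variables_available: tuple[int, ...]
    train_idx: np.ndarray
    validate_idx: np.ndarray
    validation_r2: float = np.nan

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.var] <= node.threshold else node.right
            out[i] = node.value
        return out

    def paths(self) -> list[list[int]]:
        """Variable indices split on along each root-to-leaf path."""
        found: list[list[int]] = []

        def walk(node: TreeNode, seen: list[int]) -> None:
            if node.is_leaf:
                found.append(seen)
                return
            walk(node.left, seen + [node.var])
            walk(node.right, seen + [node.var])

        walk(self.root, [])
        return found


@dataclass
class Forest:
    """A fitted forest with its feature names and per-tree validation R²."""

    trees: list[RegressionTree]
    feature_names: list[str]
    validation_r2: np.ndarray = field(default_factory=lambda: np.array([]))

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree": np.arange(len(self.trees)),
                "validation_r2": self.validation_r2,
                "variables": [
                    "|".join(self.feature_names[j] for j in t.variables_available)
                    for t in self.trees
                ],
            }
        )


@dataclass
class ImportanceRanking:
    """Path-proportion importance scores, normalized to sum 1."""

    importance: pd.Series  # indexed by variable name, descending

    def rank_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable_name": self.importance.index,
                "importance": self.importance.to_numpy(),
                "rank": np.arange(1, len(self.importance) + 1),
            }
        )


def _best_split(
    x: np.ndarray, y: np.ndarray, min_node_size: int
) -> tuple[float, float] | None:
    """Exhaustive best threshold for one variable, or None.

    Minimizes total child sum of squared deviations, equivalently
    maximizes S_L²/n_L + S_R²/n_R over sorted split positions.  Children
    must each hold at least ``min_node_size`` rows; splits between tied
    values are not allowed.  Returns (threshold, score) with the
    threshold at the midpoint of the straddling values.
    """
    n = len(y)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    csum = np.cumsum(ys)
    total = csum[-1]
    pos = np.arange(1, n)  # size of left child
    valid = (pos >= min_node_size) & (n - pos >= min_node_size)
    valid &= xs[1:] != xs[:-1]
    if not valid.any():
        return None
    sl = csum[:-1]
    score = np.where(
        valid, sl**2 / pos + (total - sl) ** 2 / (n - pos), -np.inf
    )
    best = int(np.argmax(score))  # first max: lowest threshold wins ties
    thr = 0.5 * (xs[best] + xs[best + 1])
    return float(thr), float(score[best])


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx: tuple[int, ...],
    rows: np.ndarray,
    min_node_size: int = 5,
    max_depth: int | None = 3,
    rng: np.random.Generator | None = None,
    per_node_sampling: bool = False,
    n_sample_vars: int = 3,
    _depth: int = 0,
) -> TreeNode:
    """Grow a greedy variance-reduction tree on ``rows`` of (X, y).

    Splits are restricted to ``feature_idx`` (the tree's sampled
    variables); with ``per_node_sampling`` a fresh subset of that list is
    drawn at each node.  Recursion stops at ``max_depth`` (trees are kept
    small so a path reflects the few variables that mattered most), when
    a node is smaller than twice ``min_node_size``, the outcome is
    constant, or no admissible split reduces the sum of squares.
    Tie-breaks (equal score) go to the
    lower feature index and lower threshold, so trees are deterministic.
    """
    ysub = y[rows]
    node = TreeNode(value=float(ysub.mean()), n=len(rows))
    at_depth_cap = max_depth is not None and _depth >= max_depth
    if at_depth_cap or len(rows) < 2 * min_node_size or np.ptp(ysub) == 0.0:
        return node
    if per_node_sampling and rng is not None and len(feature_idx) > n_sample_vars:
        cand = tuple(sorted(rng.choice(feature_idx, n_sample_vars, replace=False)))
    else:
        cand = feature_idx
    base = float((ysub**2).sum() - len(rows) * node.value**2)
    best: tuple[float, int, float] | None = None  # (-score, var, threshold)
    for j in cand:
        res = _best_split(X[rows, j], ysub, min_node_size)
        if res is None:
            continue
        thr, score = res
        key = (-score, j, thr)
        if best is None or key < best:
            best = key
    if best is None:
        return node
    score, j, thr = -best[0], best[1], best[2]
    # improvement = score - n*mean^2 must be positive (beyond roundoff)
    if score - len(rows) * node.value**2 <= 1e-12 * max(base, 1.0):
        return node
    mask = X[rows, j] <= thr
    node.var = int(j)
    node.threshold = float(thr)
    node.left = grow_tree(
        X, y, feature_idx, rows[mask], min_node_size, max_depth, rng,
        per_node_sampling, n_sample_vars, _depth + 1,
    )
    node.right = grow_tree(
        X, y, feature_idx, rows[~mask], min_node_size, max_depth, rng,
        per_node_sampling, n_sample_vars, _depth + 1,
    )
    return node


def build_forest(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_trees: int = 10_000,
    vars_per_tree: int = 3,
    seed: int = 0,
    min_node_size: int = 5,
    max_depth: int | None = 3,
    per_node_sampling: bool = False,
) -> Forest:
    """Build the screening forest.

    Per tree: a fresh random half-sample split (floor(n/2) rows train,
    the rest validate), ``vars_per_tree`` variables sampled without
    replacement, a greedy tree on the training half, and validation R²
    recorded on the held-out half (1 − SSE/SST about the validation
    mean; can be negative).  Missing feature values are mean-imputed
    before any tree is grown, with a warning stating the count.
    """
    if len(X) < 10:
        raise ValueError("need at least 10 rows")
    if X.shape[1] < vars_per_tree:
        raise ValueError("fewer variables than vars_per_tree")
    names = list(X.columns)
    Xv = X.to_numpy(float).copy()
    n_missing = int(np.isnan(Xv).sum())
    if n_missing:
        warnings.warn(
            f"mean-imputing {n_missing} missing feature values before forest entry",
            stacklevel=2,
        )
        col_mean = np.nanmean(Xv, axis=0)
        ii, jj = np.where(np.isnan(Xv))
        Xv[ii, jj] = col_mean[jj]
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trees: list[RegressionTree] = []
    r2s = np.empty(n_trees)
    for t in range(n_trees):
        perm = rng.permutation(n)
        train, val = perm[: n // 2], perm[n // 2 :]
        feats = tuple(sorted(rng.choice(p, vars_per_tree, replace=False)))
        root = grow_tree(
            Xv, yv, feats, train, min_node_size, max_depth, rng,
            per_node_sampling, vars_per_tree,
        )
        tree = RegressionTree(
            root=root, variables_available=feats, train_idx=train, validate_idx=val
        )
        yhat = tree.predict(Xv[val])
        sst = float(((yv[val] - yv[val].mean()) ** 2).sum())
        sse = float(((yv[val] - yhat) ** 2).sum())
        tree.validation_r2 = 1.0 - sse / sst if sst > 0 else np.nan
        r2s[t] = tree.validation_r2
        trees.append(tree)
    return Forest(trees=trees, feature_names=names, validation_r2=r2s)


def path_importance(forest: Forest) -> ImportanceRanking:
    """Path-proportion importance over the whole forest.

    Every root-to-leaf path contributes one count to each *distinct*
    variable split on along it; scores are the per-variable counts
    normalized by the total over all variables, so they sum to 1.
    Variables never split on score 0.  A forest of stumps-only (no
    splits anywhere) yields all-zero scores with a warning.
    """
    if not forest.trees:
        raise ValueError("forest is empty")
    counts = np.zeros(len(forest.feature_names))
    for tree in forest.trees:
        for path in tree.paths():
            for v in set(path):
                counts[v] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("no splits anywhere in the forest; importance all zero",
                      stacklevel=2)
        scores = counts
    else:
        scores = counts / total
    ser = pd.Series(scores, index=forest.feature_names, name="importance")
    ser = ser.sort_values(ascending=False, kind="stable")
    return ImportanceRanking(importance=ser)
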