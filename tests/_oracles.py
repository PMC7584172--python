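"""Independent brute-force oracles used to pin the main implementations.

These deliberately share no code with the package: path importance is
recomputed by iterative stack traversal and explicit counting, best
splits by direct evaluation of every admissible threshold, and WLS by a
normal-equations solve.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def brute_force_path_importance(forest) -> dict[str, float]:
    """Enumerate every root-to-leaf path with an explicit stack and count
    distinct variables per path; normalize counts over all variables."""
    counts: Counter = Counter()
    for tree in forest.trees:
        stack = [(tree.root, frozenset())]
        while stack:
            node, seen = stack.pop()
            if node.var is None:
                for v in seen:
                    counts[v] += 1
                continue
            nxt = seen | {node.var}
            stack.append((node.left, nxt))
            stack.append((node.right, nxt))
    total = sum(counts.values())
    out = {name: 0.0 for name in forest.feature_names}
    for v, c in counts.items():
        out[forest.feature_names[v]] = c / total
    return out


def brute_force_best_split(
    X: np.ndarray, y: np.ndarray, features: tuple[int, ...], min_node_size: int
):
    """Try every (feature, midpoint) split; return the one minimizing the
    total child SSE, ties to lower feature index then lower threshold.
    Returns (feature, threshold, sse) or None."""
    best = None
    for j in features:
        xs = np.unique(X[:, j])
        for a, b in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (a + b)
            left = y[X[:, j] <= thr]
            right = y[X[:, j] > thr]
            if len(left) < min_node_size or len(right) < min_node_size:
                continue
            sse = float(((left - left.mean()) ** 2).sum()
                        + ((right - right.mean()) ** 2).sum())
            key = (sse, j, thr)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[1], best[2], best[0]


def normal_equations_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """WLS coefficients by solving X'WX b = X'Wy directly."""
    XtW = X.T * w
    return np.linalg.solve(XtW @ X, XtW @ y)


def weighted_geometric_mean(values: np.ndarray, weights: np.ndarray) -> float:
    """prod(v_i ** (w_i / sum w)) computed multiplicatively."""
    weights = np.asarray(weights, float)
    values = np.asarray(values, float)
    keep = weights > 0
    p = weights[keep] / weights[keep].sum()
    out = 1.0
    for v, e in zip(values[keep], p):
        out *= v**e
    return out
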