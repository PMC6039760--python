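"""Greedy CART engine specialised to {0,1,2} dosage predictors.

With three-valued predictors a node admits at most two thresholds (0.5
and 1.5), so split search reduces to class-wise counts and target sums.
Both are recovered for all candidate columns at once from two
matrix-vector products, using the identities ``s1 + 2*s2 = r @ X`` and
``s1 + 4*s2 = r @ X**2`` (and likewise for counts via column sums).

Two split criteria are supported:

* ``"sse"``  -- sum-of-squared-error reduction (CART / first-order
  boosting; leaves predict the node mean);
* ``"gain"`` -- second-order gain with L2 penalty ``lam`` and split
  penalty ``gamma`` for squared loss (unit hessians, so H = leaf count);
  leaf weight is sum(residual)/(count + lam).

Callers may pass ``X`` as float32 (with a centred target) for speed; the
score arithmetic is always done in float64.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["Tree", "grow_tree", "predict", "fit_regression_tree", "split_gain"]

_NO_FEATURE = -1
_EPS = 1e-12


@dataclasses.dataclass
class Tree:
    """Array-of-structs decision tree; node 0 is the root."""

    feature: np.ndarray      # int, _NO_FEATURE for leaves
    threshold: np.ndarray    # float (0.5 or 1.5)
    left: np.ndarray         # int child ids, -1 for leaves
    right: np.ndarray
    value: np.ndarray        # float leaf prediction (set for all nodes)
    improvement: np.ndarray  # float split score, 0 for leaves

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def used_features(self) -> np.ndarray:
        return np.unique(self.feature[self.feature != _NO_FEATURE])


def split_gain(g_left: float, h_left: float, g_right: float, h_right: float,
               lam: float = 0.0, gamma: float = 0.0) -> float:
    """Second-order split score: 0.5*(GL^2/(HL+lam) + GR^2/(HR+lam)
    - (GL+GR)^2/(HL+HR+lam)) - gamma."""
    g = g_left + g_right
    h = h_left + h_right
    return 0.5 * (g_left**2 / (h_left + lam) + g_right**2 / (h_right + lam)
                  - g**2 / (h + lam)) - gamma


def _node_best_split(Xn: np.ndarray, r: np.ndarray, min_leaf: int,
                     criterion: str, lam: float, gamma: float):
    """Best (column, threshold, score) over all columns of ``Xn``.

    Returns ``(-1, 0.0, -inf)`` when no admissible split exists.
    """
    s = len(r)
    Xn2 = Xn * Xn
    t1 = np.asarray(r @ Xn, dtype=np.float64)    # s1 + 2 s2
    t2 = np.asarray(r @ Xn2, dtype=np.float64)   # s1 + 4 s2
    c1 = np.asarray(Xn.sum(axis=0), dtype=np.float64)
    c2 = np.asarray(Xn2.sum(axis=0), dtype=np.float64)
    s2 = 0.5 * (t2 - t1)
    s1 = t1 - 2.0 * s2
    n2 = 0.5 * (c2 - c1)
    n1 = c1 - 2.0 * n2
    n0 = s - n1 - n2
    st = float(np.asarray(r, dtype=np.float64).sum())
    s0 = st - s1 - s2

    with np.errstate(divide="ignore", invalid="ignore"):
        if criterion == "gain":
            base = st * st / (s + lam)
            sc05 = 0.5 * (s0 * s0 / (n0 + lam) + (s1 + s2) ** 2 / (n1 + n2 + lam) - base) - gamma
            sc15 = 0.5 * ((s0 + s1) ** 2 / (n0 + n1 + lam) + s2 * s2 / (n2 + lam) - base) - gamma
        else:
            base = st * st / s
            sc05 = s0 * s0 / n0 + (s1 + s2) ** 2 / (n1 + n2) - base
            sc15 = (s0 + s1) ** 2 / (n0 + n1) + s2 * s2 / n2 - base
    ok05 = (n0 >= min_leaf) & (s - n0 >= min_leaf)
    ok15 = (n2 >= min_leaf) & (s - n2 >= min_leaf)
    sc05 = np.where(ok05, sc05, -np.inf)
    sc15 = np.where(ok15, sc15, -np.inf)

    j05, j15 = int(np.argmax(sc05)), int(np.argmax(sc15))
    if sc05[j05] >= sc15[j15]:
        return j05, 0.5, float(sc05[j05])
    return j15, 1.5, float(sc15[j15])


def grow_tree(X: np.ndarray, y: np.ndarray, sample_idx: np.ndarray, *,
              max_depth: int | None = None, min_leaf: int = 1,
              mtry: int | None = None,
              rng: np.random.Generator | None = None,
              criterion: str = "sse", lam: float = 0.0, gamma: float = 0.0,
              mtry_per_tree: bool = False) -> Tree:
    """Grow a CART tree depth-first (pre-order, left child first).

    ``mtry`` candidate columns are drawn per split attempt (or once per
    tree with ``mtry_per_tree``) from ``rng``, sorted ascending so score
    ties break toward the lowest column index.
    """
    n, m = X.shape
    if criterion not in ("sse", "gain"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if max_depth is None:
        max_depth = np.iinfo(np.int32).max
    if mtry is not None and not 1 <= mtry <= m:
        raise ValueError(f"mtry must be in [1, {m}], got {mtry}")
    min_leaf = max(1, int(min_leaf))
    yt = y.astype(X.dtype, copy=False)

    tree_candidates = None
    if mtry is not None and mtry_per_tree:
        tree_candidates = np.sort(rng.choice(m, size=mtry, replace=False))

    feature, threshold, left, right, value, improvement = [], [], [], [], [], []

    def leaf_value(r: np.ndarray) -> float:
        if criterion == "gain":
            return float(np.float64(r.sum()) / (len(r) + lam))
        return float(np.float64(r.sum()) / len(r))

    sample_idx = np.asarray(sample_idx)
    is_full = len(sample_idx) == n and bool((sample_idx == np.arange(n)).all())
    # stack entries: (row indices, depth, parent node id, is_right_child)
    stack: list[tuple[np.ndarray, int, int, bool]] = [(sample_idx, 0, -1, False)]
    while stack:
        idx, depth, parent, is_right = stack.pop()
        node = len(feature)
        if parent >= 0:
            (right if is_right else left)[parent] = node
        r = yt[idx]
        feature.append(_NO_FEATURE)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(leaf_value(r))
        improvement.append(0.0)

        if depth >= max_depth or len(idx) < 2 * min_leaf or np.ptp(r) == 0.0:
            continue
        if tree_candidates is not None:
            cand = tree_candidates
        elif mtry is not None and mtry < m:
            cand = np.sort(rng.choice(m, size=mtry, replace=False))
        else:
            cand = None  # all columns

        if cand is None:
            Xn = X if (is_full and parent < 0) else X[idx]
        else:
            Xn = X[np.ix_(idx, cand)]
        j, thr, score = _node_best_split(Xn, r, min_leaf, criterion, lam, gamma)
        scale = max(1.0, abs(float(np.float64(r) @ np.float64(r))))
        if not np.isfinite(score) or score <= _EPS * scale:
            continue
        feat = int(cand[j]) if cand is not None else j
        go_left = X[idx, feat] < thr
        feature[node] = feat
        threshold[node] = thr
        improvement[node] = score
        # push right first so the left child is processed next (pre-order)
        stack.append((idx[~go_left], depth + 1, node, True))
        stack.append((idx[go_left], depth + 1, node, False))

    return Tree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        value=np.asarray(value),
        improvement=np.asarray(improvement),
    )


def predict(tree: Tree, X: np.ndarray) -> np.ndarray:
    """Vectorised tree traversal on a dosage matrix."""
    node = np.zeros(X.shape[0], dtype=np.int64)
    active = tree.feature[node] != _NO_FEATURE
    while active.any():
        rows = np.flatnonzero(active)
        nd = node[rows]
        go_left = X[rows, tree.feature[nd]] < tree.threshold[nd]
        node[rows] = np.where(go_left, tree.left[nd], tree.right[nd])
        active[rows] = tree.feature[node[rows]] != _NO_FEATURE
    return tree.value[node]


def fit_regression_tree(X: np.ndarray, y: np.ndarray,
                        candidate_snps: np.ndarray | None = None,
                        min_node_size: int = 1,
                        max_depth: int | None = None) -> Tree:
    """Greedy CART on dosage predictors restricted to ``candidate_snps``.

    Convenience wrapper over :func:`grow_tree` with the plain SSE
    criterion; leaves predict node means and each internal node records
    its split improvement.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if candidate_snps is not None:
        # subset the candidate columns, then remap split features back
        cand = np.sort(np.asarray(candidate_snps))
        t = grow_tree(X[:, cand], y, np.arange(len(y)),
                      max_depth=max_depth, min_leaf=min_node_size)
        used = t.feature != _NO_FEATURE
        t.feature[used] = cand[t.feature[used]]
        return t
    return grow_tree(X, y, np.arange(len(y)),
                     max_depth=max_depth, min_leaf=min_node_size)
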