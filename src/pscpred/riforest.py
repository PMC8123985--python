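"""Relative-importance feature selection with a forest of entropy trees.

The candidate features are shuffled once and partitioned into ``s``
near-equal subsets.  For each subset, ``t`` times, the samples are split
50/50 at random; a binary information-gain decision tree is grown on the
training half (restricted to the subset's features) and scored on the
held-out half with the weighted classification rate (macro-averaged
per-class recall).  A feature's relative importance (RI) accumulates,
over every tree and every internal node splitting on it,

    w_tree * IG(node) * n_samples(node) / n_samples(root)

Features are then ranked by RI and nested prefixes of the ranking are
scored to choose a subset size.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import numpy as np

from pscpred.assembly import FeatureMatrix

_TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# entropy / information gain


def entropy(labels: Sequence[Hashable]) -> float:
    """Shannon entropy of a label multiset, in bits; 0*log(0) := 0."""
    if len(labels) == 0:
        raise ValueError("entropy of an empty label set is undefined")
    counts = np.array(list(Counter(labels).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain(
    parent: Sequence[Hashable],
    left: Sequence[Hashable],
    right: Sequence[Hashable],
) -> float:
    """Entropy reduction of a binary partition of ``parent``."""
    if Counter(left) + Counter(right) != Counter(parent):
        raise ValueError("left/right is not a partition of parent")
    n = len(parent)
    child = 0.0
    for part in (left, right):
        if len(part):
            child += len(part) / n * entropy(part)
    return entropy(parent) - child


def _entropy_from_counts(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Row-wise entropy in bits of (m, c) count rows with row sums ``totals``."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[:, None]
        logp = np.zeros_like(p)
        np.log2(p, out=logp, where=p > 0)
    return -(p * logp).sum(axis=1)


# ---------------------------------------------------------------------------
# decision tree


@dataclass
class TreeNode:
    """Internal node (feature/threshold/IG) or leaf (``leaf_class`` set)."""

    n_samples: int
    feature: str | None = None
    threshold: float = math.nan
    info_gain: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    leaf_class: Hashable | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class FittedTree:
    root: TreeNode
    feature_subset: tuple[str, ...]
    weighted_rate: float


def _best_split(
    X: np.ndarray, onehot: np.ndarray, feature_order: Sequence[int]
) -> tuple[float, int, float] | None:
    """Best (IG, column, threshold); ties prefer earlier feature, smaller
    threshold.  ``feature_order`` fixes the tie-break feature order."""
    n = X.shape[0]
    parent_counts = onehot.sum(axis=0)
    parent_h = _entropy_from_counts(parent_counts[None, :], np.array([float(n)]))[0]
    best: tuple[float, int, float] | None = None
    for col in feature_order:
        v = X[:, col]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        cum = np.cumsum(onehot[order], axis=0)
        cuts = np.nonzero(vs[1:] > vs[:-1])[0]
        if cuts.size == 0:
            continue  # constant feature at this node
        n_left = (cuts + 1).astype(float)
        left_counts = cum[cuts]
        right_counts = parent_counts - left_counts
        h_left = _entropy_from_counts(left_counts, n_left)
        h_right = _entropy_from_counts(right_counts, n - n_left)
        ig = parent_h - (n_left * h_left + (n - n_left) * h_right) / n
        j = int(np.argmax(ig))  # first max -> smallest threshold
        if best is None or ig[j] > best[0] + _TIE_TOL:
            thr = (vs[cuts[j]] + vs[cuts[j] + 1]) / 2.0
            best = (float(ig[j]), col, float(thr))
    return best


def _majority(labels: np.ndarray) -> Hashable:
    counts = Counter(labels.tolist())
    top = max(counts.values())
    return min(k for k, v in counts.items() if v == top)


def build_tree(
    X: np.ndarray,
    y: Sequence[Hashable],
    feature_names: Sequence[str],
    *,
    max_depth: int | None = None,
    min_samples_split: int = 2,
) -> TreeNode:
    """Grow a binary axis-aligned threshold tree by maximum information gain.

    Thresholds are midpoints between consecutive distinct sorted values;
    ties break toward the lexicographically lower feature name, then the
    smaller threshold.  Growth stops at node purity, ``min_samples_split``,
    ``max_depth``, or when every candidate feature is constant.  Fully
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("need at least one sample and one feature")
    names = list(feature_names)
    if len(names) != X.shape[1]:
        raise ValueError("one name per column required")
    classes = sorted(set(y.tolist()))
    cls_idx = {c: i for i, c in enumerate(classes)}
    codes = np.array([cls_idx[c] for c in y])
    onehot_full = np.eye(len(classes))[codes]
    feature_order = sorted(range(len(names)), key=lambda i: names[i])

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        node_y = y[idx]
        node = TreeNode(n_samples=len(idx))
        pure = len(set(node_y.tolist())) == 1
        depth_stop = max_depth is not None and depth >= max_depth
        if pure or len(idx) < min_samples_split or depth_stop:
            node.leaf_class = _majority(node_y)
            return node
        split = _best_split(X[idx], onehot_full[idx], feature_order)
        if split is None or split[0] <= _TIE_TOL:
            node.leaf_class = _majority(node_y)
            return node
        ig, col, thr = split
        node.feature = names[col]
        node.threshold = thr
        node.info_gain = ig
        mask = X[idx, col] <= thr
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(len(y)), 0)


def predict_tree(
    root: TreeNode, X: np.ndarray, feature_names: Sequence[str]
) -> list[Hashable]:
    """Route each row of ``X`` down the tree to its leaf class."""
    idx = {n: i for i, n in enumerate(feature_names)}
    out = []
    for row in np.asarray(X, dtype=float):
        node = root
        while not node.is_leaf:
            node = node.left if row[idx[node.feature]] <= node.threshold else node.right
        out.append(node.leaf_class)
    return out


def iter_internal_nodes(root: TreeNode):
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            yield node
            stack.append(node.right)
            stack.append(node.left)


# ---------------------------------------------------------------------------
# weighted classification rate and RI


def confusion_counts(
    y_true: Sequence[Hashable], y_pred: Sequence[Hashable], classes: Sequence[Hashable]
) -> np.ndarray:
    """c x c count matrix, rows = true class, in ``classes`` order."""
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    return mat


def weighted_rate(confusion: np.ndarray) -> float:
    """Macro-averaged per-class recall of a c x c confusion matrix."""
    confusion = np.asarray(confusion)
    row_sums = confusion.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every true class needs at least one test sample")
    return float(np.mean(np.diag(confusion) / row_sums))


@dataclass
class RIResult:
    """Per-feature RI scores plus the forest configuration that produced them."""

    scores: dict[str, float]
    s: int
    t: int
    subset_sizes: tuple[int, ...]
    seed: int
    trees: list[FittedTree] | None = None

    def ranking(self) -> list[str]:
        """Feature names by RI descending; ties stable by name."""
        return sorted(self.scores, key=lambda f: (-self.scores[f], f))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature\tri\n")
            for name in self.ranking():
                fh.write(f"{name}\t{format(self.scores[name], '.17g')}\n")


def ri_scores(
    X: FeatureMatrix,
    y: Sequence[Hashable],
    *,
    s: int | None = None,
    t: int = 50,
    seed: int = 0,
    max_depth: int | None = None,
    keep_trees: bool = False,
    max_split_retries: int = 100,
) -> RIResult:
    """Relative importance of every feature from an s x t forest.

    ``s`` defaults to ``ceil(d / 30)`` (about 30 features per subset).
    Each of the s*t trees trains on a random half of the samples and is
    weighted by its held-out weighted classification rate.  A sample
    split whose test half misses a class is redrawn (bounded retries).
    """
    y = np.asarray(y, dtype=object)
    n, d = X.values.shape
    if n != len(y):
        raise ValueError("X and y length mismatch")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if s is None:
        s = max(1, math.ceil(d / 30))
    if not (1 <= s <= d):
        raise ValueError(f"need d >= s >= 1, got s={s}, d={d}")
    if t < 1:
        raise ValueError("t must be >= 1")
    classes = sorted(set(y.tolist()))
    rng = np.random.default_rng(seed)
    subsets = np.array_split(rng.permutation(d), s)
    scores = {name: 0.0 for name in X.names}
    trees: list[FittedTree] | None = [] if keep_trees else None
    n_train = (n + 1) // 2
    class_set = set(classes)
    for cols in subsets:
        sub_names = sorted(X.names[c] for c in cols)
        name_to_col = {X.names[c]: c for c in cols}
        sub_cols = [name_to_col[nm] for nm in sub_names]
        Xsub = X.values[:, sub_cols]
        for _ in range(t):
            for attempt in range(max_split_retries):
                perm = rng.permutation(n)
                train_idx, test_idx = perm[:n_train], perm[n_train:]
                if set(y[test_idx].tolist()) == class_set:
                    break
            else:
                raise RuntimeError(
                    "could not draw a 50/50 split with every class in the "
                    f"test half after {max_split_retries} tries"
                )
            root = build_tree(
                Xsub[train_idx], y[train_idx], sub_names, max_depth=max_depth
            )
            pred = predict_tree(root, Xsub[test_idx], sub_names)
            w = weighted_rate(confusion_counts(y[test_idx], pred, classes))
            n_root = root.n_samples
            for node in iter_internal_nodes(root):
                scores[node.feature] += w * node.info_gain * node.n_samples / n_root
            if trees is not None:
                trees.append(
                    FittedTree(
                        root=root,
                        feature_subset=tuple(sub_names),
                        weighted_rate=w,
                    )
                )
    return RIResult(
        scores=scores,
        s=s,
        t=t,
        subset_sizes=tuple(len(c) for c in subsets),
        seed=seed,
        trees=trees,
    )


def reaccumulate_ri(result: RIResult) -> dict[str, float]:
    """Recompute RI scores by walking the stored trees (oracle path)."""
    if result.trees is None:
        raise ValueError("forest was built with keep_trees=False")
    scores = {name: 0.0 for name in result.scores}
    for tree in result.trees:
        n_root = tree.root.n_samples
        for node in iter_internal_nodes(tree.root):
            scores[node.feature] += (
                tree.weighted_rate * node.info_gain * node.n_samples / n_root
            )
    return scores


# ---------------------------------------------------------------------------
# nested-subset selection


@dataclass
class SelectionResult:
    ranked: list[str]
    chosen: list[str]
    chosen_size: int
    scores: dict[int, float]

    def to_json_dict(self) -> dict:
        return {
            "chosen_size": self.chosen_size,
            "chosen": list(self.chosen),
            "scores": {str(k): v for k, v in sorted(self.scores.items())},
            "ranking_head": self.ranked[:50],
        }


def select_feature_subset(
    X: FeatureMatrix,
    y: Sequence[Hashable],
    ri: RIResult,
    size_grid: Sequence[int],
    eval_fn: Callable[[FeatureMatrix, Sequence[Hashable]], float],
) -> SelectionResult:
    """Score nested prefixes of the RI ranking; choose the smallest best.

    For each grid size q the top-q features by RI are evaluated with
    ``eval_fn`` (jackknife overall accuracy in the pipeline default);
    the chosen subset is the smallest q attaining the maximum score.
    """
    if len(size_grid) == 0:
        raise ValueError("empty size grid")
    d = X.n_features
    if any(q < 1 or q > d for q in size_grid):
        raise ValueError(f"grid sizes must be in [1, {d}]")
    ranked = ri.ranking()
    scores: dict[int, float] = {}
    for q in sorted(set(int(q) for q in size_grid)):
        scores[q] = float(eval_fn(X.subset(ranked[:q]), y))
    best = max(scores.values())
    chosen_size = min(q for q, v in scores.items() if v >= best - _TIE_TOL)
    return SelectionResult(
        ranked=ranked,
        chosen=ranked[:chosen_size],
        chosen_size=chosen_size,
        scores=scores,
    )
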