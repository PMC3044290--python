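"""Binary regression trees with variance-reduction splits.

The tree is grown top-down. At each node the split (predictor, value) with
the largest *score* is chosen, where the score of a split is the weighted
per-sample reduction of (population) variance in the label:

    w = Var(y) - (n_L / n) Var(y_L) - (n_R / n) Var(y_R)

Numerical splits test ``value < threshold`` (missing values go left);
categorical splits test ``value in subset`` (unknown tokens go right).
Growth stops at a depth limit, at a node-size floor, or when no split
improves. Pruning repeatedly collapses the intermediate node of minimal
growth-time score and returns the member of the resulting tree sequence
with the smallest mean-square error on a validation table.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import DataTable
from .predictors import PredictorRegistry

__all__ = [
    "Split",
    "TreeNode",
    "RegressionTree",
    "split_score",
    "best_split",
    "grow_tree",
    "prune_tree",
    "predict",
    "predict_table",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Split:
    predictor: str
    kind: str  # "numerical" | "categorical"
    threshold: float | None = None
    category_subset: frozenset | None = None
    score: float = 0.0

    def goes_left(self, value) -> bool:
        if self.kind == "numerical":
            v = float(value) if value is not None else float("nan")
            return bool(np.isnan(v) or v < self.threshold)
        return value in self.category_subset

    def left_mask(self, column: np.ndarray) -> np.ndarray:
        if self.kind == "numerical":
            col = np.asarray(column, dtype=float)
            with np.errstate(invalid="ignore"):
                return np.isnan(col) | (col < self.threshold)
        return np.isin(np.asarray(column, dtype=object),
                       list(self.category_subset))

    def describe(self) -> str:
        if self.kind == "numerical":
            return f"{self.predictor} < {self.threshold:.6g}"
        cats = ",".join(sorted(map(str, self.category_subset)))
        return f"{self.predictor} in {{{cats}}}"


@dataclass
class TreeNode:
    """Internal node (split + children) or leaf; every node stores the mean
    label and count of the training rows falling into it."""

    leaf_mean: float
    n_fall: int
    depth: int
    node_id: int
    split: Split | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def walk(self):
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()

    def count_nodes(self) -> int:
        return sum(1 for _ in self.walk())


@dataclass
class RegressionTree:
    root: TreeNode
    max_depth: int
    min_node_size: int
    registry: PredictorRegistry
    metadata: dict = field(default_factory=dict)

    def n_nodes(self) -> int:
        return self.root.count_nodes()

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if not n.is_leaf]

    # -- prediction ---------------------------------------------------------

    def predict_row(self, x: dict) -> float:
        node = self.root
        while not node.is_leaf:
            node = node.left if node.split.goes_left(x.get(node.split.predictor)) \
                else node.right
        return node.leaf_mean

    def predict_frame(self, df) -> np.ndarray:
        out = np.empty(len(df), dtype=float)
        idx = np.arange(len(df))
        cols = {name: df[name].to_numpy() for name in self.registry.names
                if name in df.columns}
        _predict_into(self.root, cols, idx, out, frozenset())
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def node_dict(n: TreeNode) -> dict:
            d = {"leaf_mean": n.leaf_mean, "n_fall": n.n_fall,
                 "depth": n.depth, "node_id": n.node_id}
            if not n.is_leaf:
                s = n.split
                d["split"] = {
                    "predictor": s.predictor,
                    "kind": s.kind,
                    "threshold": s.threshold,
                    "category_subset": sorted(s.category_subset)
                    if s.category_subset is not None else None,
                    "score": s.score,
                }
                d["left"] = node_dict(n.left)
                d["right"] = node_dict(n.right)
            return d

        return {
            "root": node_dict(self.root),
            "max_depth": self.max_depth,
            "min_node_size": self.min_node_size,
            "registry": self.registry.to_config(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        def build(nd: dict) -> TreeNode:
            node = TreeNode(
                leaf_mean=float(nd["leaf_mean"]), n_fall=int(nd["n_fall"]),
                depth=int(nd["depth"]), node_id=int(nd["node_id"]),
            )
            if "split" in nd:
                s = nd["split"]
                node.split = Split(
                    predictor=s["predictor"], kind=s["kind"],
                    threshold=s["threshold"],
                    category_subset=frozenset(s["category_subset"])
                    if s["category_subset"] is not None else None,
                    score=float(s["score"]),
                )
                node.left = build(nd["left"])
                node.right = build(nd["right"])
            return node

        return cls(
            root=build(d["root"]),
            max_depth=int(d["max_depth"]),
            min_node_size=int(d["min_node_size"]),
            registry=PredictorRegistry.from_config(d["registry"]),
            metadata=d.get("metadata", {}),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "RegressionTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _predict_into(node: TreeNode, cols, idx, out, collapsed: frozenset) -> None:
    if node.is_leaf or node.node_id in collapsed or idx.size == 0:
        out[idx] = node.leaf_mean
        return
    mask = node.split.left_mask(cols[node.split.predictor][idx])
    _predict_into(node.left, cols, idx[mask], out, collapsed)
    _predict_into(node.right, cols, idx[~mask], out, collapsed)


def predict(tree: RegressionTree, x: dict) -> float:
    """Predicted stability for one predictor vector (root-to-leaf descent)."""
    return tree.predict_row(x)


def predict_table(tree: RegressionTree, table: DataTable) -> np.ndarray:
    return tree.predict_frame(table.df)


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

def split_score(y_values: np.ndarray, left_mask: np.ndarray) -> float:
    """Variance reduction of a binary partition (population variances):
    ``Var(y) - (n_L/n) Var(y_L) - (n_R/n) Var(y_R)``."""
    y = np.asarray(y_values, dtype=float)
    mask = np.asarray(left_mask, dtype=bool)
    if y.shape != mask.shape:
        raise ValueError("y_values and left_mask must have the same shape")
    n = y.size
    n_l = int(mask.sum())
    if n_l == 0 or n_l == n:
        raise ValueError("both sides of a split must be nonempty")
    y_l = y[mask]
    y_r = y[~mask]
    w = y.var() - (n_l / n) * y_l.var() - ((n - n_l) / n) * y_r.var()
    return float(max(w, 0.0))


def _sse_from_sums(s: np.ndarray, s2: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return s2 - s * s / n


def _scan_numeric(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Best threshold for one numerical predictor.

    Candidates are midpoints between consecutive distinct sorted values;
    missing (NaN) rows lie on the left side of every candidate. Returns
    (threshold, score) maximizing the score, smallest threshold on ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    nan_mask = np.isnan(x)
    xf = x[~nan_mask]
    if xf.size < 1:
        return None
    order = np.argsort(xf, kind="stable")
    xs = xf[order]
    ys = y[~nan_mask][order]
    distinct = np.flatnonzero(np.diff(xs) > 0)
    if distinct.size == 0:
        return None
    s_nan = float(y[nan_mask].sum())
    s2_nan = float((y[nan_mask] ** 2).sum())
    n_nan = int(nan_mask.sum())

    cy = np.cumsum(ys)
    cy2 = np.cumsum(ys * ys)
    j = distinct  # left block = xs[:j+1] plus all NaN rows
    n_l = (j + 1) + n_nan
    s_l = cy[j] + s_nan
    s2_l = cy2[j] + s2_nan
    n_tot = n
    s_tot = float(y.sum())
    s2_tot = float((y * y).sum())
    sse_l = _sse_from_sums(s_l, s2_l, n_l.astype(float))
    sse_r = _sse_from_sums(s_tot - s_l, s2_tot - s2_l,
                           (n_tot - n_l).astype(float))
    sse_tot = _sse_from_sums(np.array(s_tot), np.array(s2_tot), float(n_tot))
    scores = (sse_tot - sse_l - sse_r) / n_tot
    best = int(np.argmax(scores))  # first (= smallest threshold) on ties
    threshold = 0.5 * (xs[j[best]] + xs[j[best] + 1])
    return float(threshold), float(max(scores[best], 0.0))


def _category_stats(tokens: np.ndarray, y: np.ndarray):
    cats, inverse = np.unique(np.asarray(tokens, dtype=str), return_inverse=True)
    k = cats.size
    counts = np.bincount(inverse, minlength=k).astype(float)
    sums = np.bincount(inverse, weights=y, minlength=k)
    sums2 = np.bincount(inverse, weights=y * y, minlength=k)
    return cats, counts, sums, sums2


def _score_subset(sel_n, sel_s, sel_s2, n_tot, s_tot, s2_tot):
    if sel_n == 0 or sel_n == n_tot:
        return None
    sse_tot = s2_tot - s_tot * s_tot / n_tot
    sse_l = sel_s2 - sel_s * sel_s / sel_n
    nr = n_tot - sel_n
    sr = s_tot - sel_s
    sse_r = (s2_tot - sel_s2) - sr * sr / nr
    return max((sse_tot - sse_l - sse_r) / n_tot, 0.0)


def _scan_categorical(
    tokens: np.ndarray, y: np.ndarray, exhaustive: bool = False
) -> tuple[frozenset, float] | None:
    """Best category subset for one categorical predictor.

    Default mode sorts categories by mean label and scans prefix subsets
    (optimal for least-squares binary splits); ``exhaustive`` enumerates all
    proper bipartitions instead (used for verification).
    """
    y = np.asarray(y, dtype=float)
    cats, counts, sums, sums2 = _category_stats(tokens, y)
    if cats.size < 2:
        return None
    n_tot = float(y.size)
    s_tot = float(y.sum())
    s2_tot = float((y * y).sum())

    if exhaustive:
        best: tuple[frozenset, float] | None = None
        others = list(range(1, cats.size))
        for r in range(0, cats.size - 1):
            for combo in itertools.combinations(others, r):
                sel = (0,) + combo  # category 0 fixed left: canonical halves
                score = _score_subset(
                    counts[list(sel)].sum(), sums[list(sel)].sum(),
                    sums2[list(sel)].sum(), n_tot, s_tot, s2_tot,
                )
                if score is None:
                    continue
                subset = frozenset(cats[list(sel)])
                if best is None or score > best[1] + _EPS or (
                    abs(score - best[1]) <= _EPS and len(subset) < len(best[0])
                ):
                    best = (subset, score)
        return best

    means = sums / counts
    order = np.lexsort((cats, means))  # mean ascending, token on ties
    c_n = np.cumsum(counts[order])
    c_s = np.cumsum(sums[order])
    c_s2 = np.cumsum(sums2[order])
    best = None
    for k in range(cats.size - 1):
        score = _score_subset(c_n[k], c_s[k], c_s2[k], n_tot, s_tot, s2_tot)
        if score is None:
            continue
        if best is None or score > best[1]:
            best = (frozenset(cats[order[:k + 1]]), score)
    return best


def best_split(
    table: DataTable | None,
    registry: PredictorRegistry | None = None,
    *,
    df=None,
    y: np.ndarray | None = None,
    exhaustive_categorical: bool = False,
) -> Split | None:
    """Highest-scoring split over all registered predictors, or ``None``.

    Ties are broken by registry order, then by smaller threshold (numerical)
    or the first subset in the mean-sorted prefix scan (categorical).
    """
    if table is not None:
        df = table.df
        registry = registry or table.registry
        y = table.y
    if registry is None or df is None or y is None:
        raise ValueError("need a table, or df + y + registry")
    n = len(y)
    if n < 2:
        return None
    s_tot = float(np.sum(y))
    s2_tot = float(np.sum(np.asarray(y, dtype=float) ** 2))
    if _sse_from_sums(np.array(s_tot), np.array(s2_tot), float(n)) <= n * _EPS:
        return None  # label effectively constant

    best: Split | None = None
    for spec in registry:
        column = df[spec.name].to_numpy()
        if spec.kind == "numerical":
            found = _scan_numeric(column, y)
            if found is None:
                continue
            threshold, score = found
            candidate = Split(spec.name, "numerical", threshold=threshold,
                              score=score)
        else:
            found = _scan_categorical(column, y, exhaustive_categorical)
            if found is None:
                continue
            subset, score = found
            candidate = Split(spec.name, "categorical", category_subset=subset,
                              score=score)
        if candidate.score <= _EPS:
            continue
        if best is None or candidate.score > best.score + _EPS:
            best = candidate
    return best


# ---------------------------------------------------------------------------
# Growth and pruning
# ---------------------------------------------------------------------------

def grow_tree(
    train: DataTable,
    max_depth: int = 5,
    min_node_size: int = 10,
    registry: PredictorRegistry | None = None,
    exhaustive_categorical: bool = False,
) -> RegressionTree:
    """Grow a tree top-down; a node becomes a leaf at the depth limit, below
    the node-size floor, or when no positive-score split exists."""
    if train.n_rows == 0:
        raise ValueError("cannot grow a tree from an empty table")
    registry = registry or train.registry
    df = train.df
    y = train.y
    cols = {spec.name: df[spec.name].to_numpy() for spec in registry}
    counter = itertools.count()

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(
            leaf_mean=float(y[idx].mean()), n_fall=int(idx.size),
            depth=depth, node_id=next(counter),
        )
        if depth >= max_depth or idx.size < min_node_size:
            return node
        sub_df = df.iloc[idx]
        split = best_split(
            None, registry, df=sub_df, y=y[idx],
            exhaustive_categorical=exhaustive_categorical,
        )
        if split is None:
            return node
        mask = split.left_mask(cols[split.predictor][idx])
        if mask.all() or not mask.any():
            return node
        node.split = split
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    root = build(np.arange(train.n_rows), 0)
    return RegressionTree(
        root=root, max_depth=max_depth, min_node_size=min_node_size,
        registry=registry,
        metadata={"n_train": train.n_rows, "l": train.l, "l_prime": train.l_prime},
    )


def _collapse_order(tree: RegressionTree) -> list[TreeNode]:
    """Deterministic collapse priority: minimal split score first, ties by
    greater depth, then registry order of the split predictor, then id."""
    reg = tree.registry

    def key(node: TreeNode):
        return (node.split.score, -node.depth,
                reg.index(node.split.predictor), node.node_id)

    return sorted(tree.internal_nodes(), key=key)


def prune_sequence(tree: RegressionTree) -> list[frozenset]:
    """Collapsed-node sets of the pruning sequence, from the full tree
    (empty set) down to a single leaf (root collapsed)."""
    order = _collapse_order(tree)
    sequence = [frozenset()]
    collapsed: set[int] = set()
    # descendant map for subsumption: collapsing an ancestor absorbs children
    descendants: dict[int, set[int]] = {}

    def collect(node: TreeNode) -> set[int]:
        ids = set()
        if not node.is_leaf:
            for child in (node.left, node.right):
                ids |= {child.node_id} | collect(child)
        descendants[node.node_id] = ids
        return ids

    collect(tree.root)
    for node in order:
        if node.node_id in collapsed or any(
            node.node_id in descendants[c] for c in collapsed
        ):
            continue
        collapsed.add(node.node_id)
        collapsed -= {c for c in collapsed if c in descendants[node.node_id]}
        sequence.append(frozenset(collapsed))
    return sequence


def _materialize(tree: RegressionTree, collapsed: frozenset) -> RegressionTree:
    def copy(node: TreeNode) -> TreeNode:
        out = TreeNode(
            leaf_mean=node.leaf_mean, n_fall=node.n_fall,
            depth=node.depth, node_id=node.node_id,
        )
        if not node.is_leaf and node.node_id not in collapsed:
            out.split = node.split
            out.left = copy(node.left)
            out.right = copy(node.right)
        return out

    return RegressionTree(
        root=copy(tree.root), max_depth=tree.max_depth,
        min_node_size=tree.min_node_size, registry=tree.registry,
        metadata=dict(tree.metadata),
    )


def prune_tree(tree: RegressionTree, validation: DataTable) -> RegressionTree:
    """Adaptive pruning: among the collapse sequence (full tree down to a
    single leaf), return the tree with minimal validation MSE; on (near)
    ties the tree with fewer nodes wins."""
    if validation.n_rows == 0:
        raise ValueError("validation table must be nonempty")
    df = validation.df
    y_val = validation.y
    cols = {name: df[name].to_numpy() for name in tree.registry.names}
    idx = np.arange(len(df))
    out = np.empty(len(df))

    best_collapsed = frozenset()
    best_mse = np.inf
    for collapsed in prune_sequence(tree):
        _predict_into(tree.root, cols, idx, out, collapsed)
        mse = float(np.mean((out - y_val) ** 2))
        if mse <= best_mse + _EPS:
            best_mse = min(best_mse, mse)
            best_collapsed = collapsed
    pruned = _materialize(tree, best_collapsed)
    pruned.metadata["validation_mse"] = best_mse
    pruned.metadata["n_validation"] = validation.n_rows
    return pruned
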