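"""Cost-sensitive binary classification trees on (field, code) indicators.

A from-scratch CART-style learner specialized to sparse binary
presence/absence features over diagnosis and procedure codes, with:

* **altered class priors** — a prior LGIB probability π is converted into
  per-class case weights ``w_j ∝ π_j / N_j`` that enter every node
  proportion, impurity and risk, equivalently raising the cost of missing a
  case;
* **Gini impurity** ``i(t) = p(1 − p)`` with weighted case proportion p;
* split selection maximizing ``Δi(s, t) = i(t) − p_L i(t_L) − p_R i(t_R)``
  with weighted branch fractions p_L, p_R;
* a minimum terminal node size on raw (unweighted) observation counts;
* cost-complexity (weakest-link) pruning with seeded, class-stratified
  cross-validation;
* flattening of a fitted tree into an ordered IF/ELSE rule list.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import sparse

from .core import Admission, Cohort, Field, LgibError, field_rank, has_code
from .rules import Literal, RuleClause, RuleList

__all__ = [
    "PriorSpec",
    "NodeStats",
    "SplitEvaluation",
    "TreeNode",
    "Tree",
    "weights_from_prior",
    "gini",
    "delta_impurity",
    "best_split",
    "grow_tree",
    "prune",
    "flatten",
    "tree_to_json",
    "save_tree",
]

#: Two deltas closer than this are treated as tied and broken by feature order.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PriorSpec:
    """A prior LGIB probability and the per-class weights it induces.

    Weights satisfy ``w_case / w_noncase = [π/(1−π)] / [N_case/N_noncase]``
    with the non-case weight normalized to 1, so that the weighted case
    fraction at the root equals π.
    """

    pi: float
    w_case: float
    w_noncase: float = 1.0

    @property
    def ratio(self) -> float:
        """Case-to-non-case weight ratio (the 'k times the weight' figure)."""
        return self.w_case / self.w_noncase


def weights_from_prior(pi: float, n_case: int, n_noncase: int) -> PriorSpec:
    """Per-class weights that move the root case fraction to ``pi``.

    With the derivation cohort's class counts (297 vs 6,677), π = 0.20 gives
    a ratio ≈ 5.62 (cases weigh ~6× non-cases) and π = 0.70 gives ≈ 52.4.
    """
    if not 0.0 < pi < 1.0:
        raise LgibError(f"prior must be in (0, 1), got {pi}")
    if n_case <= 0 or n_noncase <= 0:
        raise LgibError("both classes must be present to derive prior weights")
    w_case = (pi / (1.0 - pi)) / (n_case / n_noncase)
    return PriorSpec(pi=pi, w_case=w_case, w_noncase=1.0)


def gini(p: float) -> float:
    """Two-class Gini impurity ``p(1 − p)``; maximal (0.25) at p = 0.5."""
    if not 0.0 <= p <= 1.0:
        raise LgibError(f"proportion must be in [0, 1], got {p}")
    return p * (1.0 - p)


@dataclass(frozen=True)
class NodeStats:
    """Raw class counts and the weighted statistics they induce at a node."""

    n_case: int
    n_noncase: int
    w_case: float
    w_noncase: float

    @property
    def n(self) -> int:
        return self.n_case + self.n_noncase

    @property
    def weight(self) -> float:
        return self.w_case * self.n_case + self.w_noncase * self.n_noncase

    @property
    def p_case(self) -> float:
        w = self.weight
        return (self.w_case * self.n_case / w) if w > 0 else 0.0

    @property
    def impurity(self) -> float:
        return gini(self.p_case)

    @property
    def is_pure(self) -> bool:
        return self.n_case == 0 or self.n_noncase == 0

    @property
    def majority(self) -> bool:
        """Weighted-majority class; an exact tie predicts non-LGIB."""
        return self.w_case * self.n_case > self.w_noncase * self.n_noncase


@dataclass(frozen=True)
class SplitEvaluation:
    """A candidate split with its weighted impurity decrease."""

    feature: Tuple[Field, str]
    delta: float
    p_left: float
    p_right: float
    left: NodeStats
    right: NodeStats


def delta_impurity(parent: NodeStats, left: NodeStats, right: NodeStats) -> float:
    """``Δi = i(t) − p_L i(t_L) − p_R i(t_R)`` with weighted p_L, p_R.

    ``left`` and ``right`` must partition ``parent``'s observations class by
    class, and neither side may be empty.
    """
    if (
        left.n_case + right.n_case != parent.n_case
        or left.n_noncase + right.n_noncase != parent.n_noncase
    ):
        raise LgibError("children do not partition the parent's observations")
    if left.n == 0 or right.n == 0:
        raise LgibError("a split may not leave an empty child")
    w = parent.weight
    return (
        parent.impurity
        - (left.weight / w) * left.impurity
        - (right.weight / w) * right.impurity
    )


# ---------------------------------------------------------------------------
# Feature matrix


class _FeatureIndex(dict):
    """Feature -> column lookup returning ``None`` for unknown features."""

    def __missing__(self, key):
        return None


class _Dataset:
    """Sparse binary indicator matrix over every (field, code) pair present
    in a cohort, with features in canonical (field order, code) order."""

    def __init__(self, cohort: Cohort, require_labels: bool = True):
        if require_labels:
            cohort.require_labels()
        feats = sorted(
            {fc for a in cohort for fc in a.iter_features()},
            key=lambda fc: (field_rank(fc[0]), fc[1]),
        )
        index = {fc: j for j, fc in enumerate(feats)}
        rows, cols = [], []
        for i, a in enumerate(cohort):
            for fc in a.iter_features():
                rows.append(i)
                cols.append(index[fc])
        n, m = len(cohort), len(feats)
        self.features: List[Tuple[Field, str]] = feats
        self.X = sparse.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, m)
        )
        self.y = np.array([bool(a.lgib) for a in cohort])
        self.cohort = cohort
        self.feature_index = _FeatureIndex(index)

    def carrier_mask(self, idx: np.ndarray, fi: int) -> np.ndarray:
        col = self.X[idx, fi]
        return np.asarray(col.todense()).ravel() > 0


def _stats(n_case: int, n_noncase: int, prior: PriorSpec) -> NodeStats:
    return NodeStats(int(n_case), int(n_noncase), prior.w_case, prior.w_noncase)


def _best_split_idx(
    ds: _Dataset, idx: np.ndarray, prior: PriorSpec, min_node: int
) -> Optional[Tuple[int, SplitEvaluation]]:
    y = ds.y[idx]
    n1 = int(y.sum())
    n0 = len(idx) - n1
    if n1 == 0 or n0 == 0:
        return None
    sub = ds.X[idx]
    c1 = np.asarray(sub[y].sum(axis=0), dtype=np.int64).ravel()
    c0 = np.asarray(sub[~y].sum(axis=0), dtype=np.int64).ravel()
    w1, w0 = prior.w_case, prior.w_noncase
    W = w1 * n1 + w0 * n0
    i_t = gini(w1 * n1 / W)
    WL = w1 * c1 + w0 * c0
    WR = W - WL
    nL = c1 + c0
    nR = len(idx) - nL
    with np.errstate(divide="ignore", invalid="ignore"):
        pL_case = np.where(WL > 0, w1 * c1 / WL, 0.0)
        pR_case = np.where(WR > 0, w1 * (n1 - c1) / WR, 0.0)
    delta = i_t - (WL / W) * pL_case * (1 - pL_case) - (WR / W) * pR_case * (1 - pR_case)
    valid = (nL >= min_node) & (nR >= min_node) & (delta > _TIE_TOL)
    if not valid.any():
        return None
    masked = np.where(valid, delta, -np.inf)
    best = masked.max()
    fi = int(np.nonzero(valid & (masked >= best - _TIE_TOL))[0][0])
    left = _stats(c1[fi], c0[fi], prior)
    right = _stats(n1 - c1[fi], n0 - c0[fi], prior)
    return fi, SplitEvaluation(
        feature=ds.features[fi],
        delta=float(delta[fi]),
        p_left=left.weight / W,
        p_right=right.weight / W,
        left=left,
        right=right,
    )


def best_split(
    cohort: Cohort, prior: PriorSpec, min_node: int = 7
) -> Optional[SplitEvaluation]:
    """The (field, code) indicator split maximizing the weighted Gini
    decrease over a labeled cohort, or ``None`` when no admissible split
    improves impurity (each child must hold at least ``min_node`` raw
    observations).  Exact delta ties break toward the earlier field in
    canonical order, then the lexicographically smaller code.
    """
    ds = _Dataset(cohort)
    out = _best_split_idx(ds, np.arange(len(cohort)), prior, min_node)
    return out[1] if out is not None else None


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    stats: NodeStats
    prediction: bool
    feature: Optional[Tuple[Field, str]] = None
    present: Optional["TreeNode"] = None  # child where the code IS carried
    absent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self) -> Iterable["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            yield from self.present.leaves()
            yield from self.absent.leaves()

    def internal_nodes(self) -> Iterable["TreeNode"]:
        if not self.is_leaf:
            yield self
            yield from self.present.internal_nodes()
            yield from self.absent.internal_nodes()


@dataclass
class Tree:
    """A fitted binary classification tree plus its growth parameters."""

    root: TreeNode
    prior: PriorSpec
    min_node: int

    def predict(self, a: Admission) -> bool:
        node = self.root
        while not node.is_leaf:
            f, code = node.feature
            node = node.present if has_code(a, f, code) else node.absent
        return node.prediction

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    @property
    def n_nodes(self) -> int:
        return self.n_leaves + sum(1 for _ in self.root.internal_nodes())


def _grow(
    ds: _Dataset,
    idx: np.ndarray,
    prior: PriorSpec,
    min_node: int,
    depth: int,
    max_depth: Optional[int],
) -> TreeNode:
    y = ds.y[idx]
    n1 = int(y.sum())
    stats = _stats(n1, len(idx) - n1, prior)
    node = TreeNode(stats=stats, prediction=stats.majority)
    if (
        stats.is_pure
        or stats.n < 2 * min_node
        or (max_depth is not None and depth >= max_depth)
    ):
        return node
    found = _best_split_idx(ds, idx, prior, min_node)
    if found is None:
        return node
    fi, ev = found
    mask = ds.carrier_mask(idx, fi)
    node.feature = ev.feature
    node.present = _grow(ds, idx[mask], prior, min_node, depth + 1, max_depth)
    node.absent = _grow(ds, idx[~mask], prior, min_node, depth + 1, max_depth)
    return node


def grow_tree(
    cohort: Cohort,
    pi: float,
    min_node: int = 7,
    max_depth: Optional[int] = None,
) -> Tree:
    """Grow a tree by recursive partitioning at prior ``pi``.

    Splitting stops at purity, when fewer than ``2 * min_node`` raw
    observations remain, when no split improves weighted impurity while
    keeping both children at ``min_node``, or at ``max_depth``.  A
    single-class cohort yields a root-only tree predicting that class.
    """
    cohort.require_labels()
    n_case = cohort.n_lgib
    n_noncase = len(cohort) - n_case
    if n_case == 0 or n_noncase == 0:
        prior = PriorSpec(pi=pi, w_case=1.0, w_noncase=1.0)
        stats = _stats(n_case, n_noncase, prior)
        return Tree(TreeNode(stats=stats, prediction=n_case > 0), prior, min_node)
    prior = weights_from_prior(pi, n_case, n_noncase)
    ds = _Dataset(cohort)
    root = _grow(ds, np.arange(len(cohort)), prior, min_node, 0, max_depth)
    return Tree(root, prior, min_node)


# ---------------------------------------------------------------------------
# Cost-complexity pruning


def _leaf_risk(node: TreeNode) -> float:
    """Weighted misclassification mass if ``node`` were a terminal."""
    s = node.stats
    return s.w_noncase * s.n_noncase if node.prediction else s.w_case * s.n_case


def _subtree_risk(node: TreeNode) -> Tuple[float, int]:
    if node.is_leaf:
        return _leaf_risk(node), 1
    rl, ll = _subtree_risk(node.present)
    rr, lr = _subtree_risk(node.absent)
    return rl + rr, ll + lr


def _collapse(node: TreeNode) -> None:
    node.feature = None
    node.present = None
    node.absent = None


def _alpha_sequence(tree: Tree) -> List[Tuple[float, Tree]]:
    """Weakest-link sequence of nested pruned subtrees.

    Returns ``[(alpha_0 = 0, T_0), (alpha_1, T_1), ...]`` ending in the
    root-only tree, with alphas non-decreasing.  Risks are normalized by the
    root's total weight.
    """
    work = copy.deepcopy(tree)
    W = work.root.stats.weight
    seq: List[Tuple[float, Tree]] = [(0.0, copy.deepcopy(work))]
    alpha_prev = 0.0
    while not work.root.is_leaf:
        links = []
        for node in work.root.internal_nodes():
            r_sub, n_leaves = _subtree_risk(node)
            g = (_leaf_risk(node) - r_sub) / W / (n_leaves - 1)
            links.append((g, node))
        g_min = min(g for g, _ in links)
        for g, node in links:
            if g <= g_min + _TIE_TOL and not node.is_leaf:
                _collapse(node)
        alpha_prev = max(alpha_prev, g_min)
        seq.append((alpha_prev, copy.deepcopy(work)))
    return seq


def _pick_subtree(seq: List[Tuple[float, Tree]], alpha: float) -> Tree:
    chosen = seq[0][1]
    for a, t in seq:
        if a <= alpha + _TIE_TOL:
            chosen = t
        else:
            break
    return chosen


def _predict_matrix(ds: _Dataset, node: TreeNode, idx: np.ndarray, out: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] = node.prediction
        return
    fi = ds.feature_index[node.feature]
    if fi is None:
        # feature absent from this dataset: nobody carries it
        _predict_matrix(ds, node.absent, idx, out)
        return
    mask = ds.carrier_mask(idx, fi)
    _predict_matrix(ds, node.present, idx[mask], out)
    _predict_matrix(ds, node.absent, idx[~mask], out)


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    assignment = np.empty(len(y), dtype=int)
    for cls in (True, False):
        members = np.nonzero(y == cls)[0]
        perm = rng.permutation(members)
        assignment[perm] = np.arange(len(perm)) % folds
    return assignment


def prune(
    tree: Tree,
    cohort: Cohort,
    folds: int = 10,
    seed: int = 0,
    selection: str = "min",
) -> Tree:
    """Cost-complexity pruning with cross-validated subtree selection.

    The weakest-link alpha sequence is computed on ``tree``; candidate
    penalties are geometric midpoints of consecutive alphas.  For each
    seeded, class-stratified fold a tree is grown on the training part,
    pruned across the candidate penalties, and scored by weighted
    misclassification risk on the held-out part.  ``selection='min'``
    returns the subtree at the risk-minimizing penalty (ties favor the
    larger penalty, i.e. the smaller subtree); ``'1se'`` picks the smallest
    subtree within one standard error of the minimum.
    """
    if folds < 2:
        raise LgibError("cross-validation requires at least 2 folds")
    if selection not in ("min", "1se"):
        raise LgibError(f"selection must be 'min' or '1se', got {selection!r}")
    if tree.root.is_leaf:
        return copy.deepcopy(tree)
    seq = _alpha_sequence(tree)
    alphas = [a for a, _ in seq]
    candidates = []
    for k in range(len(alphas)):
        if k + 1 < len(alphas):
            lo, hi = alphas[k], alphas[k + 1]
            candidates.append(math.sqrt(lo * hi) if lo > 0 else hi / 2.0)
        else:
            candidates.append(alphas[k] * 2.0 + 1.0)

    ds = _Dataset(cohort)
    prior = tree.prior
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(ds.y, folds, rng)
    w = np.where(ds.y, prior.w_case, prior.w_noncase)

    fold_risks = np.zeros((folds, len(candidates)))
    all_idx = np.arange(len(cohort))
    for f in range(folds):
        test = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        if len(test) == 0 or len(train) == 0:
            continue
        root_f = _grow(ds, train, prior, tree.min_node, 0, None)
        tree_f = Tree(root_f, prior, tree.min_node)
        seq_f = _alpha_sequence(tree_f)
        for c, alpha in enumerate(candidates):
            sub = _pick_subtree(seq_f, alpha)
            pred = np.zeros(len(cohort), dtype=bool)
            _predict_matrix(ds, sub.root, test, pred)
            miss = pred[test] != ds.y[test]
            fold_risks[f, c] = float((w[test] * miss).sum())

    total = fold_risks.sum(axis=0) / w.sum()
    best = total.min()
    if selection == "min":
        # ties -> larger penalty -> smaller subtree
        k_best = max(i for i, r in enumerate(total) if r <= best + _TIE_TOL)
    else:
        se = float(fold_risks.std(axis=0, ddof=1).max()) / math.sqrt(folds)
        k_best = max(i for i, r in enumerate(total) if r <= best + se + _TIE_TOL)
    return copy.deepcopy(seq[k_best][1])


# ---------------------------------------------------------------------------
# Flattening


def flatten(tree: Tree) -> RuleList:
    """Flatten a tree into an ordered first-match rule list.

    Depth-first, positive branch first: each LGIB-predicting terminal
    contributes one clause holding the conjunction of presence/absence
    literals on its path.  Negative literals implied by the failure of an
    earlier single-test clause are dropped, so a single-branch tree (the
    shape the shipped rules have) flattens to plain IF/ELSE-IF code tests.
    The default class is non-LGIB; predictions agree with the tree on every
    admission.
    """
    paths: List[Tuple[Literal, ...]] = []

    def visit(node: TreeNode, path: Tuple[Literal, ...]) -> None:
        if node.is_leaf:
            if node.prediction:
                paths.append(path)
            return
        f, code = node.feature
        visit(node.present, path + (Literal(f, code, True),))
        visit(node.absent, path + (Literal(f, code, False),))

    visit(tree.root, ())
    clauses: List[RuleClause] = []
    singles: set = set()
    for lits in paths:
        # drop negatives already implied by an earlier simple clause failing
        kept = tuple(
            lit
            for lit in lits
            if lit.present or (lit.field, lit.code) not in singles
        )
        clause = RuleClause(kept, True)
        clauses.append(clause)
        if len(kept) == 1 and kept[0].present:
            singles.add((kept[0].field, kept[0].code))
    return RuleList(
        tuple(clauses),
        default=False,
        provenance=f"flattened tree (pi={tree.prior.pi}, min_node={tree.min_node})",
        metadata={"pi": tree.prior.pi, "min_node": tree.min_node},
    )


# ---------------------------------------------------------------------------
# Serialization


def _node_to_json(node: TreeNode) -> dict:
    doc = {
        "n_case": node.stats.n_case,
        "n_noncase": node.stats.n_noncase,
        "prediction": "LGIB" if node.prediction else "Not LGIB",
    }
    if not node.is_leaf:
        doc["split"] = {"field": node.feature[0].value, "code": node.feature[1]}
        doc["present"] = _node_to_json(node.present)
        doc["absent"] = _node_to_json(node.absent)
    return doc


def tree_to_json(tree: Tree) -> dict:
    return {
        "pi": tree.prior.pi,
        "weight_ratio": tree.prior.ratio,
        "min_node": tree.min_node,
        "root": _node_to_json(tree.root),
    }


def save_tree(tree: Tree, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(tree_to_json(tree), indent=2) + "\n", encoding="utf-8")
    return path
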