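"""Functional regression trees for a curve response.

A node holds a set of observations and their current FPCA-denoised curves
f~_i(t); its representative curve is the pointwise average
f^_R(t) = sum_{i in R} f~_i(t) / n_R.  Node heterogeneity is the integrated
squared error RSS_f(R) = sum_i int (f~_i - f^_R)^2 dt, and a candidate split
(j, s) is scored by the between-child separation

    phi(j, s, R) = int (f^_{R_L} - f^_{R_R})^2 dt,

maximized over ten equally spaced thresholds per continuous predictor and
every binary level partition per categorical predictor.  Rows with
X_ij < s go left, X_ij >= s go right.  After a split is realized, FPCA is
refit within each child (when large enough) so the denoised curves track the
child's own mean and covariance structure.  Trees grow to a maximum depth
and can be pruned back in reverse growth order by five-fold cross-validated
prediction ISE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .containers import CATEGORICAL, CONTINUOUS, CurveMatrix, Grid, PredictorTable
from .exceptions import InvalidInputError, InvalidNodeError
from .fpca import ADAPTIVE, FpcaModel, fit_fpca
from .params import FunForParams
from ._pspline import PsplineBasis

__all__ = [
    "SplitRule",
    "TreeNode",
    "FunctionalTree",
    "node_mean_curve",
    "rss_f",
    "split_criterion",
    "candidate_splits",
    "best_split",
    "grow_tree",
    "fit_tree",
    "prune_tree",
    "predict_tree",
]


@dataclass
class SplitRule:
    predictor_index: int
    kind: str  # "threshold" | "subset"
    threshold: float | None = None
    left_levels: tuple | None = None
    phi: float = float("nan")

    def goes_left(self, x: np.ndarray) -> np.ndarray:
        """Boolean mask: True where a row routes to the left child."""
        x = np.asarray(x, dtype=float)
        if self.kind == "threshold":
            return x < self.threshold
        return np.isin(x, np.asarray(self.left_levels, dtype=float))

    def to_dict(self) -> dict:
        return {
            "predictor_index": int(self.predictor_index),
            "kind": self.kind,
            "threshold": None if self.threshold is None else float(self.threshold),
            "left_levels": None if self.left_levels is None else list(self.left_levels),
            "phi": float(self.phi),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitRule":
        return cls(
            predictor_index=int(d["predictor_index"]),
            kind=d["kind"],
            threshold=d["threshold"],
            left_levels=None if d["left_levels"] is None else tuple(d["left_levels"]),
            phi=d["phi"],
        )


@dataclass
class TreeNode:
    node_id: int
    depth: int
    member_indices: np.ndarray
    mean_curve: np.ndarray
    split: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    split_order: int | None = None  # position in the growth log, internal nodes only
    node_fpca: FpcaModel | None = field(default=None, repr=False)

    @property
    def n_R(self) -> int:
        return len(self.member_indices)

    @property
    def is_leaf(self) -> bool:
        return self.split is None


class FunctionalTree:
    """A grown (optionally pruned) functional regression tree."""

    def __init__(
        self,
        root: TreeNode,
        grid: Grid,
        growth_log: list[tuple[int, SplitRule]],
        column_types: list[str],
        hyperparams: FunForParams,
    ):
        self.root = root
        self.grid = grid
        self.growth_log = growth_log
        self.column_types = column_types
        self.hyperparams = hyperparams
        self.cv_ise_path: list[float] | None = None  # filled by prune_tree

    # ------------------------------------------------------------ traversal
    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def leaves(self):
        return [nd for nd in self.nodes() if nd.is_leaf]

    @property
    def n_splits(self) -> int:
        return len(self.growth_log)

    def used_predictors(self, max_splits: int | None = None) -> list[int]:
        m = self.n_splits if max_splits is None else min(max_splits, self.n_splits)
        return sorted({rule.predictor_index for _, rule in self.growth_log[:m]})

    # ----------------------------------------------------------- prediction
    def predict(self, X: np.ndarray, max_splits: int | None = None) -> np.ndarray:
        """Route rows to leaves; returns an (m, K) matrix of leaf mean curves.

        ``max_splits`` truncates the tree to its first ``max_splits`` splits
        in growth order (used during reverse-order pruning).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.grid.K))
        limit = self.n_splits if max_splits is None else max_splits
        stack = [(self.root, np.arange(X.shape[0]))]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if node.is_leaf or node.split_order >= limit:
                out[rows] = node.mean_curve
                continue
            mask = node.split.goes_left(X[rows, node.split.predictor_index])
            stack.append((node.left, rows[mask]))
            stack.append((node.right, rows[~mask]))
        return out

    def truncate(self, n_splits: int) -> "FunctionalTree":
        """Subtree keeping only the first ``n_splits`` splits in growth order."""

        def copy_node(node: TreeNode) -> TreeNode:
            if node.is_leaf or node.split_order >= n_splits:
                return TreeNode(
                    node.node_id, node.depth, node.member_indices, node.mean_curve
                )
            new = TreeNode(
                node.node_id,
                node.depth,
                node.member_indices,
                node.mean_curve,
                split=node.split,
                split_order=node.split_order,
            )
            new.left = copy_node(node.left)
            new.right = copy_node(node.right)
            return new

        sub = FunctionalTree(
            copy_node(self.root),
            self.grid,
            self.growth_log[:n_splits],
            self.column_types,
            self.hyperparams,
        )
        return sub

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d = {
                "node_id": int(node.node_id),
                "depth": int(node.depth),
                "member_indices": np.asarray(node.member_indices).tolist(),
                "mean_curve": np.asarray(node.mean_curve).tolist(),
                "split": None if node.split is None else node.split.to_dict(),
                "split_order": node.split_order,
            }
            if not node.is_leaf:
                d["left"] = node_dict(node.left)
                d["right"] = node_dict(node.right)
            return d

        return {
            "grid": self.grid.points.tolist(),
            "column_types": list(self.column_types),
            "hyperparams": self.hyperparams.to_dict(),
            "growth_log": [[nid, rule.to_dict()] for nid, rule in self.growth_log],
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunctionalTree":
        def build(nd: dict) -> TreeNode:
            node = TreeNode(
                node_id=nd["node_id"],
                depth=nd["depth"],
                member_indices=np.asarray(nd["member_indices"], dtype=int),
                mean_curve=np.asarray(nd["mean_curve"]),
                split=None if nd["split"] is None else SplitRule.from_dict(nd["split"]),
                split_order=nd["split_order"],
            )
            if node.split is not None:
                node.left = build(nd["left"])
                node.right = build(nd["right"])
            return node

        return cls(
            root=build(d["root"]),
            grid=Grid(np.asarray(d["grid"])),
            growth_log=[(nid, SplitRule.from_dict(rd)) for nid, rd in d["growth_log"]],
            column_types=list(d["column_types"]),
            hyperparams=FunForParams.from_dict(d["hyperparams"]),
        )


# ---------------------------------------------------------------- node math
def node_mean_curve(smoothed_rows: np.ndarray) -> np.ndarray:
    """Pointwise average f^_R of the member curves; errors on an empty node."""
    rows = np.atleast_2d(np.asarray(smoothed_rows, dtype=float))
    if rows.shape[0] == 0:
        raise InvalidNodeError("cannot average an empty node")
    return rows.mean(axis=0)


def rss_f(smoothed_rows: np.ndarray, mean_curve: np.ndarray, grid: Grid) -> float:
    """Integrated squared error of member curves around the node mean."""
    rows = np.atleast_2d(np.asarray(smoothed_rows, dtype=float))
    dev = rows - np.asarray(mean_curve)[None, :]
    return float(np.sum((dev**2) @ grid.trap_weights))

def split_criterion(left_mean: np.ndarray, right_mean: np.ndarray, grid: Grid) -> float:
    """Between-child separation phi = int (f^_L - f^_R)^2 dt."""
    d = np.asarray(left_mean) - np.asarray(right_mean)
    return float((d**2) @ grid.trap_weights)


def candidate_splits(
    column_values: np.ndarray,
    column_type: str,
    n_split_points: int = 10,
    min_node_size: int = 1,
    predictor_index: int = 0,
) -> list[SplitRule]:
    """Candidate split rules for one predictor column within a node.

    Continuous: ``n_split_points`` thresholds equally spaced strictly inside
    the node's observed range (the interior points of an
    ``n_split_points + 2``-point equipartition).  Categorical with c observed
    levels: all 2^(c-1) - 1 binary partitions, canonicalized so the left set
    contains the smallest level.  Candidates that would leave either child
    below ``min_node_size`` are dropped; a constant column yields no
    candidates.
    """
    x = np.asarray(column_values, dtype=float)
    m = x.size
    rules: list[SplitRule] = []
    if column_type == CONTINUOUS:
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            return []
        for i in range(1, n_split_points + 1):
            s = lo + (hi - lo) * i / (n_split_points + 1)
            n_left = int(np.sum(x < s))
            if n_left < min_node_size or m - n_left < min_node_size:
                continue
            rules.append(SplitRule(predictor_index, "threshold", threshold=s))
    elif column_type == CATEGORICAL:
        levels = sorted(np.unique(x).tolist())
        if len(levels) < 2:
            return []
        rest = levels[1:]
        subsets = []
        for r in range(0, len(rest)):
            for combo in combinations(rest, r):
                subsets.append((levels[0],) + combo)
        for left in sorted(subsets):
            mask = np.isin(x, np.asarray(left))
            n_left = int(mask.sum())
            if n_left < min_node_size or m - n_left < min_node_size:
                continue
            rules.append(SplitRule(predictor_index, "subset", left_levels=left))
    else:  # pragma: no cover - guarded upstream
        raise InvalidInputError(f"unknown column type {column_type!r}")
    return rules


def _score_candidates(
    rules: list[SplitRule],
    X_node: np.ndarray,
    F_node: np.ndarray,
    grid: Grid,
) -> np.ndarray:
    """phi for each candidate, vectorized via mask-matrix multiplication."""
    m = X_node.shape[0]
    masks = np.empty((len(rules), m))
    for r, rule in enumerate(rules):
        masks[r] = rule.goes_left(X_node[:, rule.predictor_index])
    counts = masks.sum(axis=1)
    total = F_node.sum(axis=0)
    left_sums = masks @ F_node
    left_means = left_sums / counts[:, None]
    right_means = (total[None, :] - left_sums) / (m - counts)[:, None]
    diff = left_means - right_means
    return (diff**2) @ grid.trap_weights


def best_split(
    X_node: np.ndarray,
    column_types: list[str],
    F_node: np.ndarray,
    grid: Grid,
    candidate_columns: np.ndarray,
    min_node_size: int,
    n_split_points: int = 10,
) -> SplitRule | None:
    """Exhaustive phi-maximization over the candidate columns' split points.

    Ties break deterministically: lowest predictor index first, then smallest
    threshold / lexicographically smallest left level set (the enumeration
    order of ``candidate_splits``), with a strict comparison keeping the
    first maximizer.
    """
    rules: list[SplitRule] = []
    for j in sorted(int(c) for c in candidate_columns):
        rules.extend(
            candidate_splits(
                X_node[:, j], column_types[j], n_split_points, min_node_size, j
            )
        )
    if not rules:
        return None
    phis = _score_candidates(rules, X_node, F_node, grid)
    best_idx = int(np.argmax(phis))  # first occurrence wins on exact ties
    rule = rules[best_idx]
    rule.phi = float(phis[best_idx])
    return rule


# ------------------------------------------------------------------- growth
def _refit_child_curves(
    raw_rows: np.ndarray,
    inherited_rows: np.ndarray,
    grid: Grid,
    params: FunForParams,
    root_L: int,
    basis: PsplineBasis,
) -> np.ndarray:
    """FPCA refit of a child's curves, or inheritance when the child is tiny."""
    m = raw_rows.shape[0]
    if not params.refit_per_node or m < max(params.min_fpca_n, 2):
        return inherited_rows
    if params.l_fixed is not None:
        L_override = min(params.l_fixed, m - 1)
    elif params.l_option == ADAPTIVE:
        L_override = None
    else:  # fixed dual rule: L pinned at the root-level choice
        L_override = min(root_L, m - 1)
    model = fit_fpca(
        CurveMatrix(raw_rows, grid),
        option=ADAPTIVE if params.l_option == ADAPTIVE else params.l_option,
        tau1=params.tau1,
        tau2=params.tau2,
        L_override=L_override,
        basis=basis,
        keep_cov=False,
    )
    return model.smoothed_curves


def grow_tree(
    curves: CurveMatrix,
    fpca: FpcaModel,
    predictors: PredictorTable,
    params: FunForParams,
    rng: np.random.Generator,
    basis: PsplineBasis | None = None,
) -> FunctionalTree:
    """Grow a functional regression tree to maximum depth.

    ``curves``/``predictors`` are the training rows (a bootstrap sample when
    called from the forest) and ``fpca`` the FPCA fit to those rows; its
    smoothed curves seed the root.  At every node an mtry-subset of
    predictors is drawn from ``rng``, the best phi-maximizing split is
    realized, and each child's curves are re-denoised by a fresh FPCA fit
    (subject to ``refit_per_node``/``min_fpca_n``).  Splits with phi = 0 are
    not realized.
    """
    if curves.n != predictors.n:
        raise InvalidInputError("curves and predictors disagree on n")
    grid = curves.grid
    if basis is None:
        basis = PsplineBasis(grid, params.n_basis)
    X = predictors.values
    mtry = params.resolve_mtry(predictors.p)
    root_L = fpca.L
    growth_log: list[tuple[int, SplitRule]] = []
    next_id = [0]

    def make_node(depth: int, members: np.ndarray, F: np.ndarray) -> TreeNode:
        node = TreeNode(
            node_id=next_id[0],
            depth=depth,
            member_indices=members,
            mean_curve=node_mean_curve(F),
        )
        next_id[0] += 1
        m = members.size
        if depth >= params.max_depth or m < 2 * params.min_node_size:
            return node
        cand_cols = np.sort(rng.choice(predictors.p, size=mtry, replace=False))
        if params.refit_per_candidate:
            rule = _best_split_refit(members, F, cand_cols)
        else:
            rule = best_split(
                X[members],
                predictors.column_types,
                F,
                grid,
                cand_cols,
                params.min_node_size,
                params.n_split_points,
            )
        if rule is None or not (rule.phi > 0.0):
            return node
        node.split = rule
        node.split_order = len(growth_log)
        growth_log.append((node.node_id, rule))
        mask = rule.goes_left(X[members, rule.predictor_index])
        for side, sel in (("left", mask), ("right", ~mask)):
            child_members = members[sel]
            child_F = _refit_child_curves(
                curves.values[child_members], F[sel], grid, params, root_L, basis
            )
            child = make_node(depth + 1, child_members, child_F)
            setattr(node, side, child)
        return node

    def _best_split_refit(members, F, cand_cols) -> SplitRule | None:
        """Per-candidate FPCA refit mode: phi from each candidate's refit children."""
        best_rule, best_phi = None, 0.0
        for j in sorted(int(c) for c in cand_cols):
            for rule in candidate_splits(
                X[members, j],
                predictors.column_types[j],
                params.n_split_points,
                params.min_node_size,
                j,
            ):
                mask = rule.goes_left(X[members, j])
                FL = _refit_child_curves(
                    curves.values[members[mask]], F[mask], grid, params, root_L, basis
                )
                FR = _refit_child_curves(
                    curves.values[members[~mask]], F[~mask], grid, params, root_L, basis
                )
                phi = split_criterion(FL.mean(axis=0), FR.mean(axis=0), grid)
                if phi > best_phi:
                    best_rule, best_phi = rule, phi
        if best_rule is not None:
            best_rule.phi = best_phi
        return best_rule

    root = make_node(0, np.arange(curves.n), fpca.smoothed_curves)
    return FunctionalTree(root, grid, growth_log, list(predictors.column_types), params)


def fit_tree(
    curves: CurveMatrix,
    predictors: PredictorTable,
    params: FunForParams,
    rng: np.random.Generator,
    basis: PsplineBasis | None = None,
) -> FunctionalTree:
    """Convenience: FPCA fit on the given rows followed by ``grow_tree``."""
    if basis is None:
        basis = PsplineBasis(curves.grid, params.n_basis)
    fpca = fit_fpca(
        curves,
        option=params.l_option,
        tau1=params.tau1,
        tau2=params.tau2,
        L_override=params.l_fixed,
        basis=basis,
        keep_cov=False,
    )
    return grow_tree(curves, fpca, predictors, params, rng, basis=basis)


def predict_tree(tree: FunctionalTree, new_predictor_row: np.ndarray) -> np.ndarray:
    """Leaf mean curve for one predictor row (threshold rows route right at s)."""
    row = np.asarray(new_predictor_row, dtype=float)
    if row.ndim != 1 or np.any(~np.isfinite(row)):
        raise InvalidInputError("predictor row must be a finite 1-d vector")
    return tree.predict(row[None, :])[0]


def prune_tree(
    tree: FunctionalTree,
    curves: CurveMatrix,
    predictors: PredictorTable,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> FunctionalTree:
    """Reverse-order pruning by cross-validated prediction ISE.

    The nested subtree sequence undoes splits in reverse growth order (full
    tree, ..., root stump).  For each subtree size m, a tree is grown afresh
    on each training fold and truncated to its first m splits; held-out rows
    are predicted and scored by ISE against their observed curves.  The size
    minimizing mean CV ISE wins (ties to the smaller subtree) and the
    full-data tree truncated to that size is returned, carrying the CV curve
    in ``cv_ise_path``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = curves.n
    n_sizes = tree.n_splits + 1
    if tree.n_splits == 0:
        tree.cv_ise_path = [0.0]
        return tree
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    w = curves.grid.trap_weights
    totals = np.zeros(n_sizes)
    count = 0
    basis = PsplineBasis(curves.grid, tree.hyperparams.n_basis)
    for fold in folds:
        if fold.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), fold)
        fold_tree = fit_tree(
            curves.subset(train), predictors.subset(train), tree.hyperparams, rng, basis
        )
        Xv = predictors.values[fold]
        Yv = curves.values[fold]
        for m in range(n_sizes):
            pred = fold_tree.predict(Xv, max_splits=min(m, fold_tree.n_splits))
            totals[m] += float(np.sum(((Yv - pred) ** 2) @ w))
        count += fold.size
    cv = totals / count
    best_m = int(np.argmin(cv))  # argmin takes the first (smallest) on ties
    pruned = tree.truncate(best_m)
    pruned.cv_ise_path = cv.tolist()
    return pruned
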