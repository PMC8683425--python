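"""Bootstrap ensembles of functional regression trees (the FunFor model).

Each tree is grown on a bootstrap sample of the observations with a fresh
mtry-subset of predictors drawn at every node.  Predictions for new rows
average the leaf mean curves over all trees; training rows can instead be
averaged over the trees whose bootstrap sample contains them (in-bag) or
excludes them (out-of-bag, the honest generalization proxy).

Permutation variable importance (PVIM) measures, for each predictor X_j,
the average increase in out-of-bag prediction ISE caused by permuting X_j
among each tree's out-of-bag rows:

    PVIM(X_j) = (1/ntree) sum_q (1/|B_q|) sum_{i in B_q}
                [ int (f~_i - f^p_i)^2 dt - int (f~_i - f^_i)^2 dt ]

where B_q is tree q's out-of-bag set, f~_i the full-data FPCA smooth of
observation i, f^_i tree q's prediction, and f^p_i the prediction after
permuting X_j within B_q.  Predictors never used by a tree's splits leave
routing unchanged, so their contribution from that tree is exactly zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._pspline import PsplineBasis
from .containers import CurveMatrix, Grid, PredictorTable
from .exceptions import InvalidInputError, NoOobCoverageError
from .fpca import FpcaModel, fit_fpca
from .params import FunForParams
from .tree import FunctionalTree, fit_tree, prune_tree

logger = logging.getLogger(__name__)

ALL_TREES = "all_trees"
INBAG = "inbag"
OOB = "oob"


def bootstrap_sample(n: int, rng: np.random.Generator):
    """n uniform draws with replacement; returns (indices, in-bag mask)."""
    if n < 2:
        raise InvalidInputError("bootstrap needs n >= 2")
    idx = rng.integers(0, n, size=n)
    inbag = np.zeros(n, dtype=bool)
    inbag[idx] = True
    return idx, inbag


@dataclass
class PvimResult:
    """Permutation importance scores with their deterministic ranking."""

    scores: np.ndarray
    ranking: np.ndarray  # predictor indices, descending score, ties by index
    n_permutations: np.ndarray  # per predictor: number of trees actually permuted
    column_names: list[str]

    def rank_of(self, predictor_index: int) -> int:
        """1-based rank position of a predictor in the importance ordering."""
        return int(np.nonzero(self.ranking == predictor_index)[0][0]) + 1

    def to_dict(self) -> dict:
        return {
            "scores": self.scores.tolist(),
            "ranking": self.ranking.tolist(),
            "n_permutations": self.n_permutations.tolist(),
            "column_names": list(self.column_names),
        }


def rank_scores(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score; exact ties by ascending index."""
    scores = np.asarray(scores)
    return np.lexsort((np.arange(scores.size), -scores))


class FunForForest:
    """A fitted ensemble of functional regression trees."""

    def __init__(
        self,
        trees: list[FunctionalTree],
        inbag: np.ndarray,
        params: FunForParams,
        grid: Grid,
        seed: int,
        reference_fpca: FpcaModel,
        column_names: list[str],
    ):
        self.trees = trees
        self.inbag = inbag  # (ntree, n) boolean
        self.params = params
        self.grid = grid
        self.seed = seed
        self.reference_fpca = reference_fpca
        self.column_names = column_names

    @property
    def ntree(self) -> int:
        return len(self.trees)

    @property
    def n(self) -> int:
        return self.inbag.shape[1]

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "grid": self.grid.points.tolist(),
            "seed": int(self.seed),
            "inbag": self.inbag.astype(int).tolist(),
            "column_names": list(self.column_names),
            "reference_fpca": self.reference_fpca.to_dict(),
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunForForest":
        return cls(
            trees=[FunctionalTree.from_dict(td) for td in d["trees"]],
            inbag=np.asarray(d["inbag"], dtype=bool),
            params=FunForParams.from_dict(d["params"]),
            grid=Grid(np.asarray(d["grid"])),
            seed=d["seed"],
            reference_fpca=FpcaModel.from_dict(d["reference_fpca"]),
            column_names=list(d["column_names"]),
        )


def fit_forest(
    curves: CurveMatrix,
    predictors: PredictorTable,
    params: FunForParams | None = None,
    seed: int = 0,
) -> FunForForest:
    """Fit a FunFor ensemble.

    Per-tree generators are spawned from one master seed, so the fit is
    reproducible and independent of tree evaluation order.  A full-data FPCA
    fit is stored alongside the trees; its smoothed curves are the reference
    functions in the PVIM and the default denoised response for reporting.
    """
    if params is None:
        params = FunForParams()
    if curves.n != predictors.n:
        raise InvalidInputError("curves and predictors disagree on n")
    n = curves.n
    basis = PsplineBasis(curves.grid, params.n_basis)
    reference = fit_fpca(
        curves,
        option=params.l_option,
        tau1=params.tau1,
        tau2=params.tau2,
        L_override=params.l_fixed,
        basis=basis,
        keep_cov=False,
    )
    tree_seeds = np.random.SeedSequence(seed).spawn(params.ntree)
    trees: list[FunctionalTree] = []
    inbag = np.zeros((params.ntree, n), dtype=bool)
    for q in range(params.ntree):
        rng = np.random.default_rng(tree_seeds[q])
        if params.bootstrap:
            idx, mask = bootstrap_sample(n, rng)
        else:
            idx, mask = np.arange(n), np.ones(n, dtype=bool)
        inbag[q] = mask
        tree = fit_tree(curves.subset(idx), predictors.subset(idx), params, rng, basis)
        if params.prune:
            tree = prune_tree(tree, curves.subset(idx), predictors.subset(idx),
                              params.n_folds, rng)
        trees.append(tree)
        logger.debug("tree %d: %d splits", q, tree.n_splits)
    return FunForForest(
        trees, inbag, params, curves.grid, seed, reference, list(predictors.column_names)
    )


def predict_forest(
    forest: FunForForest,
    predictor_rows: np.ndarray,
    mode: str = ALL_TREES,
    row_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Ensemble curve predictions.

    ``all_trees`` averages every tree (the rule for new observations).
    ``inbag``/``oob`` apply to training rows only (``row_indices`` gives
    their positions in the training set): the average runs over trees whose
    bootstrap sample does (in-bag) or does not (out-of-bag) contain the row.
    A training row that is in-bag everywhere has no OOB prediction and
    raises ``NoOobCoverageError``.
    """
    X = np.atleast_2d(np.asarray(predictor_rows, dtype=float))
    m = X.shape[0]
    preds = np.stack([t.predict(X) for t in forest.trees])  # (ntree, m, K)
    if mode == ALL_TREES:
        return preds.mean(axis=0)
    if mode not in (INBAG, OOB):
        raise InvalidInputError(f"unknown prediction mode {mode!r}")
    if row_indices is None:
        raise InvalidInputError(f"mode={mode!r} requires training row_indices")
    row_indices = np.asarray(row_indices, dtype=int)
    if row_indices.size != m:
        raise InvalidInputError("row_indices must match the number of rows")
    qual = forest.inbag[:, row_indices]  # (ntree, m)
    if mode == OOB:
        qual = ~qual
    counts = qual.sum(axis=0)
    if np.any(counts == 0):
        bad = row_indices[counts == 0].tolist()
        raise NoOobCoverageError(f"rows {bad} have no qualifying tree for mode {mode!r}")
    out = np.einsum("qm,qmk->mk", qual.astype(float), preds) / counts[:, None]
    return out


def oob_prediction(forest: FunForForest, predictors: PredictorTable) -> np.ndarray:
    """Out-of-bag ensemble prediction for every training row."""
    return predict_forest(
        forest, predictors.values, mode=OOB, row_indices=np.arange(predictors.n)
    )


def pvim(
    forest: FunForForest,
    curves: CurveMatrix,
    predictors: PredictorTable,
    seed: int = 0,
) -> PvimResult:
    """Permutation variable importance for every predictor.

    A fresh permutation stream is spawned per (tree, predictor) from
    ``seed``, so scores are reproducible and independent of evaluation
    order.  Permutations act within each tree's out-of-bag set only.  Trees
    with an empty out-of-bag set are skipped (with a warning) and the
    averaging divisor reduced accordingly.
    """
    n, p = predictors.n, predictors.p
    if forest.n != n:
        raise InvalidInputError("forest was not fitted on these data")
    X = predictors.values
    w = forest.grid.trap_weights
    ref = forest.reference_fpca.smoothed_curves
    master = np.random.SeedSequence(seed)
    tree_streams = master.spawn(forest.ntree)
    contrib = np.zeros(p)
    n_perm = np.zeros(p, dtype=int)
    n_used = 0
    for q, tree in enumerate(forest.trees):
        oob_rows = np.nonzero(~forest.inbag[q])[0]
        if oob_rows.size == 0:
            warnings.warn(f"tree {q} has an empty out-of-bag set; skipped in PVIM")
            continue
        n_used += 1
        pred_streams = tree_streams[q].spawn(p)
        Xb = X[oob_rows]
        base_pred = tree.predict(Xb)
        err0 = ((ref[oob_rows] - base_pred) ** 2) @ w
        for j in tree.used_predictors():
            rng = np.random.default_rng(pred_streams[j])
            Xp = Xb.copy()
            Xp[:, j] = Xb[rng.permutation(oob_rows.size), j]
            errp = ((ref[oob_rows] - tree.predict(Xp)) ** 2) @ w
            contrib[j] += float(np.mean(errp - err0))
            n_perm[j] += 1
    if n_used == 0:
        raise InvalidInputError("no tree has out-of-bag rows; PVIM undefined")
    scores = contrib / n_used
    return PvimResult(scores, rank_scores(scores), n_perm, list(forest.column_names))
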