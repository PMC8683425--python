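"""Assessment criteria and multi-replication study driver.

Three criteria summarize a variable-selection/prediction study:

* M, the minimum selection size: the smallest prefix of the importance
  ranking containing every true predictor (per replication; averaged and
  quantiled across replications).
* Rk, a true predictor's importance rank averaged across replications.
* MAE, the mean absolute error between the observed curves and the forest's
  out-of-bag predictions (out-of-bag is the standard honest generalization
  proxy for a bagged ensemble).

Cross-validated prediction ISE is provided for tuning-parameter studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CurveMatrix, Grid, PredictorTable
from .exceptions import InvalidInputError
from .forest import fit_forest, oob_prediction, predict_forest, pvim
from .params import FunForParams
from .simulate import generate

M_QUANTILES = (5, 25, 50, 75, 95)


def ise(curve_a: np.ndarray, curve_b: np.ndarray, grid: Grid) -> float:
    """Integrated squared error int (a - b)^2 dt by trapezoid quadrature."""
    d = np.asarray(curve_a, dtype=float) - np.asarray(curve_b, dtype=float)
    return float((d**2) @ grid.trap_weights)


def mae(
    observed: CurveMatrix | np.ndarray,
    predicted: np.ndarray,
    row_subset: np.ndarray | None = None,
) -> float:
    """Mean absolute error between observed and predicted curves."""
    obs = observed.values if isinstance(observed, CurveMatrix) else np.asarray(observed)
    pred = np.asarray(predicted)
    if row_subset is not None:
        obs = obs[np.asarray(row_subset)]
    if obs.shape != pred.shape:
        raise InvalidInputError("observed and predicted shapes differ")
    return float(np.mean(np.abs(obs - pred)))


def min_selection_size(ranking: np.ndarray, true_set) -> int:
    """Largest 1-based rank position among the true predictors."""
    true_set = set(int(j) for j in true_set)
    if not true_set:
        raise InvalidInputError("minimum selection size is undefined for an empty true set")
    ranking = np.asarray(ranking)
    positions = []
    for j in true_set:
        hit = np.nonzero(ranking == j)[0]
        if hit.size == 0:
            raise InvalidInputError(f"true predictor {j} missing from ranking")
        positions.append(int(hit[0]) + 1)
    return max(positions)


def cv_prediction_ise(
    curves: CurveMatrix,
    predictors: PredictorTable,
    params: FunForParams | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean held-out prediction ISE under a random n_folds split.

    Each fold's forest is fitted on the remaining rows; held-out rows are
    predicted with the all-trees rule and scored by ISE against their
    observed curves.
    """
    if params is None:
        params = FunForParams()
    n = curves.n
    if n < n_folds:
        raise InvalidInputError("need at least n_folds observations")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    fit_seeds = rng.integers(0, 2**31 - 1, size=n_folds)
    total, count = 0.0, 0
    w = curves.grid.trap_weights
    for f, fold in enumerate(folds):
        if fold.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), fold)
        if train.size < 2 * params.min_node_size:
            raise InvalidInputError("training fold too small to fit a forest")
        forest = fit_forest(
            curves.subset(train), predictors.subset(train), params, int(fit_seeds[f])
        )
        pred = predict_forest(forest, predictors.values[fold])
        total += float(np.sum(((curves.values[fold] - pred) ** 2) @ w))
        count += fold.size
    return total / count


@dataclass
class ReplicationReport:
    """Per-replication records and their aggregates for one design."""

    design: int
    n_replications: int
    seed: int
    params: FunForParams
    records: list[dict] = field(default_factory=list)
    # aggregates
    mean_M: float | None = None
    M_quantiles: dict | None = None
    Rk: dict | None = None
    mean_mae: float | None = None
    mean_pvim: np.ndarray | None = None
    column_names: list[str] | None = None

    def aggregate(self) -> "ReplicationReport":
        """(Re)compute aggregates from the per-replication records."""
        maes = [r["mae"] for r in self.records]
        self.mean_mae = float(np.mean(maes)) if maes else None
        pv = np.stack([r["pvim_scores"] for r in self.records])
        self.mean_pvim = pv.mean(axis=0)
        if self.records and self.records[0].get("M") is not None:
            Ms = np.array([r["M"] for r in self.records], dtype=float)
            self.mean_M = float(Ms.mean())
            # type-7 (linear interpolation) quantiles
            self.M_quantiles = {
                q: float(np.quantile(Ms, q / 100.0, method="linear"))
                for q in M_QUANTILES
            }
            key_sets = [tuple(sorted(r["ranks"])) for r in self.records]
            if len(set(key_sets)) == 1:
                self.Rk = {
                    j: float(np.mean([r["ranks"][j] for r in self.records]))
                    for j in key_sets[0]
                }
            else:
                # the true set varies per replication (e.g. a randomly chosen
                # causal marker): average ranks positionally
                width = len(key_sets[0])
                self.Rk = {
                    f"true_{i + 1}": float(
                        np.mean(
                            [r["ranks"][sorted(r["ranks"])[i]] for r in self.records]
                        )
                    )
                    for i in range(width)
                }
        else:
            self.mean_M, self.M_quantiles, self.Rk = None, None, None
        return self

    def summary(self) -> str:
        """Human-readable table in the style of a simulation-results report."""
        lines = [
            f"Replication study: design {self.design}, "
            f"{self.n_replications} replications, ntree={self.params.ntree}",
        ]
        if self.mean_M is not None:
            qs = "  ".join(f"{q}%={v:.2f}" for q, v in self.M_quantiles.items())
            lines.append(f"mean M = {self.mean_M:.2f}   quantiles: {qs}")
            for j, rk in self.Rk.items():
                if isinstance(j, str):
                    name = j
                else:
                    name = self.column_names[j] if self.column_names else f"X{j + 1}"
                lines.append(f"Rk[{name}] = {rk:.2f}")
        if self.mean_mae is not None:
            lines.append(f"mean MAE = {self.mean_mae:.3f}")
        if self.mean_pvim is not None and self.mean_M is None:
            lines.append(
                "null design: mean PVIM range "
                f"[{self.mean_pvim.min():.5f}, {self.mean_pvim.max():.5f}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "n_replications": self.n_replications,
            "seed": self.seed,
            "params": self.params.to_dict(),
            "records": [
                {
                    "M": r.get("M"),
                    "ranks": {str(k): v for k, v in r.get("ranks", {}).items()},
                    "mae": r["mae"],
                    "pvim_scores": np.asarray(r["pvim_scores"]).tolist(),
                }
                for r in self.records
            ],
            "mean_M": self.mean_M,
            "M_quantiles": (
                None
                if self.M_quantiles is None
                else {str(k): v for k, v in self.M_quantiles.items()}
            ),
            "Rk": None if self.Rk is None else {str(k): v for k, v in self.Rk.items()},
            "mean_mae": self.mean_mae,
            "mean_pvim": None if self.mean_pvim is None else self.mean_pvim.tolist(),
            "column_names": self.column_names,
        }


def run_replication_study(
    design: int,
    n_replications: int,
    params: FunForParams | None = None,
    seed: int = 0,
    sim_overrides: dict | None = None,
) -> ReplicationReport:
    """Generate-fit-score loop over independent replications of one design.

    Per replication: draw a fresh dataset (child seed), fit a forest,
    compute PVIM, the minimum selection size M and true-predictor ranks
    (except for the null design), and the out-of-bag MAE.  Aggregates are
    the across-replication mean/quantiles per ``ReplicationReport``.
    """
    if design not in (1, 2, 3, 4, 5):
        raise InvalidInputError(f"unknown design id {design}")
    if params is None:
        params = FunForParams()
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(n_replications, 3))
    report = ReplicationReport(design, n_replications, seed, params)
    for r in range(n_replications):
        gen_rng = np.random.default_rng(int(rep_seeds[r, 0]))
        ds = generate(design, gen_rng, **(sim_overrides or {}))
        forest = fit_forest(ds.curves, ds.predictors, params, int(rep_seeds[r, 1]))
        pv = pvim(forest, ds.curves, ds.predictors, int(rep_seeds[r, 2]))
        rec: dict = {"pvim_scores": pv.scores}
        if ds.true_predictor_indices:
            rec["M"] = min_selection_size(pv.ranking, ds.true_predictor_indices)
            rec["ranks"] = {
                j: pv.rank_of(j) for j in sorted(ds.true_predictor_indices)
            }
        else:
            rec["M"], rec["ranks"] = None, {}
        rec["mae"] = mae(ds.curves, oob_prediction(forest, ds.predictors))
        report.records.append(rec)
        report.column_names = list(ds.predictors.column_names)
    return report.aggregate()
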