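"""Model/Results facade over the FunFor ensemble.

``FunFor`` is constructed from data (curve matrix + predictor table) plus
hyperparameters; ``fit(seed)`` returns a ``FunForResults`` carrying the
fitted forest, predictions, importance scores and a ``summary()`` table —
the familiar model/results split of statistical modelling packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CurveMatrix, Grid, PredictorTable, rescale_grid
from .exceptions import InvalidInputError
from .forest import ALL_TREES, FunForForest, oob_prediction, predict_forest, pvim
from .metrics import mae as _mae
from .params import FunForParams


class FunFor:
    """Random-forest model for a functional (curve) response.

    Parameters
    ----------
    curves : CurveMatrix or array (n, K)
        Discretely observed response curves on a shared dense grid.  A raw
        array is placed on the uniform grid over [0, 1].
    predictors : PredictorTable or DataFrame (n, p)
        Scalar predictors; DataFrame columns get genotype-style type
        inference (values in {0, 1, 2} -> categorical).
    **param_overrides
        Fields of :class:`FunForParams` (ntree, mtry_fraction, max_depth,
        l_option, l_fixed, prune, ...).
    """

    def __init__(self, curves, predictors, **param_overrides):
        if not isinstance(curves, CurveMatrix):
            arr = np.atleast_2d(np.asarray(curves, dtype=float))
            curves = CurveMatrix(arr, Grid.uniform(arr.shape[1]))
        if isinstance(predictors, pd.DataFrame):
            predictors = PredictorTable.from_dataframe(predictors)
        elif not isinstance(predictors, PredictorTable):
            predictors = PredictorTable(np.asarray(predictors, dtype=float))
        if curves.n != predictors.n:
            raise InvalidInputError("curves and predictors disagree on n")
        self.curves = curves
        self.predictors = predictors
        self.params = FunForParams(**param_overrides)

    @classmethod
    def from_dataframe(
        cls,
        curves_df: pd.DataFrame,
        predictors_df: pd.DataFrame,
        grid_points=None,
        type_overrides=None,
        **param_overrides,
    ) -> "FunFor":
        """Build from DataFrames; ``grid_points`` (raw locations) are rescaled."""
        arr = curves_df.to_numpy(dtype=float)
        grid = rescale_grid(grid_points) if grid_points is not None else Grid.uniform(
            arr.shape[1]
        )
        return cls(
            CurveMatrix(arr, grid),
            PredictorTable.from_dataframe(predictors_df, type_overrides),
            **param_overrides,
        )

    def fit(self, seed: int) -> "FunForResults":
        from .forest import fit_forest

        forest = fit_forest(self.curves, self.predictors, self.params, seed)
        return FunForResults(self, forest)


class FunForResults:
    """Fitted-forest results: predictions, importance, diagnostics."""

    def __init__(self, model: FunFor, forest: FunForForest):
        self.model = model
        self.forest = forest
        self._pvim_cache = None

    @property
    def params(self) -> FunForParams:
        return self.forest.params

    @property
    def smoothed_curves(self) -> np.ndarray:
        """Full-data FPCA denoised curves (the reference functions)."""
        return self.forest.reference_fpca.smoothed_curves

    def predict(self, predictor_rows=None, mode: str = ALL_TREES) -> np.ndarray:
        """Curve predictions; defaults to the training rows (in-bag rule)."""
        if predictor_rows is None:
            return predict_forest(
                self.forest,
                self.model.predictors.values,
                mode="inbag" if mode == ALL_TREES else mode,
                row_indices=np.arange(self.model.predictors.n),
            )
        rows = (
            predictor_rows.to_numpy(dtype=float)
            if isinstance(predictor_rows, pd.DataFrame)
            else np.asarray(predictor_rows, dtype=float)
        )
        return predict_forest(self.forest, rows, mode=ALL_TREES)

    def oob_predict(self) -> np.ndarray:
        return oob_prediction(self.forest, self.model.predictors)

    def oob_mae(self) -> float:
        return _mae(self.model.curves, self.oob_predict())

    def importance(self, seed: int | None = None):
        """Permutation variable importance (cached for seed = fit seed)."""
        if seed is None:
            if self._pvim_cache is None:
                self._pvim_cache = pvim(
                    self.forest, self.model.curves, self.model.predictors,
                    self.forest.seed,
                )
            return self._pvim_cache
        return pvim(self.forest, self.model.curves, self.model.predictors, seed)

    def summary(self, top: int = 10) -> str:
        pv = self.importance()
        lines = [
            "FunFor: random forest for a functional response",
            "=" * 48,
            f"n obs: {self.model.curves.n:>6}    grid points: {self.model.curves.K}",
            f"predictors: {self.model.predictors.p}    trees: {self.forest.ntree}",
            f"mtry: {self.params.resolve_mtry(self.model.predictors.p)}"
            f"    retained PCs (root): {self.forest.reference_fpca.L}",
            f"out-of-bag MAE: {self.oob_mae():.4f}",
            "-" * 48,
            f"top {min(top, pv.scores.size)} predictors by permutation importance:",
        ]
        for j in pv.ranking[:top]:
            lines.append(f"  {pv.column_names[j]:>12}  {pv.scores[j]: .5f}")
        return "\n".join(lines)
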