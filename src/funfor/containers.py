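"""Core data containers: evaluation grids, curve matrices, predictor tables.

A curve response is recorded on a shared dense grid of K points.  All
integrals over the domain use the trapezoid rule on that grid, so the grid
carries its quadrature weights.  Predictors are scalar (continuous or
categorical); genotype tables coded 0/1/2 are treated as categorical by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidGridError, InvalidInputError

MAX_CATEGORICAL_LEVELS = 32
CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class Grid:
    """Ordered evaluation points on [0, 1] with trapezoid quadrature weights."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 4:
            raise InvalidGridError(f"grid needs >= 4 points, got {pts.size}")
        if not np.all(np.diff(pts) > 0):
            raise InvalidGridError("grid points must be strictly increasing")
        if abs(pts[0]) > 1e-12 or abs(pts[-1] - 1.0) > 1e-12:
            raise InvalidGridError("grid must start at 0 and end at 1; use rescale_grid")

    @property
    def K(self) -> int:
        return self.points.size

    @property
    def trap_weights(self) -> np.ndarray:
        """Trapezoid quadrature weights w with sum(w) = 1 (domain length)."""
        d = np.diff(self.points)
        w = np.zeros(self.K)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return w

    def inner(self, a: np.ndarray, b: np.ndarray) -> float:
        """L2([0,1]) inner product of two curves via trapezoid quadrature."""
        return float(np.sum(self.trap_weights * np.asarray(a) * np.asarray(b)))

    @classmethod
    def uniform(cls, K: int) -> "Grid":
        return cls(np.linspace(0.0, 1.0, K))


def rescale_grid(raw_points: Sequence[float]) -> Grid:
    """Affinely map ordered raw locations onto [0, 1].

    The number of points is preserved; a grid already on [0, 1] is returned
    unchanged (up to floating identity).
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 1 or pts.size < 4:
        raise InvalidGridError(f"grid needs >= 4 points, got {pts.size}")
    if not np.all(np.diff(pts) > 0):
        raise InvalidGridError("grid points must be strictly increasing (no duplicates)")
    span = pts[-1] - pts[0]
    return Grid((pts - pts[0]) / span)


@dataclass(frozen=True)
class CurveMatrix:
    """n discretely observed curves sharing one grid: values[i, k] = Y_ik."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[None, :]
        object.__setattr__(self, "values", v)
        if v.shape[1] != self.grid.K:
            raise InvalidInputError(
                f"curve matrix has {v.shape[1]} columns but grid has {self.grid.K} points"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("curve matrix contains missing/non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.grid.K

    def subset(self, rows) -> "CurveMatrix":
        return CurveMatrix(self.values[np.asarray(rows)], self.grid)


@dataclass
class PredictorTable:
    """n x p scalar predictors with per-column continuous/categorical typing.

    Values are stored as a float matrix; categorical columns hold level codes
    (e.g. genotypes 0/1/2).  Categorical columns are capped at
    ``MAX_CATEGORICAL_LEVELS`` distinct levels so binary-partition scans stay
    exhaustive.
    """

    values: np.ndarray
    column_names: list[str] = field(default=None)
    column_types: list[str] = field(default=None)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidInputError("predictor table must be 2-dimensional")
        self.values = v
        p = v.shape[1]
        if self.column_names is None:
            self.column_names = [f"X{j + 1}" for j in range(p)]
        if self.column_types is None:
            self.column_types = [CONTINUOUS] * p
        self.column_names = list(self.column_names)
        self.column_types = list(self.column_types)
        if len(self.column_names) != p or len(self.column_types) != p:
            raise InvalidInputError("column names/types length must match p")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("predictor table contains missing values")
        for j, t in enumerate(self.column_types):
            if t not in (CONTINUOUS, CATEGORICAL):
                raise InvalidInputError(f"unknown column type {t!r}")
            if t == CATEGORICAL:
                nlev = np.unique(v[:, j]).size
                if nlev > MAX_CATEGORICAL_LEVELS:
                    raise InvalidInputError(
                        f"categorical column {self.column_names[j]!r} has {nlev} levels "
                        f"(max {MAX_CATEGORICAL_LEVELS})"
                    )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, rows) -> "PredictorTable":
        return PredictorTable(
            self.values[np.asarray(rows)], list(self.column_names), list(self.column_types)
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, type_overrides: Mapping[str, str] | None = None
    ) -> "PredictorTable":
        """Build a table from a DataFrame with genotype-style type inference.

        Columns whose distinct values all lie in {0, 1, 2} (and number at most
        ten) default to categorical — the genotype convention; every other
        numeric column is continuous.  ``type_overrides`` (name -> type) wins.
        """
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise InvalidInputError(f"missing values in predictor columns {bad}")
        overrides = dict(type_overrides or {})
        names = [str(c) for c in df.columns]
        types = []
        for name in names:
            col = pd.to_numeric(df[name], errors="raise").to_numpy(dtype=float)
            uniq = np.unique(col)
            if name in overrides:
                types.append(overrides[name])
            elif uniq.size <= 10 and np.all(np.isin(uniq, [0.0, 1.0, 2.0])):
                types.append(CATEGORICAL)
            else:
                types.append(CONTINUOUS)
        return cls(df.to_numpy(dtype=float), names, types)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)
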