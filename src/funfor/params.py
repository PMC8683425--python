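"""Hyperparameters shared by trees and forests."""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

from .exceptions import InvalidInputError


@dataclass
class FunForParams:
    """Tuning parameters for functional trees and forests.

    ``mtry`` (explicit count) wins over ``mtry_fraction`` (default 0.4, i.e.
    40% of the predictors are candidate split variables at every node).
    ``l_option`` is ``fixed_dual_rule`` (L chosen once at the root by the
    dual-threshold rule and held fixed) or ``adaptive`` (L re-selected at
    each node refit from the cumulative-proportion rule alone); ``l_fixed``
    pins L to an explicit value instead.  ``refit_per_node`` re-runs FPCA
    inside each realized child node (size permitting); the much costlier
    ``refit_per_candidate`` re-runs it for every candidate split.
    """

    ntree: int = 100
    mtry: int | None = None
    mtry_fraction: float = 0.4
    l_option: str = "fixed_dual_rule"
    tau1: float = 0.90
    tau2: float = 0.01
    l_fixed: int | None = None
    max_depth: int = 10
    min_node_size: int = 5
    n_split_points: int = 10
    refit_per_node: bool = True
    refit_per_candidate: bool = False
    prune: bool = False
    n_folds: int = 5
    min_fpca_n: int = 5
    n_basis: int | None = None
    bootstrap: bool = True

    def __post_init__(self):
        if not (0 < self.mtry_fraction <= 1):
            raise InvalidInputError("mtry_fraction must lie in (0, 1]")
        if not (0 < self.tau1 < 1):
            raise InvalidInputError("tau1 must lie in (0, 1)")
        if self.min_node_size < 1 or self.max_depth < 0 or self.ntree < 1:
            raise InvalidInputError("invalid tree/forest size parameters")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            m = self.mtry
            if m > p:
                warnings.warn(f"mtry={m} exceeds p={p}; clipped to {p}")
                m = p
            return max(1, m)
        return max(1, min(p, math.ceil(self.mtry_fraction * p)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FunForParams":
        return cls(**d)
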