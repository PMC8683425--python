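"""Functional principal component analysis on a dense regular grid.

Each observed curve is modelled as a smooth random function plus independent
measurement noise, Y_ik = f_i(t_k) + eps_ik.  The random functions admit the
Karhunen-Loeve expansion f_i(t) = mu(t) + sum_l zeta_il v_l(t), where the
v_l are the orthonormal eigenfunctions of the auto-covariance operator and
the scores zeta_il are uncorrelated with variances lambda_l.  We estimate

* mu by a GCV-tuned univariate P-spline fit to the pointwise sample mean,
* G(s, t) by the tensor-product sandwich smoother applied to the sample
  covariance of the centered curves (one shared GCV penalty for rows and
  columns),
* eigenpairs by the trapezoid-quadrature discretization of the integral
  operator, and
* scores by quadrature inner products of the centered curves with the
  eigenfunctions.

Truncating at L components gives the denoised curves
f~_i(t) = mu^(t) + sum_{l<=L} zeta^_il v^_l(t) used throughout the tree and
forest machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from ._pspline import PsplineBasis
from .containers import CurveMatrix, Grid
from .exceptions import InsufficientDataError, InvalidInputError

FIXED_DUAL_RULE = "fixed_dual_rule"
ADAPTIVE = "adaptive"

#: cap on internally retained components: min(n - 1, K, MAX_COMPONENTS)
MAX_COMPONENTS = 50


@dataclass
class FpcaModel:
    """Fitted FPCA decomposition of a curve sample.

    ``smoothed_curves[i] == mean_curve + scores[i, :L] @ eigenfunctions[:L]``
    by construction.  ``eigenvalues``/``eigenfunctions``/``scores`` may hold
    more than L components (up to the internal cap) so L can be revisited
    without refitting.
    """

    grid: Grid
    mean_curve: np.ndarray
    eigenvalues: np.ndarray
    eigenfunctions: np.ndarray
    scores: np.ndarray
    L: int
    smoothed_curves: np.ndarray
    variance_explained: np.ndarray
    smoothed_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.points.tolist(),
            "mean_curve": self.mean_curve.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "scores": self.scores.tolist(),
            "L": int(self.L),
            "variance_explained": self.variance_explained.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FpcaModel":
        grid = Grid(np.asarray(d["grid"]))
        mean = np.asarray(d["mean_curve"])
        scores = np.asarray(d["scores"])
        funcs = np.asarray(d["eigenfunctions"])
        L = int(d["L"])
        smoothed = mean[None, :] + scores[:, :L] @ funcs[:L]
        return cls(
            grid=grid,
            mean_curve=mean,
            eigenvalues=np.asarray(d["eigenvalues"]),
            eigenfunctions=funcs,
            scores=scores,
            L=L,
            smoothed_curves=smoothed,
            variance_explained=np.asarray(d["variance_explained"]),
        )


def smooth_mean(
    curves: CurveMatrix, n_basis: int | None = None, penalty_order: int = 2
) -> np.ndarray:
    """P-spline fit (GCV-tuned) to the pointwise sample mean curve."""
    basis = PsplineBasis(curves.grid, n_basis, penalty_order=penalty_order)
    fit, _ = basis.smooth_gcv(curves.values.mean(axis=0))
    return fit


def smooth_covariance(
    curves: CurveMatrix, mean_curve: np.ndarray, n_basis: int | None = None
) -> np.ndarray:
    """Sandwich-smoothed K x K covariance of the centered curves.

    The sample covariance of ``Y - mean`` is smoothed as S G S' with a single
    GCV-chosen P-spline penalty applied to both coordinates; the result is
    symmetrized.  The measurement-error nugget on the diagonal is not
    subtracted (the smoother already attenuates the diagonal ridge).
    """
    if curves.n < 2:
        raise InsufficientDataError("covariance estimation needs n >= 2 curves")
    mean_curve = np.asarray(mean_curve, dtype=float)
    if mean_curve.shape != (curves.K,):
        raise InvalidInputError("mean_curve must live on the curve grid")
    basis = PsplineBasis(curves.grid, n_basis)
    Mt, _ = basis.cov_smooth_gcv(curves.values - mean_curve[None, :])
    return basis.cov_to_matrix(Mt)


def eigen_decompose(smoothed_cov: np.ndarray, grid: Grid, max_components: int):
    """Eigenpairs of the covariance operator, orthonormal in L2([0,1]).

    Solves the trapezoid-quadrature discretization: with weights W, the
    eigenproblem of W^{1/2} G W^{1/2} yields quadrature-orthonormal
    eigenfunctions v = W^{-1/2} u.  Negative eigenvalues are clipped to 0 and
    each eigenfunction's largest-magnitude entry is made positive.
    """
    G = np.asarray(smoothed_cov, dtype=float)
    if G.shape != (grid.K, grid.K):
        raise InvalidInputError("covariance matrix does not match the grid")
    if np.max(np.abs(G - G.T)) > 1e-8:
        raise InvalidInputError("covariance matrix is not symmetric within 1e-8")
    w = grid.trap_weights
    sw = np.sqrt(w)
    Gw = sw[:, None] * ((G + G.T) / 2.0) * sw[None, :]
    vals, vecs = eigh((Gw + Gw.T) / 2.0)
    order = np.argsort(vals)[::-1][:max_components]
    vals = np.clip(vals[order], 0.0, None)
    funcs = (vecs[:, order] / sw[:, None]).T
    for i in range(funcs.shape[0]):
        k = int(np.argmax(np.abs(funcs[i])))
        if funcs[i, k] < 0:
            funcs[i] = -funcs[i]
    return vals, funcs


def select_L(
    variance_explained: np.ndarray,
    option: str = FIXED_DUAL_RULE,
    tau1: float = 0.90,
    tau2: float = 0.01,
) -> int:
    """Number of components to retain from eigenvalue proportions.

    ``fixed_dual_rule`` keeps the smallest L whose cumulative proportion
    reaches ``tau1`` while every later component explains less than ``tau2``;
    if no L satisfies both, the cumulative criterion alone decides.
    ``adaptive`` uses the cumulative criterion only.  Always returns L >= 1.
    """
    props = np.asarray(variance_explained, dtype=float)
    if props.size == 0:
        raise InvalidInputError("empty variance_explained vector")
    if np.any(props < -1e-12) or props.sum() > 1 + 1e-8:
        raise InvalidInputError("variance proportions must be nonnegative, sum <= 1")
    cum = np.cumsum(props)
    meets_cum = np.nonzero(cum >= tau1 - 1e-12)[0]
    if meets_cum.size == 0:
        L_cum = props.size
    else:
        L_cum = int(meets_cum[0]) + 1
    if option == ADAPTIVE:
        return max(L_cum, 1)
    if option != FIXED_DUAL_RULE:
        raise InvalidInputError(f"unknown L-selection option {option!r}")
    # scan truncation levels that leave at least one later component to judge;
    # if no level satisfies both criteria, the cumulative criterion wins
    for L in range(L_cum, props.size):
        if np.all(props[L:] < tau2):
            return max(L, 1)
    return max(L_cum, 1)


def compute_scores(
    curves: CurveMatrix, mean_curve: np.ndarray, eigenfunctions: np.ndarray, grid: Grid
) -> np.ndarray:
    """Quadrature inner products of centered curves with each eigenfunction."""
    Xc = curves.values - np.asarray(mean_curve)[None, :]
    if eigenfunctions.shape[1] != grid.K:
        raise InvalidInputError("eigenfunctions do not match the grid")
    w = grid.trap_weights
    return (Xc * w[None, :]) @ eigenfunctions.T


def fit_fpca(
    curves: CurveMatrix,
    option: str = FIXED_DUAL_RULE,
    tau1: float = 0.90,
    tau2: float = 0.01,
    n_basis: int | None = None,
    L_override: int | None = None,
    basis: PsplineBasis | None = None,
    keep_cov: bool = True,
) -> FpcaModel:
    """Full FPCA fit: mean, covariance, eigenpairs, L, scores, smooth curves.

    ``L_override`` fixes the truncation level directly (clipped to the number
    of available components), bypassing the proportion rules.  ``basis`` lets
    callers reuse one precomputed P-spline basis across many fits on the same
    grid; ``keep_cov=False`` skips materializing the K x K smoothed
    covariance (used by per-node refits inside trees).
    """
    if curves.n < 2:
        raise InsufficientDataError("FPCA needs n >= 2 curves")
    grid = curves.grid
    if basis is None:
        basis = PsplineBasis(grid, n_basis)
    mean, _ = basis.smooth_gcv(curves.values.mean(axis=0))
    Xc = curves.values - mean[None, :]
    Mt, _ = basis.cov_smooth_gcv(Xc)
    max_comp = min(curves.n - 1, grid.K, MAX_COMPONENTS)
    vals, funcs = basis.eigh_basis(Mt, max_comp)
    total = vals.sum()
    props = vals / total if total > 0 else np.zeros_like(vals)
    if L_override is not None:
        L = int(min(max(L_override, 1), vals.size))
    else:
        L = min(select_L(props, option, tau1, tau2), vals.size)
    w = grid.trap_weights
    scores = (Xc * w[None, :]) @ funcs.T
    scores -= scores.mean(axis=0, keepdims=True)  # centered by construction
    smoothed = mean[None, :] + scores[:, :L] @ funcs[:L]
    return FpcaModel(
        grid=grid,
        mean_curve=mean,
        eigenvalues=vals,
        eigenfunctions=funcs,
        scores=scores,
        L=L,
        smoothed_curves=smoothed,
        variance_explained=props,
        smoothed_cov=basis.cov_to_matrix(Mt) if keep_cov else None,
    )
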