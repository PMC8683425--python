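"""Penalized B-spline (P-spline) smoothing in Demmler–Reinsch form.

The univariate smoother is S(lam) = B (B'B + lam D'D)^{-1} B' with a cubic
B-spline design matrix B and an order-2 difference penalty D.  Writing
B'B = C'C (Cholesky) and eigendecomposing C^{-T} D'D C^{-1} = U s U' gives
S(lam) = A diag(1/(1 + lam s)) A' with A = B C^{-1} U, where A'A = I.  All
smooths, GCV traces and the tensor-product (sandwich) covariance smoother
then reduce to cheap operations in the A-basis, which is what makes per-node
FPCA refits inside trees affordable.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cholesky, eigh, qr, solve_triangular

from .exceptions import NumericalError

#: GCV candidate penalties: 21 log-spaced values spanning [1e-6, 1e6].
GCV_LAMBDAS = np.logspace(-6.0, 6.0, 21)


def bspline_design(points: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Dense B-spline design matrix on ``points`` with equally spaced knots."""
    points = np.asarray(points, dtype=float)
    if n_basis <= degree:
        raise NumericalError(f"n_basis={n_basis} must exceed spline degree {degree}")
    lo, hi = points[0], points[-1]
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    return BSpline.design_matrix(points, knots, degree, extrapolate=False).toarray()


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """Order-d difference penalty matrix D'D on the spline coefficients."""
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


class PsplineBasis:
    """Precomputed Demmler–Reinsch machinery for one grid and basis size.

    Attributes
    ----------
    A : (K, nb) array with orthonormal columns spanning the spline space.
    s : (nb,) nonnegative shrinkage eigenvalues; smoother weights for a
        penalty ``lam`` are ``1 / (1 + lam * s)``.
    Qw, Rw : thin QR of ``sqrt(w)[:, None] * A`` where ``w`` are the grid's
        trapezoid weights — used to solve the weighted (L2) eigenproblem of a
        smoothed covariance without forming the K x K matrix.
    """

    def __init__(self, grid, n_basis: int | None = None, degree: int = 3, penalty_order: int = 2):
        self.grid = grid
        K = grid.K
        if n_basis is None:
            n_basis = min(35, K // 2)
        n_basis = max(n_basis, degree + 1 + 1)
        self.n_basis = n_basis
        self.degree = degree
        self.penalty_order = penalty_order
        B = bspline_design(grid.points, n_basis, degree)
        P = difference_penalty(n_basis, penalty_order)
        BtB = B.T @ B
        try:
            C = cholesky(BtB + 1e-10 * np.eye(n_basis), lower=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NumericalError(f"singular penalized system: {exc}") from exc
        Cinv = solve_triangular(C, np.eye(n_basis), lower=False)
        M = Cinv.T @ P @ Cinv
        s, U = eigh((M + M.T) / 2.0)
        self.s = np.clip(s, 0.0, None)
        self.A = B @ (Cinv @ U)
        w = grid.trap_weights
        self.Qw, self.Rw = qr(np.sqrt(w)[:, None] * self.A, mode="economic")
        self._sqrt_w = np.sqrt(w)

    # ----------------------------------------------------------- univariate
    def shrink_weights(self, lam: float) -> np.ndarray:
        return 1.0 / (1.0 + lam * self.s)

    def smooth(self, y: np.ndarray, lam: float) -> np.ndarray:
        """Apply S(lam) to one curve (or to rows of a matrix, last axis = K)."""
        coef = np.asarray(y) @ self.A
        return (coef * self.shrink_weights(lam)) @ self.A.T

    def smooth_gcv(self, y: np.ndarray, lambdas: np.ndarray = GCV_LAMBDAS):
        """Smooth one curve, choosing the penalty by generalized cross-validation.

        Returns (fitted curve, selected lambda).
        """
        y = np.asarray(y, dtype=float)
        K = y.size
        coef = self.A.T @ y  # projection onto the orthonormal basis
        ss_off = float(y @ y - coef @ coef)  # residual outside the spline space
        best = (np.inf, None, None)
        for lam in lambdas:
            tau = self.shrink_weights(lam)
            rss = ss_off + float(np.sum(((1.0 - tau) * coef) ** 2))
            tr = float(np.sum(tau))
            denom = (1.0 - tr / K) ** 2
            if denom <= 0:
                continue
            gcv = rss / (K * denom)
            if gcv < best[0]:
                best = (gcv, lam, tau)
        if best[1] is None:
            raise NumericalError("GCV failed: effective df >= K for all penalties")
        _, lam, tau = best
        return (tau * coef) @ self.A.T, lam

    # ----------------------------------------------------------- covariance
    def cov_smooth_gcv(self, centered: np.ndarray, lambdas: np.ndarray = GCV_LAMBDAS):
        """Sandwich-smooth the sample covariance of centered curves.

        ``centered`` is (m, K) with the mean estimate already removed.  The
        sample covariance G = X'X / (m-1) is smoothed as S G S' with one
        common GCV-selected penalty for rows and columns (tensor-product
        P-spline smoother).  Returns ``(Mtilde, lam)`` where the smoothed
        covariance equals ``A @ Mtilde @ A.T`` (never formed here).
        """
        X = np.asarray(centered, dtype=float)
        m, K = X.shape
        if m < 2:
            raise NumericalError("covariance smoothing needs at least 2 curves")
        P = X @ self.A  # (m, nb)
        M = (P.T @ P) / (m - 1)
        gram = X @ X.T
        norm_G2 = float(np.sum(gram**2)) / (m - 1) ** 2  # ||G||_F^2
        M2 = M**2
        best = (np.inf, None, None)
        for lam in lambdas:
            tau = self.shrink_weights(lam)
            t1 = float(tau @ M2 @ tau)  # tr(G S G S)
            t2 = float((tau**2) @ M2 @ (tau**2))  # ||S G S'||_F^2
            rss = max(norm_G2 - 2.0 * t1 + t2, 0.0)
            tr = float(np.sum(tau))
            denom = (1.0 - (tr / K) ** 2) ** 2
            if denom <= 0:
                continue
            gcv = rss / (K * K * denom)
            if gcv < best[0]:
                best = (gcv, lam, tau)
        if best[1] is None:
            raise NumericalError("covariance GCV failed for all penalties")
        _, lam, tau = best
        Mt = tau[:, None] * M * tau[None, :]
        return (Mt + Mt.T) / 2.0, lam

    def cov_to_matrix(self, Mtilde: np.ndarray) -> np.ndarray:
        """Materialize the K x K smoothed covariance A Mtilde A' (symmetrized)."""
        G = self.A @ Mtilde @ self.A.T
        return (G + G.T) / 2.0

    def eigh_basis(self, Mtilde: np.ndarray, max_components: int):
        """Eigenpairs of the L2([0,1]) integral operator with kernel A Mtilde A'.

        Solves the weighted problem through the precomputed QR of W^{1/2} A,
        so only an nb x nb symmetric eigenproblem is needed.  Returns
        eigenvalues (nonincreasing, negatives clipped to 0) and eigenfunctions
        (rows, orthonormal under trapezoid quadrature) with the
        largest-absolute-entry-positive sign convention.
        """
        S = self.Rw @ Mtilde @ self.Rw.T
        vals, vecs = eigh((S + S.T) / 2.0)
        order = np.argsort(vals)[::-1][:max_components]
        vals = vals[order]
        U = vecs[:, order]
        funcs = (self.Qw @ U).T / self._sqrt_w[None, :]
        vals = np.clip(vals, 0.0, None)
        # sign convention: entry of largest magnitude is positive
        for i in range(funcs.shape[0]):
            k = int(np.argmax(np.abs(funcs[i])))
            if funcs[i, k] < 0:
                funcs[i] = -funcs[i]
        return vals, funcs
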