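"""Synthetic curve-response designs used to study the method.

Five designs are provided:

1. A genotype design: p biallelic markers coded 0/1/2 (aa/Aa/AA) with
   random minor allele frequencies, one marker driving the response through
   three genotype-specific mean curves plus correlated Gaussian noise whose
   covariance is the empirical covariance of the three mean curves.  The
   default mean curves are three distinct smooth closed-contour radius
   functions (synthetic stand-ins for real leaf-shape curves, which are not
   publicly available).
2./3. Linear-plus-interaction designs: Gaussian predictors with AR(1)
   correlation (sigma = 1, rho = 0.6); response
   Y_ik = X_i2 b1(t_k) + X_i3 b2(t_k) + X_i2 X_i3 b3(t_k) + eps_ik with
   b1 = sin(20 pi t), b2 = cos(20 pi t), b3 = b1 + b2, evaluated at
   t_k = k/K.  Design 2 uses (n, p, K) = (100, 100, 500); design 3
   (200, 500, 100).
4. Interaction-only: Y_ik = X_i2 X_i3 b1(t_k)/3 + eps_ik at (100, 100, 100).
5. A null design: Y_ik = b1(t_k) + eps_ik, independent of all predictors.

The error rows follow an AR(1) covariance with rho = 0.01 and heteroscedastic
scales sigma_k = |(5 cos(k) + z_k)/10| (z_k standard normal, raw index
k = 1..K); the absolute value makes the printed scale formula a valid
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CATEGORICAL, CONTINUOUS, CurveMatrix, Grid, PredictorTable
from .exceptions import InvalidInputError

SIM_DEFAULTS = {
    1: dict(n=100, p=100, K=360),
    2: dict(n=100, p=100, K=500),
    3: dict(n=200, p=500, K=100),
    4: dict(n=100, p=100, K=100),
    5: dict(n=100, p=100, K=100),
}


@dataclass(frozen=True)
class Ar1Spec:
    """First-order autoregressive covariance: Sigma_ab = s_a s_b rho^|a-b|."""

    dimension: int
    sigma: float | np.ndarray
    rho: float

    def __post_init__(self):
        if not (-1.0 < self.rho < 1.0):
            raise InvalidInputError("AR(1) correlation must lie in (-1, 1)")

    def sample(self, n_rows: int, rng: np.random.Generator) -> np.ndarray:
        """Exact draws via the AR(1) recursion, then per-coordinate scaling."""
        K = self.dimension
        z = rng.standard_normal((n_rows, K))
        e = np.empty_like(z)
        e[:, 0] = z[:, 0]
        c = np.sqrt(1.0 - self.rho**2)
        for k in range(1, K):
            e[:, k] = self.rho * e[:, k - 1] + c * z[:, k]
        return e * np.broadcast_to(np.asarray(self.sigma, dtype=float), (K,))[None, :]

    def matrix(self) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.sigma, dtype=float), (self.dimension,))
        idx = np.arange(self.dimension)
        return np.outer(s, s) * self.rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SimulatedDataset:
    """A generated (curves, predictors, truth) triple."""

    curves: CurveMatrix
    predictors: PredictorTable
    true_predictor_indices: frozenset  # 0-based column indices; empty for the null
    truth_meta: dict = field(default_factory=dict)

    @property
    def noiseless(self) -> np.ndarray:
        return self.truth_meta["noiseless_curves"]


def beta_functions(t):
    """The three coefficient curves b1 = sin(20 pi t), b2 = cos(20 pi t), b3 = b1 + b2.

    ``t`` may be a Grid or a raw array of evaluation points in [0, 1].
    """
    pts = t.points if isinstance(t, Grid) else np.asarray(t, dtype=float)
    b1 = np.sin(20 * np.pi * pts)
    b2 = np.cos(20 * np.pi * pts)
    return b1, b2, b1 + b2


def gen_genotype_matrix(
    n: int, p: int, rng: np.random.Generator, maf: float | None = None
) -> PredictorTable:
    """p biallelic markers: per marker q ~ U(0.1, 0.5), genotype ~ Binomial(2, q).

    Codes count copies of the allele with frequency q (0 = aa, 1 = Aa,
    2 = AA).  ``maf`` forces a common allele frequency (testing hook).
    """
    qs = np.full(p, maf) if maf is not None else rng.uniform(0.1, 0.5, size=p)
    geno = rng.binomial(2, qs[None, :], size=(n, p)).astype(float)
    return PredictorTable(geno, [f"X{j + 1}" for j in range(p)], [CATEGORICAL] * p)


def default_leaf_curves(K: int) -> np.ndarray:
    """Three smooth closed-contour radius functions r(theta) = 1 + a sin(2 theta) + b cos(3 theta).

    Synthetic stand-ins for digitized leaf-outline radius curves; the three
    (a, b) pairs give visibly distinct but overlapping shapes.
    """
    theta = 2 * np.pi * np.arange(K) / K
    ab = [(0.10, 0.05), (0.25, 0.10), (0.05, 0.25)]
    return np.stack([1 + a * np.sin(2 * theta) + b * np.cos(3 * theta) for a, b in ab])


def _noise_sigma(K: int, rng: np.random.Generator) -> np.ndarray:
    """Heteroscedastic error scales |(5 cos(k) + z_k)/10|, raw index k = 1..K."""
    k = np.arange(1, K + 1)
    return np.abs((5.0 * np.cos(k) + rng.standard_normal(K)) / 10.0)


def _gauss_ar1_predictors(n: int, p: int, rng: np.random.Generator) -> PredictorTable:
    X = Ar1Spec(p, 1.0, 0.6).sample(n, rng)
    return PredictorTable(X, [f"X{j + 1}" for j in range(p)], [CONTINUOUS] * p)


def gen_sim1(
    rng: np.random.Generator,
    n: int = 100,
    p: int = 100,
    K: int = 360,
    mean_curves: np.ndarray | str = "default",
    noise_cov: np.ndarray | str = "default",
) -> SimulatedDataset:
    """Genotype design: one true marker selects among three mean curves.

    Y_i = mu_g(t) + eps_i with g determined by the true marker's genotype
    (AA -> mu_1, Aa -> mu_2, aa -> mu_3) and eps ~ N(0, Sigma), Sigma being
    the empirical covariance of the three mean curves (plus a small ridge
    keeping it positive definite).
    """
    predictors = gen_genotype_matrix(n, p, rng)
    true_col = int(rng.integers(p))
    mu = default_leaf_curves(K) if isinstance(mean_curves, str) else np.asarray(mean_curves)
    if mu.shape != (3, K):
        raise InvalidInputError(f"mean_curves must be 3 x {K}")
    for a in range(3):
        for b in range(a + 1, 3):
            if np.allclose(mu[a], mu[b]):
                raise InvalidInputError("mean curves must be pairwise distinct")
    geno = predictors.values[:, true_col].astype(int)
    mean_rows = mu[2 - geno]  # AA (2) -> mu_1, Aa (1) -> mu_2, aa (0) -> mu_3
    if isinstance(noise_cov, str):
        C = np.cov(mu, rowvar=False, ddof=1)  # rank <= 2 empirical covariance
        tau = 1e-4 * float(np.mean(np.diag(C)))
        # rank-aware sampling: eigen part + isotropic ridge
        vals, vecs = np.linalg.eigh(C)
        keep = vals > 1e-12
        root = vecs[:, keep] * np.sqrt(vals[keep])[None, :]
        noise = rng.standard_normal((n, int(keep.sum()))) @ root.T
        noise += np.sqrt(tau) * rng.standard_normal((n, K))
    elif np.isscalar(noise_cov) and noise_cov == 0:
        noise = np.zeros((n, K))
    else:
        Sigma = np.asarray(noise_cov, dtype=float)
        if np.all(Sigma == 0):
            noise = np.zeros((n, K))
        else:
            noise = rng.multivariate_normal(np.zeros(K), Sigma, size=n, method="eigh")
    Y = mean_rows + noise
    grid = Grid(np.linspace(0, 1, K))
    return SimulatedDataset(
        CurveMatrix(Y, grid),
        predictors,
        frozenset({true_col}),
        {
            "design": 1,
            "n": n,
            "p": p,
            "K": K,
            "true_column": true_col,
            "mean_curves": mu,
            "noiseless_curves": mean_rows,
        },
    )


def gen_sim234(
    design: int,
    rng: np.random.Generator,
    n: int | None = None,
    p: int | None = None,
    K: int | None = None,
) -> SimulatedDataset:
    """Continuous-predictor designs 2-4 (see module docstring).

    Dimensions default to the design's standard values; overrides support
    scaled-down studies.  The true predictors are X2 and X3 (0-based
    indices 1 and 2).
    """
    if design not in (2, 3, 4):
        raise InvalidInputError(f"design must be 2, 3 or 4, got {design}")
    defaults = SIM_DEFAULTS[design]
    n = n or defaults["n"]
    p = p or defaults["p"]
    K = K or defaults["K"]
    predictors = _gauss_ar1_predictors(n, p, rng)
    t = np.arange(1, K + 1) / K
    b1, b2, b3 = beta_functions(t)
    x2 = predictors.values[:, 1][:, None]
    x3 = predictors.values[:, 2][:, None]
    if design == 4:
        signal = x2 * x3 * b1[None, :] / 3.0
    else:
        signal = x2 * b1[None, :] + x3 * b2[None, :] + x2 * x3 * b3[None, :]
    sigma_k = _noise_sigma(K, rng)
    eps = Ar1Spec(K, sigma_k, 0.01).sample(n, rng)
    grid = Grid(np.linspace(0, 1, K))
    return SimulatedDataset(
        CurveMatrix(signal + eps, grid),
        predictors,
        frozenset({1, 2}),
        {
            "design": design,
            "n": n,
            "p": p,
            "K": K,
            "t": t,
            "sigma_k": sigma_k,
            "noiseless_curves": signal,
        },
    )


def gen_sim5(
    rng: np.random.Generator, n: int = 100, p: int = 100, K: int = 100
) -> SimulatedDataset:
    """Null design: Y_ik = b1(t_k) + eps_ik, independent of every predictor."""
    predictors = _gauss_ar1_predictors(n, p, rng)
    t = np.arange(1, K + 1) / K
    b1, _, _ = beta_functions(t)
    sigma_k = _noise_sigma(K, rng)
    eps = Ar1Spec(K, sigma_k, 0.01).sample(n, rng)
    signal = np.tile(b1, (n, 1))
    grid = Grid(np.linspace(0, 1, K))
    return SimulatedDataset(
        CurveMatrix(signal + eps, grid),
        predictors,
        frozenset(),
        {
            "design": 5,
            "n": n,
            "p": p,
            "K": K,
            "t": t,
            "sigma_k": sigma_k,
            "noiseless_curves": signal,
        },
    )


def generate(design: int, rng: np.random.Generator, **overrides) -> SimulatedDataset:
    """Dispatch on design id 1-5."""
    if design == 1:
        return gen_sim1(rng, **overrides)
    if design in (2, 3, 4):
        return gen_sim234(design, rng, **overrides)
    if design == 5:
        return gen_sim5(rng, **overrides)
    raise InvalidInputError(f"unknown design id {design}")
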