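"""Unit and property tests for grids, smoothing and FPCA."""

import numpy as np
import pytest
from scipy.linalg import eig

from funfor import (
    CurveMatrix,
    Grid,
    compute_scores,
    eigen_decompose,
    fit_fpca,
    rescale_grid,
    select_L,
    smooth_covariance,
    smooth_mean,
)
from funfor.exceptions import (
    InsufficientDataError,
    InvalidGridError,
    InvalidInputError,
)


class TestGrid:
    def test_rescale_affine(self):
        g = rescale_grid([1, 2, 3, 4, 5])
        np.testing.assert_allclose(g.points, [0, 0.25, 0.5, 0.75, 1])

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidGridError):
            rescale_grid([0, 1])

    def test_identity_on_unit_interval(self):
        pts = [0, 0.1, 0.9, 1.0]
        np.testing.assert_allclose(rescale_grid(pts).points, pts)

    def test_non_monotone_rejected(self):
        with pytest.raises(InvalidGridError):
            rescale_grid([0, 0.5, 0.5, 1])

    def test_trap_weights_integrate_constants(self):
        g = Grid.uniform(17)
        assert g.trap_weights.sum() == pytest.approx(1.0)


class TestSmoothMean:
    def test_constant_curves_reproduced(self):
        g = Grid.uniform(30)
        cm = CurveMatrix(np.full((5, 30), 3.7), g)
        np.testing.assert_allclose(smooth_mean(cm), 3.7, atol=1e-8)

    def test_recovers_sin_mean_under_noise(self):
        rng = np.random.default_rng(0)
        g = Grid.uniform(100)
        truth = np.sin(2 * np.pi * g.points)
        Y = truth[None, :] + 0.1 * rng.standard_normal((200, 100))
        assert np.max(np.abs(smooth_mean(CurveMatrix(Y, g)) - truth)) < 0.1

    def test_single_cubic_polynomial_reproduced(self):
        g = Grid.uniform(50)
        t = g.points
        poly = 2.0 - t + 3 * t**2 - 0.5 * t**3
        cm = CurveMatrix(poly[None, :], g)
        np.testing.assert_allclose(smooth_mean(cm), poly, atol=1e-6)


class TestSmoothCovariance:
    def test_identical_curves_give_zero(self):
        g = Grid.uniform(25)
        cm = CurveMatrix(np.tile(np.sin(2 * np.pi * g.points), (6, 1)), g)
        G = smooth_covariance(cm, cm.values.mean(axis=0))
        assert np.max(np.abs(G)) < 1e-10

    def test_rank_one_truth_dominates(self):
        rng = np.random.default_rng(1)
        g = Grid.uniform(50)
        f = np.sin(2 * np.pi * g.points)
        Y = rng.standard_normal((500, 1)) * f[None, :]
        G = smooth_covariance(CurveMatrix(Y, g), np.zeros(50))
        vals = np.linalg.eigvalsh(G)
        assert vals[-1] / np.abs(vals).sum() > 0.95

    def test_near_identity_on_smooth_data(self):
        rng = np.random.default_rng(2)
        g = Grid.uniform(60)
        t = g.points
        basis = np.stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), t - 0.5])
        Y = rng.standard_normal((300, 3)) @ basis
        cm = CurveMatrix(Y, g)
        mean = Y.mean(axis=0)
        sample = np.cov(Y - mean, rowvar=False, ddof=1)
        smoothed = smooth_covariance(cm, mean)
        rel = np.linalg.norm(smoothed - sample) / np.linalg.norm(sample)
        assert rel < 0.05

    def test_single_curve_rejected(self):
        g = Grid.uniform(10)
        with pytest.raises(InsufficientDataError):
            smooth_covariance(CurveMatrix(np.ones((1, 10)), g), np.ones(10))


class TestEigenDecompose:
    def test_constant_rank_one_kernel(self):
        g = Grid.uniform(40)
        c = 2.5
        G = c * np.ones((40, 40))
        vals, funcs = eigen_decompose(G, g, 3)
        assert vals[0] == pytest.approx(c, rel=1e-10)
        assert np.max(np.abs(funcs[0] - 1.0)) < 1e-8
        assert np.all(vals[1:] < 1e-10)

    def test_sin_kernel_closed_form(self):
        g = Grid.uniform(400)
        s = np.sin(2 * np.pi * g.points)
        G = 2.0 * np.outer(s, s)
        vals, funcs = eigen_decompose(G, g, 2)
        # 2 * integral of sin^2 over [0,1] = 1
        assert vals[0] == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(np.abs(funcs[0]), np.sqrt(2) * np.abs(s), atol=1e-6)

    def test_orthonormality_contract(self, noisy_sin_curves):
        model = fit_fpca(noisy_sin_curves)
        w = noisy_sin_curves.grid.trap_weights
        V = model.eigenfunctions[: max(model.L, 3)]
        gram = (V * w) @ V.T
        assert np.max(np.abs(gram - np.eye(V.shape[0]))) < 1e-6

    def test_asymmetric_input_rejected(self):
        g = Grid.uniform(10)
        G = np.eye(10)
        G[0, 1] = 0.5
        with pytest.raises(InvalidInputError):
            eigen_decompose(G, g, 2)

    def test_matches_independent_dense_quadrature_eigensolve(self):
        """Dual route: nonsymmetric eigensolve of G @ diag(w) on a small grid."""
        rng = np.random.default_rng(3)
        K = 25
        g = Grid.uniform(K)
        A = rng.standard_normal((K, 4))
        G = A @ A.T  # arbitrary PSD kernel
        vals, funcs = eigen_decompose(G, g, 4)
        w = g.trap_weights
        ev, evec = eig(G @ np.diag(w))
        order = np.argsort(ev.real)[::-1][:4]
        np.testing.assert_allclose(vals, ev.real[order], atol=1e-8)
        for i, idx in enumerate(order):
            v = evec[:, idx].real
            v = v / np.sqrt(np.sum(w * v * v))
            agreement = abs(np.sum(w * v * funcs[i]))
            assert agreement == pytest.approx(1.0, abs=1e-8)


class TestSelectL:
    @pytest.mark.parametrize(
        "props,option,expected",
        [
            ([0.95, 0.005, 0.005], "fixed_dual_rule", 1),
            ([0.5, 0.3, 0.15, 0.05], "adaptive", 3),
            ([1.0], "fixed_dual_rule", 1),
            # both criteria first hold at L = 2
            ([0.7, 0.25, 0.008, 0.008], "fixed_dual_rule", 2),
            # conflict case: no L satisfies both; cumulative criterion wins
            ([0.88, 0.03, 0.03, 0.03, 0.03], "fixed_dual_rule", 2),
        ],
    )
    def test_rule_examples(self, props, option, expected):
        assert select_L(np.array(props), option) == expected

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            select_L(np.array([]), "adaptive")


class TestScoresAndFit:
    def test_zero_scores_for_mean_curve(self, noisy_sin_curves):
        model = fit_fpca(noisy_sin_curves)
        cm = CurveMatrix(model.mean_curve[None, :], noisy_sin_curves.grid)
        s = compute_scores(cm, model.mean_curve, model.eigenfunctions, cm.grid)
        assert np.max(np.abs(s)) < 1e-8

    def test_score_of_shifted_eigenfunction(self, noisy_sin_curves):
        model = fit_fpca(noisy_sin_curves)
        curve = model.mean_curve + 3.0 * model.eigenfunctions[0]
        cm = CurveMatrix(curve[None, :], noisy_sin_curves.grid)
        s = compute_scores(cm, model.mean_curve, model.eigenfunctions[:3], cm.grid)[0]
        assert s[0] == pytest.approx(3.0, abs=1e-6)
        assert np.max(np.abs(s[1:])) < 1e-6

    def test_score_variance_estimates_eigenvalue(self):
        rng = np.random.default_rng(11)
        g = Grid.uniform(50)
        t = g.points
        v1 = np.sqrt(2) * np.sin(2 * np.pi * t)
        v2 = np.sqrt(2) * np.cos(2 * np.pi * t)
        lam = np.array([4.0, 1.0])
        scores = rng.standard_normal((2000, 2)) * np.sqrt(lam)
        Y = 1.0 + scores @ np.stack([v1, v2]) + 0.05 * rng.standard_normal((2000, 50))
        model = fit_fpca(CurveMatrix(Y, g), L_override=2)
        est = model.scores[:, :2].var(axis=0, ddof=1)
        np.testing.assert_allclose(est, lam, rtol=0.15)

    def test_exact_two_dim_subspace(self):
        rng = np.random.default_rng(4)
        g = Grid.uniform(50)
        t = g.points
        basis = np.stack(
            [np.sqrt(2) * np.sin(2 * np.pi * t), np.sqrt(2) * np.cos(2 * np.pi * t)]
        )
        coef = rng.standard_normal((100, 2)) * np.array([1.0, 0.8])
        Y = 1.0 + coef @ basis
        model = fit_fpca(CurveMatrix(Y, g), option="adaptive", tau1=0.9)
        assert model.L == 2
        err = np.linalg.norm(model.smoothed_curves - Y, axis=1) / np.linalg.norm(Y, axis=1)
        assert np.max(err) < 1e-3

    def test_two_curves_rank_one(self):
        g = Grid.uniform(20)
        t = g.points
        Y = np.stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
        model = fit_fpca(CurveMatrix(Y, g))
        assert model.L == 1
        recon = model.mean_curve[None, :] + np.outer(
            model.scores[:, 0], model.eigenfunctions[0]
        )
        np.testing.assert_allclose(model.smoothed_curves, recon)

    def test_null_design_mean_recovery(self):
        from funfor import gen_sim5

        ds = gen_sim5(np.random.default_rng(8), n=100, p=5, K=100)
        model = fit_fpca(ds.curves)
        b1 = np.sin(20 * np.pi * ds.truth_meta["t"])
        assert np.max(np.abs(model.mean_curve - b1)) < 0.15

    def test_scores_centered_and_variance_ordered(self, noisy_sin_curves):
        model = fit_fpca(noisy_sin_curves)
        assert np.max(np.abs(model.scores.mean(axis=0))) < 1e-8
        assert np.all(np.diff(model.variance_explained) <= 1e-12)

    def test_mean_smoother_contraction(self, noisy_sin_curves):
        """Re-smoothing an already-smoothed mean moves it less than pass one."""
        one = smooth_mean(noisy_sin_curves)
        g = noisy_sin_curves.grid
        two = smooth_mean(CurveMatrix(one[None, :], g))
        raw = noisy_sin_curves.values.mean(axis=0)
        assert np.linalg.norm(two - one) < np.linalg.norm(one - raw)
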