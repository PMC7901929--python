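"""Epsilon-SVR coupling quantification: tuning rules, dual solution, indices."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from rsacoupling import (
    KernelSpec,
    LaggedDesign,
    TuningParams,
    build_design,
    coupling_indices,
)
from rsacoupling.osp import build_embedding, project
from rsacoupling.svr_coupling import (
    dual_objective,
    fit,
    predict_in_sample,
    tune_c_epsilon,
    tune_sigma2,
)


def solve_dual_slsqp(K, y, c, eps):
    """Generic constrained-optimizer oracle for the SVR dual.

    Maximizes W(a, a*) = -1/2 (a-a*)'K(a-a*) - eps*sum(a+a*) + y'(a-a*)
    over the box [0, c]^2N with sum(a - a*) = 0, via scipy SLSQP on the
    stacked variables.  Independent of the package's solver path.
    """
    n = len(y)

    def neg_obj(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta + eps * z.sum() - y @ beta

    cons = {"type": "eq", "fun": lambda z: np.sum(z[:n] - z[n:])}
    res = minimize(
        neg_obj, x0=np.full(2 * n, c / 4), method="SLSQP",
        bounds=[(0.0, c)] * (2 * n), constraints=[cons],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    return -res.fun


class TestTuning:
    def test_iqr_rule(self):
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.349, 1.349, 1.349, 1.349])
        c, eps = tune_c_epsilon(y)
        assert c == pytest.approx(1.0)
        assert eps == pytest.approx(0.1)

    def test_homogeneity(self, rng):
        y = rng.standard_normal(100)
        c1, e1 = tune_c_epsilon(y)
        c2, e2 = tune_c_epsilon(4.5 * y)
        assert c2 == pytest.approx(4.5 * c1)
        assert e2 == pytest.approx(4.5 * e1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            tune_c_epsilon(np.full(20, 2.0))

    def test_sigma2_deterministic_and_interior(self, rng):
        X = rng.standard_normal((100, 4))
        s2a = tune_sigma2(X)
        s2b = tune_sigma2(X)
        assert s2a == s2b
        dbar = np.median(pdist(X, "sqeuclidean"))
        # interior to the grid and near the median heuristic
        assert 0.01 * dbar < s2a < 100 * dbar
        assert dbar / 10 <= s2a <= 10 * dbar

    def test_sigma2_matches_entropy_curve_oracle(self, rng):
        """Direct argmax over the entropy curve, recomputed independently."""
        X = rng.standard_normal((60, 3))
        K_full = squareform(pdist(X, "sqeuclidean"))
        dbar = np.median(pdist(X, "sqeuclidean"))
        off = ~np.eye(len(X), dtype=bool)
        best_h, best_s2 = -np.inf, None
        for s2 in np.logspace(-2, 2, 21) * dbar:
            k = np.exp(-K_full[off] / s2)
            h_counts, _ = np.histogram(k, bins=30, range=(0, 1))
            p = h_counts[h_counts > 0] / h_counts.sum()
            h = -(p * np.log(p)).sum()
            if h > best_h + 1e-12:
                best_h, best_s2 = h, s2
        assert tune_sigma2(X) == pytest.approx(best_s2)

    def test_sigma2_degenerate_rejected(self):
        with pytest.raises(ValueError):
            tune_sigma2(np.ones((20, 3)))


class TestFit:
    def test_realizable_linear_target(self, rng):
        x = rng.standard_normal(120)
        design = build_design(x, np.concatenate([[0.0], 0.8 * x[:-1]]), L=2)
        tuning = TuningParams(c=10.0, epsilon=1e-5)
        model = fit(design, KernelSpec("linear"), tuning)
        pred = predict_in_sample(model)
        assert np.max(np.abs(pred - design.y)) < 10 * tuning.epsilon

    def test_flat_solution_inside_tube(self, rng):
        X = rng.standard_normal((50, 3))
        y = 0.01 * rng.uniform(-1, 1, 50)  # entirely inside the tube
        design = LaggedDesign(X=X, y=y, L=3, fs=2.0)
        model = fit(design, KernelSpec("linear"),
                    TuningParams(c=1.0, epsilon=0.1))
        assert np.all(model.dual_coeffs == 0.0)
        assert np.allclose(predict_in_sample(model), model.bias)

    @pytest.mark.parametrize("kind", ["linear", "rbf"])
    def test_dual_feasibility(self, rng, kind):
        X = rng.standard_normal((80, 3))
        y = X[:, 0] + 0.3 * X[:, 1] ** 2 + 0.1 * rng.standard_normal(80)
        c, eps = tune_c_epsilon(y)
        s2 = tune_sigma2(X) if kind == "rbf" else None
        kernel = KernelSpec(kind, sigma2=s2)
        model = fit(LaggedDesign(X=X, y=y, L=3, fs=2.0), kernel,
                    TuningParams(c=c, epsilon=eps, sigma2=s2))
        beta = model.dual_coeffs
        assert np.all(np.abs(beta) <= c * (1 + 1e-6))
        assert abs(beta.sum()) <= 1e-6 * c * len(beta)

    @pytest.mark.parametrize("seed", range(5))
    def test_dual_objective_matches_qp_oracle(self, seed):
        """Tiny instances against a generic SLSQP solution of the dual."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((12, 2))
        y = X[:, 0] + 0.2 * rng.standard_normal(12)
        c, eps = 1.0, 0.05
        design = LaggedDesign(X=X, y=y, L=2, fs=2.0)
        model = fit(design, KernelSpec("linear"), TuningParams(c=c, epsilon=eps))
        oracle = solve_dual_slsqp(X @ X.T, y, c, eps)
        assert model.objective == pytest.approx(oracle, abs=1e-6)

    def test_linear_prediction_equals_primal_weights(self, rng):
        X = rng.standard_normal((60, 3))
        y = X @ [0.5, -0.2, 0.1] + 0.05 * rng.standard_normal(60)
        design = LaggedDesign(X=X, y=y, L=3, fs=2.0)
        model = fit(design, KernelSpec("linear"), TuningParams(c=1.0, epsilon=0.02))
        w = X.T @ model.dual_coeffs
        assert np.allclose(predict_in_sample(model), X @ w + model.bias,
                           atol=1e-10)

    def test_rbf_prediction_recomputation(self, rng):
        X = rng.standard_normal((60, 3))
        y = np.sin(X[:, 0]) + 0.05 * rng.standard_normal(60)
        s2 = tune_sigma2(X)
        design = LaggedDesign(X=X, y=y, L=3, fs=2.0)
        model = fit(design, KernelSpec("rbf", sigma2=s2),
                    TuningParams(c=1.0, epsilon=0.02, sigma2=s2))
        D = squareform(pdist(X, "sqeuclidean"))
        pred_oracle = np.exp(-D / s2) @ model.dual_coeffs + model.bias
        assert np.allclose(predict_in_sample(model), pred_oracle, atol=1e-10)


class TestCouplingIndices:
    @pytest.mark.parametrize("seed", range(10))
    def test_independence_baseline(self, seed):
        rng = np.random.default_rng(seed)
        design = build_design(rng.standard_normal(600),
                              rng.standard_normal(600), L=16)
        res = coupling_indices(design)
        assert res.Px < 0.15
        assert res.Pxl < 0.25

    def test_quadratic_coupling_visible_only_to_rbf(self, rng):
        x = rng.standard_normal(600)
        y = np.concatenate([[0.0], x[:-1] ** 2])
        y = y - y.mean()
        res = coupling_indices(build_design(x, y, L=4))
        assert res.Pxk - res.Pxl > 0.2

    def test_strong_linear_coupling_matches_projection(self, rng):
        x = rng.standard_normal(600)
        y = np.concatenate([[0.0], x[:-1]]) + 0.05 * rng.standard_normal(600)
        res = coupling_indices(build_design(x, y, L=4))
        assert abs(res.Pxl - res.Px) < 0.1

    def test_linear_limit_converges_to_projection(self, linear_epoch):
        """As eps -> 0 and c -> large, the linear-kernel index meets Px."""
        design = build_design(linear_epoch.resp, linear_epoch.hrv, L=8)
        # c far above the IQR rule's ~0.2, epsilon far below the HRV scale
        model = fit(design, KernelSpec("linear"),
                    TuningParams(c=10.0, epsilon=1e-3))
        y_mean = design.y.mean()
        yc = design.y - y_mean
        yl = predict_in_sample(model) - y_mean
        pxl = (yl @ yl) / (yc @ yc)
        sub = build_embedding(linear_epoch.resp, 8)
        _, px, _ = project(sub, design.y)
        assert abs(pxl - px) < 0.02

    def test_respiration_rescaling_invariance(self, rng):
        x = rng.standard_normal(400)
        y = np.concatenate([[0.0], x[:-1] + 0.3 * x[:-1] ** 2])
        y += 0.1 * rng.standard_normal(400)
        r1 = coupling_indices(build_design(x, y, L=4))
        r2 = coupling_indices(build_design(3.7 * x, y, L=4))
        # RBF: the bandwidth grid scales with the data, so Pxk is invariant up
        # to roundoff; linear: the ridge penalty is not scale-free, so a small
        # finite-c drift is tolerated
        assert r2.Pxk == pytest.approx(r1.Pxk, abs=1e-3)
        assert r2.Pxl == pytest.approx(r1.Pxl, abs=0.02)
        assert r2.Px == pytest.approx(r1.Px, abs=1e-10)

    def test_determinism(self, rng):
        x = rng.standard_normal(400)
        y = np.concatenate([[0.0], 0.5 * x[:-1]]) + 0.1 * rng.standard_normal(400)
        d = build_design(x, y, L=6)
        r1, r2 = coupling_indices(d), coupling_indices(d)
        assert (r1.Px, r1.Pxl, r1.Pxk) == (r2.Px, r2.Pxl, r2.Pxk)
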