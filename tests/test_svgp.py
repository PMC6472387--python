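"""Sparse variational GP classifier: kernel algebra, inference, prediction."""

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from penaltyshot.svgp import (
    ARDKernel,
    SVGPClassifier,
    fit_svgp,
    kernel_eval,
    probit_average,
    _param_slices,
)


class TestKernel:
    def test_zero_distance_gives_variance(self):
        k = ARDKernel(2.5, [1.0, 2.0])
        assert kernel_eval([0.3, -0.1], [0.3, -0.1], k) == pytest.approx(2.5)

    def test_unit_distance_unit_lengthscale_closed_form(self):
        k = ARDKernel(1.0, [1.0])
        assert kernel_eval([0.0], [1.0], k) == pytest.approx(np.exp(-0.5))

    def test_gram_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        k = ARDKernel(1.3, rng.uniform(0.5, 2.0, 3))
        X = rng.normal(size=(5, 3))
        eig = np.linalg.eigvalsh(k(X))
        assert eig.min() >= -1e-10

    def test_kernel_bounded_by_variance_and_symmetric(self):
        rng = np.random.default_rng(1)
        k = ARDKernel(0.7, [1.0, 0.3])
        X = rng.normal(size=(6, 2))
        K = k(X)
        assert np.allclose(K, K.T)
        assert K.max() <= 0.7 + 1e-12

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ARDKernel(-1.0, [1.0])
        with pytest.raises(ValueError):
            ARDKernel(1.0, [0.0, 1.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval([0.0], [0.0, 1.0], ARDKernel(1.0, [1.0]))


class TestElboGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        n, D, M = 30, 3, 5
        X = rng.normal(size=(n, D))
        y_pm = np.where(rng.random(n) < 0.4, 1.0, -1.0)
        model = SVGPClassifier(n_inducing=M, n_quadrature=30)
        model._gh = model._gh_nodes()
        slices, npar = _param_slices(M, D)
        theta = rng.normal(scale=0.3, size=npar)
        theta[slices["Z"]] = rng.normal(size=M * D)
        idx = np.arange(n)
        _, g = model._elbo_and_grad(theta, X, y_pm, idx, slices, M, D)
        h = 1e-6
        gfd = np.zeros(npar)
        for i in range(npar):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            ep, _ = model._elbo_and_grad(tp, X, y_pm, idx, slices, M, D)
            em, _ = model._elbo_and_grad(tm, X, y_pm, idx, slices, M, D)
            gfd[i] = (ep - em) / (2 * h)
        rel = np.abs(g - gfd) / (np.abs(gfd) + 1e-6)
        assert rel.max() < 1e-4


class TestPrediction:
    def _manual_model(self, q_mu):
        m = SVGPClassifier(jitter=1e-8)
        rng = np.random.default_rng(0)
        m.kernel_ = ARDKernel(1.0, [1.0, 1.0])
        m.Z_ = rng.normal(size=(4, 2))
        m.q_mu_ = np.asarray(q_mu, float)
        m.q_S_ = np.eye(4)
        m._finalize_cache()
        return m

    def test_zero_latent_mean_predicts_half_regardless_of_variance(self):
        # the probit-Gaussian integral is symmetric: mean 0 -> pi = 0.5
        m = self._manual_model(np.zeros(4))
        X = np.random.default_rng(1).normal(size=(10, 2)) * 3
        assert np.allclose(m.predict_proba(X), 0.5)

    def test_probability_monotone_in_latent_mean(self):
        m = self._manual_model([1.0, -0.5, 0.2, 0.0])
        X = np.linspace(-2, 2, 40)[:, None] * np.ones((1, 2))
        mu, v = m.latent(X)
        p = m.predict_proba(X)
        order = np.argsort(mu / np.sqrt(1 + v))
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_far_from_data_reverts_to_prior(self, tiny_gp):
        far = np.full((1, 4), 60.0)
        mu, v = tiny_gp.latent(far)
        assert abs(mu[0]) < 1e-6
        assert v[0] == pytest.approx(tiny_gp.kernel_.variance, rel=1e-6)
        assert tiny_gp.predict_proba(far)[0] == pytest.approx(0.5, abs=1e-6)

    def test_dimension_mismatch_raises(self, tiny_gp):
        with pytest.raises(ValueError):
            tiny_gp.latent(np.zeros((3, 7)))

    def test_unfitted_model_raises(self):
        with pytest.raises(RuntimeError):
            SVGPClassifier().latent(np.zeros((1, 2)))


class TestFit:
    def test_recovers_one_dimensional_probit_function(self):
        rng = np.random.default_rng(1)
        n = 8000
        x = rng.uniform(-3, 3, size=(n, 1))
        f = np.sin(1.5 * x[:, 0]) * 1.8 - 0.5
        y = (rng.random(n) < ndtr(f)).astype(int)
        m = fit_svgp(x, y, n_inducing=30, n_iter=10000, seed=0,
                     learning_rate=0.02)
        grid = np.linspace(-2.8, 2.8, 50)[:, None]
        p_true = ndtr(np.sin(1.5 * grid[:, 0]) * 1.8 - 0.5)
        assert np.abs(m.predict_proba(grid) - p_true).max() < 0.05

    def test_flipped_labels_negate_the_latent(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 2))
        y = (rng.random(500) < ndtr(X[:, 0])).astype(int)
        m1 = fit_svgp(X, y, n_inducing=15, n_iter=500, seed=0)
        m2 = fit_svgp(X, 1 - y, n_inducing=15, n_iter=500, seed=0)
        mu1, _ = m1.latent(X[:50])
        mu2, _ = m2.latent(X[:50])
        # negation is exact up to floating-point reordering in the
        # quadrature sums, which Adam amplifies slightly over the run
        assert np.allclose(mu1, -mu2, atol=0.01)

    def test_ard_prunes_irrelevant_dimension(self):
        rng = np.random.default_rng(3)
        n = 4000
        X = rng.uniform(-3, 3, size=(n, 2))
        f = 2.0 * np.sin(2.5 * X[:, 0])
        y = (rng.random(n) < ndtr(f)).astype(int)
        m = fit_svgp(X, y, n_inducing=30, n_iter=4000, seed=0,
                     learning_rate=0.03)
        ls = m.kernel_.lengthscales
        assert ls[1] > 5.0 * ls[0]

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_svgp(X, np.ones(10), n_inducing=4, n_iter=10)

    def test_elbo_trend_is_upward(self, tiny_gp):
        trace = np.array([v for _, v in tiny_gp.elbo_trace_])
        k = len(trace) // 4
        assert trace[-k:].mean() > trace[:k].mean()


class TestAUC:
    def test_separable_data_reaches_perfect_auc(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(-4, 0.3, (100, 1)),
                            rng.normal(4, 0.3, (100, 1))])
        y = np.repeat([0, 1], 100)
        m = fit_svgp(X, y, n_inducing=10, n_iter=600, seed=0)
        assert m.score_auc(X, y) == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_auc(self, tiny_gp):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(800, 4))
        y = rng.integers(0, 2, 800)
        assert abs(tiny_gp.score_auc(X, y) - 0.5) < 0.06

    def test_single_class_test_set_rejected(self, tiny_gp):
        with pytest.raises(ValueError):
            tiny_gp.score_auc(np.zeros((5, 4)), np.ones(5))


class TestPolicyOnSyntheticCohort:
    def test_calibration_slope_near_unity_at_scale(self, fitted_policy, default_design):
        # reliability-diagram slope on >= 20k timepoints
        p = fitted_policy.predict_proba()
        y = default_design.a
        assert len(p) >= 20000
        qs = np.quantile(p, np.linspace(0, 1, 11))
        idx = np.clip(np.searchsorted(qs, p, side="right") - 1, 0, 9)
        pred, emp, w = [], [], []
        for b in range(10):
            m = idx == b
            if m.sum():
                pred.append(p[m].mean())
                emp.append(y[m].mean())
                w.append(m.sum())
        slope = np.polyfit(pred, emp, 1, w=np.sqrt(w))[0]
        assert 0.8 <= slope <= 1.2

    def test_summary_reports_hyperparameters(self, fitted_policy):
        text = fitted_policy.summary()
        assert "AUC" in text and "time_since_cp" in text


class TestUtilities:
    def test_probit_average_differs_from_plain_mean(self):
        p = np.array([0.01, 0.5])
        assert probit_average(p) != pytest.approx(p.mean())
        assert probit_average(p) == pytest.approx(
            ndtr(np.mean(ndtri(p)))
        )

    def test_probit_average_of_constant_is_identity(self):
        assert probit_average(np.full(5, 0.2)) == pytest.approx(0.2)

    def test_save_load_round_trip_preserves_predictions(self, tiny_gp, tmp_path):
        path = tmp_path / "model.npz"
        tiny_gp.save(path)
        back = SVGPClassifier.load(path)
        X = np.random.default_rng(6).normal(size=(20, 4))
        assert np.allclose(back.predict_proba(X), tiny_gp.predict_proba(X))
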