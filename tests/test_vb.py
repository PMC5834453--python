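"""Unit tests of the variational update equations and the lower bound."""

import numpy as np
import pytest
from scipy.stats import wishart

from semgmoe import _vb


def hyper(d_x, d_y, **kw):
    return _vb.Hyperparameters(d_x=d_x, d_y=d_y, **kw)


class TestInit:
    def test_responsibility_rows_sum_to_one(self, rng):
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 2))
        r, ups, pi, h = _vb.init_state(X, Y, hyper(3, 2), M_init=4, seed=0)
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((r >= 0) & (r <= 1))
        np.testing.assert_allclose(ups, 0.01 / 0.0001)
        np.testing.assert_allclose(pi, 0.25)
        assert h.m0.shape == (4, 3)

    def test_single_expert_gets_all_mass(self, rng):
        X = rng.normal(size=(10, 2))
        r, *_ = _vb.init_state(X, X[:, :1], hyper(2, 1), M_init=1, seed=1)
        np.testing.assert_allclose(r, 1.0)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(20, 2))
        Y = rng.normal(size=(20, 1))
        a = _vb.init_state(X, Y, hyper(2, 1), M_init=3, seed=7)
        b = _vb.init_state(X, Y, hyper(2, 1), M_init=3, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[3].m0, b[3].m0)

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError, match="M_init"):
            _vb.init_state(X, X[:, :1], hyper(2, 1), M_init=5, seed=0)


class TestGateUpdates:
    def test_empty_expert_keeps_prior(self, rng):
        X = rng.normal(size=(40, 2))
        r = np.column_stack([np.ones(40), np.zeros(40)])
        h = hyper(2, 1)
        h.m0 = np.array([[0.0, 0.0], [5.0, 5.0]])
        g = _vb.vbm_gates(X, r, h)
        np.testing.assert_allclose(g.m[1], [5.0, 5.0])
        assert g.beta[1] == h.beta0
        assert g.nu[1] == h.nu0
        np.testing.assert_allclose(g.B[1], np.eye(2))

    def test_flat_prior_limit_recovers_sample_mean(self, rng):
        X = rng.normal(loc=3.0, size=(200, 2))
        r = np.ones((200, 1))
        h = hyper(2, 1, beta0=1e-12)
        h.m0 = np.zeros((1, 2))
        g = _vb.vbm_gates(X, r, h)
        np.testing.assert_allclose(g.m[0], X.mean(axis=0), atol=1e-9)

    def test_posterior_mean_precision_matches_sample_covariance(self, rng):
        """E[Lambda] = nu B approaches the inverse sample covariance."""
        C = np.array([[1.0, 0.3], [0.3, 0.5]])
        X = rng.multivariate_normal([1.0, -2.0], C, size=10_000)
        r = np.ones((10_000, 1))
        h = hyper(2, 1)
        h.m0 = np.zeros((1, 2))
        g = _vb.vbm_gates(X, r, h)
        E_Lam = g.nu[0] * g.B[0]
        S_inv = np.linalg.inv(np.cov(X.T, bias=True))
        np.testing.assert_allclose(E_Lam, S_inv, rtol=0.05)


class TestExpertUpdates:
    def test_zero_responsibility_gives_prior(self, rng):
        X = rng.normal(size=(30, 2))
        Y = rng.normal(size=(30, 2))
        r = np.zeros((30, 1))
        ups = np.full((1, 3), 100.0)
        e = _vb.vbm_experts(X, Y, r, ups, hyper(2, 2))
        np.testing.assert_allclose(e.W_hat[0], 0.0)
        np.testing.assert_allclose(e.L[0], np.diag(1 / ups[0]))
        assert e.lam[0] == hyper(2, 2).lambda0
        np.testing.assert_allclose(e.Q[0], np.eye(2))

    def test_noiseless_matches_ols(self, rng):
        """With a vanishing ARD prior the posterior mean is the OLS fit."""
        X = rng.normal(size=(100, 3))
        W = rng.normal(size=(4, 2))
        Xt = np.column_stack([X, np.ones(100)])
        Y = Xt @ W
        r = np.ones((100, 1))
        ups = np.full((1, 4), 1e-12)
        e = _vb.vbm_experts(X, Y, r, ups, hyper(3, 2))
        W_ols, *_ = np.linalg.lstsq(Xt, Y, rcond=None)
        np.testing.assert_allclose(e.W_hat[0], W_ols, atol=1e-8)
        assert e.lam[0] == pytest.approx(hyper(3, 2).lambda0 + 100.0)

    def test_invalid_upsilon_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="positive"):
            _vb.vbm_experts(X, X, np.ones((10, 1)), np.zeros((1, 3)),
                            hyper(2, 2))


class TestARDUpdates:
    def test_shape_parameter_closed_form(self, rng):
        """c_i = c0 + d_y/2: with six outputs and c0 = 0.01, c_i = 3.01."""
        X = rng.normal(size=(50, 2))
        Y = rng.normal(size=(50, 6))
        e = _vb.vbm_experts(X, Y, np.ones((50, 1)), np.full((1, 3), 100.0),
                            hyper(2, 6))
        a = _vb.vbm_ard(e, hyper(2, 6))
        np.testing.assert_allclose(a.c, 3.01)
        assert np.all(a.d >= hyper(2, 6).d0)

    def test_null_weight_row_is_suppressed(self, rng):
        """A weight row pinned at zero drives E[a] to its ceiling c/d0, so
        the corresponding input loses influence."""
        e = _vb.ExpertPosterior(
            W_hat=np.array([[[1.0], [0.0], [0.5]]]),
            L=np.diag([1e-12, 1e-12, 1e-12])[None],
            lam=np.array([100.0]),
            Q=np.eye(1)[None])
        h = hyper(2, 1)
        a = _vb.vbm_ard(e, h)
        ups = a.Upsilon[0]
        assert ups[1] == pytest.approx((h.c0 + 0.5) / h.d0, rel=1e-6)
        assert ups[1] > 1e3 * max(ups[0], ups[2])

    def test_statistic_matches_monte_carlo(self, rng):
        """xi_ij equals E_q[w_ij chi w_ij'] + d_y (L)_jj by Monte Carlo."""
        L = np.array([[0.2, 0.05, 0.0], [0.05, 0.3, 0.0], [0.0, 0.0, 0.1]])
        Q = np.array([[0.5, 0.1], [0.1, 0.4]])
        lam = 12.0
        What = np.array([[1.0, -0.5], [0.3, 0.8], [0.0, 2.0]])
        ex = _vb.ExpertPosterior(W_hat=What[None], L=L[None],
                                 lam=np.array([lam]), Q=Q[None])
        xi = _vb.ard_statistic(ex)[0]
        n_mc = 100_000
        chis = wishart(df=lam, scale=Q).rvs(n_mc, random_state=rng)
        cholL = np.linalg.cholesky(L)
        samples = np.zeros((n_mc, 3))
        for k in range(n_mc):
            chol_ci = np.linalg.cholesky(np.linalg.inv(chis[k]))
            W = What + cholL @ rng.standard_normal((3, 2)) @ chol_ci.T
            samples[k] = np.einsum("jd,de,je->j", W, chis[k], W)
        se = samples.std(axis=0, ddof=1) / np.sqrt(n_mc)
        assert np.all(np.abs(samples.mean(axis=0) - xi) < 3 * se)


class TestVBEStep:
    def _sym_state(self, d_x=2, d_y=1):
        gates = _vb.GatePosterior(
            m=np.array([[-3.0, 0.0], [3.0, 0.0]]),
            beta=np.array([10.0, 10.0]),
            B=np.tile(np.eye(d_x) / 10, (2, 1, 1)),
            nu=np.array([10.0, 10.0]))
        experts = _vb.ExpertPosterior(
            W_hat=np.zeros((2, d_x + 1, d_y)),
            L=np.tile(np.eye(d_x + 1) * 0.01, (2, 1, 1)),
            lam=np.array([10.0, 10.0]),
            Q=np.tile(np.eye(d_y) / 10, (2, 1, 1)))
        return gates, experts

    def test_single_expert_is_certain(self, rng):
        X = rng.normal(size=(20, 2))
        Y = rng.normal(size=(20, 1))
        g, e = self._sym_state()
        g1 = g.subset(np.array([0]))
        e1 = e.subset(np.array([0]))
        r = _vb.vbe_step(X, Y, g1, e1, np.array([1.0]))
        np.testing.assert_allclose(r, 1.0)

    def test_symmetric_experts_split_evenly(self, rng):
        g, e = self._sym_state()
        g.m[:] = 0.0  # identical posteriors
        X = rng.normal(size=(15, 2))
        Y = rng.normal(size=(15, 1))
        r = _vb.vbe_step(X, Y, g, e, np.array([0.5, 0.5]))
        np.testing.assert_allclose(r, 0.5, atol=1e-12)

    def test_point_at_gate_mean_is_claimed(self):
        g, e = self._sym_state()
        X = np.array([[-3.0, 0.0]])
        Y = np.zeros((1, 1))
        r = _vb.vbe_step(X, Y, g, e, np.array([0.5, 0.5]))
        assert r[0, 0] > 0.99

    def test_underflow_handled_by_logsumexp(self):
        g, e = self._sym_state()
        X = np.array([[1e4, 1e4]])  # astronomically unlikely everywhere
        Y = np.zeros((1, 1))
        r = _vb.vbe_step(X, Y, g, e, np.array([0.5, 0.5]))
        assert np.all(np.isfinite(r))
        np.testing.assert_allclose(r.sum(axis=1), 1.0)


class TestMixingAndPruning:
    def test_uniform_responsibilities(self):
        r = np.full((10, 4), 0.25)
        np.testing.assert_allclose(_vb.update_mixing(r), 0.25)

    def test_zero_column_gives_zero_weight(self):
        r = np.column_stack([np.ones(6), np.zeros(6)])
        pi = _vb.update_mixing(r)
        np.testing.assert_allclose(pi, [1.0, 0.0])

    def test_weights_sum_to_one(self, rng):
        g = rng.uniform(size=(50, 5))
        r = g / g.sum(axis=1, keepdims=True)
        assert _vb.update_mixing(r).sum() == pytest.approx(1.0, abs=1e-12)

    def test_prune_noop_when_all_above_threshold(self, rng):
        r = np.full((10, 2), 0.5)
        keep, r2, pi2 = _vb.prune_experts(r, np.array([0.5, 0.5]), 0.05)
        np.testing.assert_array_equal(keep, [0, 1])
        np.testing.assert_array_equal(r2, r)

    def test_prune_removes_and_renormalizes(self):
        r = np.column_stack([np.full(10, 0.5), np.full(10, 0.5), np.zeros(10)])
        keep, r2, pi2 = _vb.prune_experts(r, np.array([0.5, 0.5, 0.0]), 0.05)
        np.testing.assert_array_equal(keep, [0, 1])
        np.testing.assert_allclose(pi2, [0.5, 0.5])
        np.testing.assert_allclose(r2.sum(axis=1), 1.0)

    def test_prune_keeps_largest_when_all_fall_below(self):
        r = np.column_stack([np.full(4, 0.6), np.full(4, 0.4)])
        with pytest.warns(UserWarning, match="keeping the largest"):
            keep, _, pi2 = _vb.prune_experts(r, np.array([0.6, 0.4]), 0.9)
        np.testing.assert_array_equal(keep, [0])
        np.testing.assert_allclose(pi2, [1.0])


class TestLowerBoundAndFit:
    def test_monotone_over_iterations(self, sess2):
        state = _vb.fit_single(sess2.X, sess2.Y, hyper(3, 2), M_init=5,
                               max_iter=60, tol=0.0,
                               seed=np.random.default_rng(3))
        diffs = np.diff(state.lower_bound_trace)
        assert diffs.min() >= -1e-8

    def test_convergence_flag_set_at_tolerance(self, sess2):
        state = _vb.fit_single(sess2.X, sess2.Y, hyper(3, 2), M_init=2,
                               max_iter=200, tol=1e-6,
                               seed=np.random.default_rng(4))
        assert state.converged
        tr = state.lower_bound_trace
        assert abs(tr[-1] - tr[-2]) <= 1e-6 * abs(tr[-1])

    def test_posteriors_remain_spd(self, sess2):
        state = _vb.fit_single(sess2.X, sess2.Y, hyper(3, 2), M_init=4,
                               max_iter=50, tol=1e-6,
                               seed=np.random.default_rng(5))
        for i in range(state.n_experts):
            np.linalg.cholesky(state.gates.B[i])
            np.linalg.cholesky(state.experts.L[i])
            np.linalg.cholesky(state.experts.Q[i])

    def test_label_permutation_symmetry(self, sess2):
        """Permuting expert columns of r permutes every VBM posterior."""
        X, Y = sess2.X, sess2.Y
        r, ups, pi, h = _vb.init_state(X, Y, hyper(3, 2), M_init=3, seed=6)
        perm = np.array([2, 0, 1])
        h_p = _vb.Hyperparameters(3, 2)
        h_p.m0 = h.m0[perm]
        g_a = _vb.vbm_gates(X, r, h)
        g_b = _vb.vbm_gates(X, r[:, perm], h_p)
        np.testing.assert_allclose(g_b.m, g_a.m[perm], atol=1e-12)
        np.testing.assert_allclose(g_b.B, g_a.B[perm], atol=1e-12)
        e_a = _vb.vbm_experts(X, Y, r, ups, h)
        e_b = _vb.vbm_experts(X, Y, r[:, perm], ups[perm], h_p)
        np.testing.assert_allclose(e_b.W_hat, e_a.W_hat[perm], atol=1e-12)
        r_a = _vb.vbe_step(X, Y, g_a, e_a, pi)
        r_b = _vb.vbe_step(X, Y, g_b, e_b, pi[perm])
        np.testing.assert_allclose(r_b, r_a[:, perm], atol=1e-10)

    def test_non_finite_bound_is_diagnosed(self, rng):
        X = rng.normal(size=(20, 2))
        Y = rng.normal(size=(20, 1))
        r, ups, pi, h = _vb.init_state(X, Y, hyper(2, 1), M_init=2, seed=8)
        g = _vb.vbm_gates(X, r, h)
        e = _vb.vbm_experts(X, Y, r, ups, h)
        a = _vb.vbm_ard(e, h)
        a.d[0, 0] = np.inf  # corrupt one posterior parameter
        with pytest.raises(FloatingPointError, match="offending"):
            _vb.lower_bound(X, Y, r, g, e, a, pi, h)
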