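"""Latent-utility updates, field full conditionals, cross-level marginals, memberships."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import integrate
from scipy.stats import norm

from gridcomp.geometry import build_grid, cardinal_adjacency, normalize_overlap
from gridcomp.priors import (
    FOUR_PI,
    HyperpriorBounds,
    build_car_precision,
    build_spde_precision,
)
from gridcomp.sampler import (
    MCMCConfig,
    ProbitGibbsSampler,
    SuffStats,
    alpha_conditional_mean,
    compute_suff_stats,
    gibbs_update_W,
    gibbs_update_alpha,
    gibbs_update_membership,
    marginal_hyper_logpost,
    membership_probabilities,
    run_sampler,
)


class _StubRng:
    """Deterministic stand-in for a Generator: returns queued normal vectors."""

    def __init__(self, vectors):
        self._queue = list(vectors)

    def standard_normal(self, size):
        v = np.asarray(self._queue.pop(0), dtype=float)
        assert v.shape == (size,) if np.isscalar(size) else v.shape == tuple(size)
        return v


class TestGibbsUpdateW:
    def test_truncated_draw_median(self, rng):
        # P=2, observed taxon 1 of 2, other utility fixed at 0.3, alpha = 0:
        # the winner's full conditional is N(0,1) truncated to (0.3, inf),
        # whose median is Phi^-1((Phi(0.3)+1)/2) ~ 0.8134
        n = 40000
        W = np.column_stack([np.full(n, -1.0), np.full(n, 0.3)])
        taxa = np.zeros(n, dtype=np.int64)
        cells = np.zeros(n, dtype=np.int64)
        alpha = np.zeros((2, 1))
        gibbs_update_W(W, taxa, cells, alpha, rng)
        expect = norm.ppf((norm.cdf(0.3) + 1) / 2)
        assert np.median(W[:, 0]) == pytest.approx(expect, abs=0.02)
        assert np.all(W[:, 0] > 0.3)

    def test_max_invariant_holds_for_all_trees(self, rng):
        n, P = 500, 4
        W = rng.standard_normal((n, P))
        taxa = rng.integers(0, P, n)
        W[np.arange(n), taxa] += 10  # make invariant hold on entry
        cells = rng.integers(0, 6, n)
        alpha = rng.standard_normal((P, 6)) * 3
        for _ in range(3):
            gibbs_update_W(W, taxa, cells, alpha, rng)
            assert np.array_equal(np.argmax(W, axis=1), taxa)

    def test_extreme_fields_stay_finite(self, rng):
        # truncation points tens of sd away must not corrupt the draws
        W = np.array([[1.0, 0.0]])
        taxa = np.array([0])
        cells = np.array([0])
        alpha = np.array([[-30.0], [30.0]])
        gibbs_update_W(W, taxa, cells, alpha, rng)
        assert np.all(np.isfinite(W))
        assert W[0, 0] > W[0, 1]

    def test_nonfinite_alpha_aborts(self, rng):
        with pytest.raises(FloatingPointError):
            gibbs_update_W(
                np.zeros((1, 2)), np.array([0]), np.array([0]),
                np.array([[np.nan], [0.0]]), rng,
            )


class TestSuffStats:
    def test_empty_cells_zeroed(self):
        stats = compute_suff_stats(np.zeros((0, 2)), np.zeros(0, dtype=int), 4)
        assert np.all(stats.A == 0)
        assert np.all(stats.wbar == 0)

    def test_mean_arithmetic(self):
        W = np.array([[1.0], [3.0]])
        stats = compute_suff_stats(W, np.array([2, 2]), 4)
        assert stats.A[2] == 2
        assert stats.wbar[2, 0] == 2.0

    def test_reassignment_conserves_totals(self, rng):
        W = rng.standard_normal((30, 2))
        cells = rng.integers(0, 5, 30)
        before = compute_suff_stats(W, cells, 5)
        cells2 = cells.copy()
        cells2[0] = (cells2[0] + 1) % 5
        after = compute_suff_stats(W, cells2, 5)
        assert before.A.sum() == after.A.sum() == 30


class TestAlphaFullConditional:
    def _dense(self, stats, Qp, mu):
        M = Qp.toarray() + np.diag(stats.A)
        b = stats.A * stats.wbar[:, 0] + Qp.toarray() @ (mu * np.ones(Qp.shape[0]))
        return M, b

    @pytest.mark.parametrize("kind", ["car", "spde"])
    def test_moments_match_dense_oracle(self, kind, rng):
        g = build_grid(4, 4)
        adj = cardinal_adjacency(g)
        m = g.n_cells
        A = rng.integers(0, 8, m).astype(float)
        stats = SuffStats(A=A, wbar=rng.standard_normal((m, 1)))
        if kind == "car":
            Qp = build_car_precision(adj).Q / 1.3**2
            root = adj.incidence() / 1.3
            mu = 0.0
        else:
            t = build_spde_precision(adj, 2.0)
            c = 0.7**2 * FOUR_PI * 2.0**2
            Qp = t.Q / c
            root = t.root / np.sqrt(c)
            mu = 0.4
        M, b = self._dense(stats, Qp, mu)
        # conditional mean
        assert np.allclose(
            alpha_conditional_mean(stats, Qp, 0, mu), np.linalg.solve(M, b), atol=1e-10
        )
        # the draw is an affine map of the injected noise; with noise zeroed
        # it returns the mean, and its covariance is M^-1 exactly
        z = [np.zeros(m), np.zeros(root.shape[0])]
        draw = gibbs_update_alpha(stats, Qp, root, 0, _StubRng(z), mu_p=mu)
        assert np.allclose(draw, np.linalg.solve(M, b), atol=1e-8)
        # unit-noise responses reproduce M^-1 (A + Q) M^-1 = M^-1 column-wise
        Minv = np.linalg.inv(M)
        cov_map = np.zeros((m, m))
        sqrtA = np.diag(np.sqrt(A))
        L1 = np.linalg.solve(M, sqrtA)
        L2 = np.linalg.solve(M, root.toarray().T)
        cov_map = L1 @ L1.T + L2 @ L2.T
        assert np.allclose(cov_map, Minv, atol=1e-8)

    def test_no_data_spde_returns_prior(self):
        g = build_grid(3, 3)
        adj = cardinal_adjacency(g)
        m = g.n_cells
        t = build_spde_precision(adj, 1.0)
        stats = SuffStats(A=np.zeros(m), wbar=np.zeros((m, 1)))
        mean = alpha_conditional_mean(stats, t.Q / FOUR_PI, 0, mu_p=1.7)
        assert np.allclose(mean, 1.7, atol=1e-9)

    def test_single_cell_car_reduces_to_sample_mean(self):
        stats = SuffStats(A=np.array([5.0]), wbar=np.array([[0.9]]))
        Qp = sp.csr_matrix((1, 1))
        mean = alpha_conditional_mean(stats, Qp, 0)
        assert mean[0] == pytest.approx(0.9, abs=1e-12)


class TestCrossLevelMarginal:
    def test_car_two_cell_matches_dense_marginalization(self):
        # brute force: integrate p(W|alpha) p(alpha|sigma) over alpha in 2-D
        # with dense matrices, including the improper ICAR's 1/sigma factor
        g = build_grid(2, 1)
        adj = cardinal_adjacency(g)
        t = build_car_precision(adj)
        stats = SuffStats(A=np.array([4.0, 2.0]), wbar=np.array([[0.8], [-0.3]]))

        def dense_log_marginal(sigma):
            A = np.diag(stats.A)
            Q = t.Q.toarray() / sigma**2
            M = A + Q
            b = stats.A * stats.wbar[:, 0]
            # int exp(-1/2 (a-wbar)'A(a-wbar)) (1/sigma) exp(-1/2 a'Qa) da
            val = (
                -np.log(sigma)
                - 0.5 * np.linalg.slogdet(M)[1]
                + 0.5 * b @ np.linalg.solve(M, b)
                - 0.5 * stats.wbar[:, 0] @ (A @ stats.wbar[:, 0])
            )
            return val + np.log(sigma)  # log-scale sampling Jacobian

        for s1, s2 in [(0.7, 1.4), (1.0, 3.0), (2.5, 0.4)]:
            mine = marginal_hyper_logpost(stats, "car", t, 0, s2) - marginal_hyper_logpost(
                stats, "car", t, 0, s1
            )
            oracle = dense_log_marginal(s2) - dense_log_marginal(s1)
            assert mine == pytest.approx(oracle, abs=1e-8)

    def test_car_two_cell_matches_quadrature(self):
        g = build_grid(2, 1)
        adj = cardinal_adjacency(g)
        t = build_car_precision(adj)
        stats = SuffStats(A=np.array([3.0, 2.0]), wbar=np.array([[0.5], [-0.2]]))

        def quad_log_marginal(sigma):
            def f(a2, a1):
                lik = np.exp(
                    -0.5 * (3.0 * (a1 - 0.5) ** 2 + 2.0 * (a2 + 0.2) ** 2)
                )
                prior = np.exp(-((a1 - a2) ** 2) / (2 * sigma**2)) / sigma
                return lik * prior
            val, _ = integrate.dblquad(f, -12, 12, -12, 12, epsabs=1e-13, epsrel=1e-11)
            return np.log(val) + np.log(sigma)

        mine = marginal_hyper_logpost(stats, "car", t, 0, 1.8) - marginal_hyper_logpost(
            stats, "car", t, 0, 0.9
        )
        oracle = quad_log_marginal(1.8) - quad_log_marginal(0.9)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_spde_matches_quadrature(self):
        g = build_grid(2, 1)
        adj = cardinal_adjacency(g)
        stats = SuffStats(A=np.array([3.0, 2.0]), wbar=np.array([[0.7], [-0.4]]))

        def brute(sigma, mu, rho):
            t = build_spde_precision(adj, rho)
            Q = t.Q.toarray() / (sigma**2 * FOUR_PI * rho**2)

            def f(a2, a1):
                al = np.array([a1, a2])
                ll = -0.5 * float(stats.A @ (al - stats.wbar[:, 0]) ** 2)
                d = al - mu
                lp = -0.5 * d @ Q @ d + 0.5 * np.linalg.slogdet(Q)[1]
                return np.exp(ll + lp)

            val, _ = integrate.dblquad(f, -25, 25, -25, 25, epsabs=1e-13, epsrel=1e-11)
            return np.log(val) + np.log(sigma) + np.log(rho)

        ref = None
        for sigma, mu, rho in [(1.0, 0.0, 1.0), (0.5, 0.3, 2.0), (2.0, -1.0, 0.5)]:
            t = build_spde_precision(adj, rho)
            mine = marginal_hyper_logpost(stats, "spde", t, 0, sigma, mu=mu, rho=rho, grid=g)
            oracle = brute(sigma, mu, rho)
            if ref is None:
                ref = (mine, oracle)
            else:
                assert mine - ref[0] == pytest.approx(oracle - ref[1], abs=1e-7)

    def test_out_of_support_rejected(self):
        g = build_grid(2, 1)
        adj = cardinal_adjacency(g)
        t = build_car_precision(adj)
        stats = SuffStats(A=np.array([1.0, 1.0]), wbar=np.zeros((2, 1)))
        assert marginal_hyper_logpost(stats, "car", t, 0, 1001.0) == -np.inf
        ts = build_spde_precision(adj, 0.05)
        assert (
            marginal_hyper_logpost(stats, "spde", ts, 0, 1.0, mu=0.0, rho=0.05, grid=g)
            == -np.inf
        )

    def test_identical_proposal_accepts(self):
        # acceptance log-ratio for an unchanged block is exactly zero
        g = build_grid(3, 1)
        adj = cardinal_adjacency(g)
        t = build_car_precision(adj)
        stats = SuffStats(A=np.array([2.0, 0.0, 1.0]), wbar=np.array([[0.1], [0.0], [-0.6]]))
        lp = marginal_hyper_logpost(stats, "car", t, 0, 1.23)
        assert marginal_hyper_logpost(stats, "car", t, 0, 1.23) == lp


class TestMembership:
    def test_single_cell_township(self):
        p = membership_probabilities(np.array([0.0]), np.zeros((1, 4)), np.array([2]), np.array([1.0]))
        assert p.tolist() == [1.0]

    def test_symmetric_cells_split_evenly(self):
        alpha = np.zeros((2, 3))
        p = membership_probabilities(
            np.array([0.4, -0.2]), alpha, np.array([0, 2]), np.array([0.5, 0.5])
        )
        assert np.allclose(p, [0.5, 0.5])

    def test_density_ratio_example(self):
        # two cells, equal psi, P=1, W=0, alpha=(0,1): odds phi(0):phi(1) = e^0.5
        alpha = np.array([[0.0, 1.0]])
        p = membership_probabilities(np.array([0.0]), alpha, np.array([0, 1]), np.array([0.5, 0.5]))
        expect = np.exp(0.5) / (np.exp(0.5) + 1)
        assert p[0] == pytest.approx(expect, abs=1e-12)
        assert p[0] == pytest.approx(0.6225, abs=1e-4)

    def test_underflow_safe(self):
        alpha = np.array([[0.0, 500.0]])
        p = membership_probabilities(np.array([0.0]), alpha, np.array([0, 1]), np.array([0.5, 0.5]))
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)

    def test_sweep_respects_support_and_frequencies(self, rng):
        # many identical trees in one township: empirical assignment
        # frequencies converge to the analytic posterior weights
        g = build_grid(2, 1)
        ov = normalize_overlap([("t", 0, 0.5), ("t", 1, 0.5)])
        from gridcomp.sampler import LatentState, _overlap_arrays
        from gridcomp.priors import HyperParams

        n = 20000
        state = LatentState(
            W=np.zeros((n, 1)),
            alpha=np.array([[0.0, 1.0]]),
            tree_cell=np.zeros(n, dtype=np.int64),
            tree_town=np.zeros(n, dtype=np.int64),
            taxa=np.zeros(n, dtype=np.int64),
            hp=HyperParams(sigma=np.ones(1)),
        )
        gibbs_update_membership(state, _overlap_arrays(ov), rng)
        frac0 = np.mean(state.tree_cell == 0)
        assert frac0 == pytest.approx(np.exp(0.5) / (np.exp(0.5) + 1), abs=0.01)


class TestRunSampler:
    def test_determinism_bitwise(self):
        g = build_grid(3, 3)
        counts = np.zeros((9, 2), dtype=int)
        counts[:, 0] = 5
        counts[:, 1] = 3
        cfg = MCMCConfig(n_iter=60, n_burn=20, n_keep=10, seed=42)
        a = run_sampler(counts, "car", g, config=cfg)
        b = run_sampler(counts, "car", g, config=cfg)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.sigma, b.sigma)

    def test_zero_count_taxa_dropped_with_warning(self, caplog):
        g = build_grid(2, 2)
        counts = np.zeros((4, 3), dtype=int)
        counts[:, 0] = 4
        counts[:, 2] = 4
        with caplog.at_level("WARNING", logger="gridcomp.sampler"):
            post = run_sampler(
                g.n_cells and counts, "car", g,
                config=MCMCConfig(n_iter=30, n_burn=10, n_keep=5, seed=0),
            )
        assert post.taxa_kept.tolist() == [0, 2]
        assert "dropping" in caplog.text

    def test_single_taxon_aborts(self):
        g = build_grid(2, 2)
        counts = np.zeros((4, 2), dtype=int)
        counts[:, 0] = 3
        with pytest.raises(ValueError):
            run_sampler(counts, "car", g, config=MCMCConfig(n_iter=20, n_burn=5, n_keep=5))

    def test_single_cell_consistency(self):
        # one cell, 700/300 split: posterior mean composition near 0.7
        from gridcomp.composition import theta_from_posterior

        g = build_grid(1, 1)
        counts = np.array([[700, 300]])
        post = run_sampler(
            counts, "car", g, config=MCMCConfig(n_iter=800, n_burn=200, n_keep=150, seed=3)
        )
        ts = theta_from_posterior(post, n_mc=4000, seed=1)
        theta1 = ts.theta[:, 0, 0].mean()
        assert theta1 == pytest.approx(0.7, abs=0.03)

    def test_township_conservation_and_support(self, rng):
        # township trees must stay inside their overlap support and the
        # total tree count is conserved across membership resampling
        from gridcomp.sampler import compute_suff_stats

        g = build_grid(3, 1)
        overlap = normalize_overlap([("a", 0, 1.0), ("a", 1, 1.0), ("b", 2, 1.0)])
        tcounts = np.array([[6, 4], [3, 5]])
        cfg = MCMCConfig(n_iter=40, n_burn=10, n_keep=5, seed=9)
        sampler = ProbitGibbsSampler(None, "car", g, township_counts=tcounts, overlap=overlap, config=cfg)
        for _ in range(10):
            sampler.step()
            stats = sampler.stats
            assert stats.A.sum() == tcounts.sum()
            trees_ab = sampler.state.tree_town == 0
            assert set(np.unique(sampler.state.tree_cell[trees_ab])) <= {0, 1}
            assert np.all(sampler.state.tree_cell[sampler.state.tree_town == 1] == 2)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=10, n_burn=10, n_keep=1)
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=10, n_burn=2, n_keep=9)
        g = build_grid(2, 2)
        with pytest.raises(ValueError):
            run_sampler(np.ones((4, 2), dtype=int), "icar", g)


class TestPriorInvariance:
    def test_geweke_successive_conditional(self):
        """Alternating data regeneration with the transition kernel leaves the
        joint prior invariant: chain moments of the hyperparameters match
        their uniform priors within Monte Carlo error."""
        g = build_grid(3, 3)
        counts = np.zeros((9, 2), dtype=int)
        counts[:, 0] = 1
        counts[0, 1] = 1
        bounds = HyperpriorBounds(sigma_max=2.0, mu_abs_max=1.0, rho_min=1.0, rho_max=4.0)
        cfg = MCMCConfig(n_iter=10, n_burn=1, n_keep=1, seed=77, adapt=False)
        s = ProbitGibbsSampler(counts, "spde", g, config=cfg, bounds=bounds)
        s.draw_hyperparams_from_prior()
        s.draw_fields_from_prior()
        s.regenerate_data()

        N = 12000
        sig = np.empty(N)
        rho = np.empty(N)
        mu = np.empty(N)
        for i in range(N):
            s.step()
            s.regenerate_data()
            sig[i] = s.state.hp.sigma[0]
            rho[i] = s.state.hp.rho[0]
            mu[i] = s.state.hp.mu[0]

        def max_z(x, mean_true, var_true):
            xc = x - x.mean()
            n = len(x)
            ac = np.correlate(xc, xc, "full")[n - 1 :] / (xc @ xc)
            tau = 1.0
            for L in range(1, 2000):
                if ac[L] < 0.02:
                    break
                tau += 2 * ac[L]
            se = np.sqrt(var_true * tau / n)
            return abs(x.mean() - mean_true) / se

        assert max_z(sig, 1.0, 1 / 3) < 4.0
        assert max_z(rho, 2.5, 0.75) < 4.0
        assert max_z(mu, 0.0, 1 / 3) < 4.0
        # marginal variances should match the prior too (10% slack)
        assert sig.var() == pytest.approx(1 / 3, rel=0.15)
        assert rho.var() == pytest.approx(0.75, rel=0.15)
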