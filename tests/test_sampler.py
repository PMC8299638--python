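"""Gibbs-sweep conditionals against closed-form and Monte-Carlo oracles."""

import time

import numpy as np
import pytest

from factorlmm import (
    MCMCConfig,
    ModelSpec,
    RandomEffectTerm,
    RelationshipMatrix,
    TraitMatrix,
    initialize_state,
    run_mcmc,
    simulate_factor_truth,
    simulate_kinship,
)
from factorlmm import sampler as smp


def _complete_tm(n, t, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n, t))
    return TraitMatrix(
        vals, np.ones((n, t), bool), [f"u{i}" for i in range(n)], [f"y{j}" for j in range(t)]
    )


def _state(n=10, t=3, K=2, seed=0, kin_seed=9, hyper=None, tm=None):
    Kmat = simulate_kinship(n, seed=kin_seed)
    tm = tm if tm is not None else _complete_tm(n, t, seed=seed + 50)
    spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=K, hyper=hyper or {})
    return initialize_state(tm, spec, seed=seed)


class TestInitializeState:
    def test_same_seed_identical_states(self):
        s1, s2 = _state(seed=4), _state(seed=4)
        for a, b in [(s1.F, s2.F), (s1.Lambda, s2.Lambda), (s1.sigma2, s2.sigma2)]:
            assert np.array_equal(a, b)

    def test_zero_factors_valid(self):
        s = _state(K=0)
        assert s.F.shape == (10, 0) and s.Lambda.shape == (0, 3)
        smp.gibbs_sweep(s)  # univariate-stack model still sweeps

    def test_K_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="K <= n"):
            _state(n=6, t=8, K=7)

    def test_initial_factors_explain_rank_K_svd_variance(self):
        s = _state(n=20, t=6, K=3, seed=1)
        Yc = s.Yw - s.X1w @ s.B1
        _, sv, _ = np.linalg.svd(Yc, full_matrices=False)
        svd_explained = np.sum(sv[:3] ** 2)
        init_explained = np.sum(Yc**2) - np.sum((Yc - s.F @ s.Lambda) ** 2)
        assert init_explained >= svd_explained - 1e-6


class TestFactorScores:
    def test_zero_loadings_draws_follow_level2_marginal(self):
        s = _state(n=8, t=3, K=2, seed=2)
        s.Lambda = np.zeros((2, 3))
        draws = []
        for _ in range(3000):
            smp.sample_factor_scores(s)
            draws.append(s.F.copy())
        draws = np.stack(draws)
        # with no data term, rows of F follow N(prior mean, psi_FE) per factor
        prior_mean = s.Zu_F()
        var_emp = draws.var(axis=0)
        for k in range(2):
            v = s.psi_FE[k]
            assert np.allclose(draws[:, :, k].mean(axis=0), prior_mean[:, k], atol=4 * np.sqrt(v / 3000))
            assert np.allclose(var_emp[:, k], v, rtol=0.25)

    def test_noiseless_limit_concentrates_on_lambda_inverse(self):
        s = _state(n=8, t=2, K=2, seed=3)
        s.Lambda = np.array([[1.0, 0.3], [-0.2, 0.8]])
        s.sigma2 = np.full(2, 1e-10)  # psi_RE -> 0
        smp.sample_factor_scores(s)
        target = (s.Yw - s.X1w @ s.B1 - s.Zu_R()) @ np.linalg.inv(s.Lambda)
        assert np.allclose(s.F, target, atol=1e-3)

    def test_conditional_mean_matches_hand_derived(self):
        s = _state(n=5, t=2, K=2, seed=4)
        draws = np.stack([smp.sample_factor_scores(s).F.copy() for _ in range(4000)])
        psi_RE, pvF = s.psi_RE, s.psi_FE
        P = (s.Lambda / psi_RE) @ s.Lambda.T + np.diag(1.0 / pvF)
        R = s.Yw - s.X1w @ s.B1 - s.Zu_R()
        RHS = (R / psi_RE) @ s.Lambda.T + s.Zu_F() / pvF
        mean = np.linalg.solve(P, RHS.T).T
        sd = np.sqrt(np.diag(np.linalg.inv(P)))
        se = sd / np.sqrt(4000)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se[None, :])


class TestLoadings:
    def test_infinite_shrinkage_drives_loadings_to_zero(self):
        s = _state(n=10, t=3, K=2, seed=5)
        s.shrinkage.lam_phi2 = np.full((2, 3), 1e-16)
        smp.sample_loadings(s)
        assert np.abs(s.Lambda).max() < 1e-4

    def test_conditional_mean_matches_dense_ridge(self):
        s = _state(n=6, t=3, K=2, seed=6)
        pv = s.shrinkage.lambda_prior_var()
        draws = np.stack([smp.sample_loadings(s).Lambda.copy() for _ in range(4000)])
        W = s.Yw - s.X1w @ s.B1 - s.Zu_R()
        for j in range(3):
            P = np.diag(s.psi_RE[j] / pv[:, j])
            mean = np.linalg.solve(s.F.T @ s.F + P, s.F.T @ W[:, j])
            cov = s.psi_RE[j] * np.linalg.inv(s.F.T @ s.F + P)
            se = np.sqrt(np.diag(cov) / 4000)
            assert np.all(np.abs(draws[:, :, j].mean(axis=0) - mean) < 4 * se)

    def test_flat_prior_noiseless_recovers_least_squares(self):
        rng = np.random.default_rng(7)
        n, t, K = 30, 4, 2
        F_true = rng.standard_normal((n, K))
        L_true = rng.standard_normal((K, t))
        tm = TraitMatrix(
            F_true @ L_true, np.ones((n, t), bool),
            [f"u{i}" for i in range(n)], [f"y{j}" for j in range(t)],
        )
        s = _state(n=n, t=t, K=K, seed=7, tm=tm)
        s.F = s.cache.to_working(F_true)
        s.B1 = np.zeros_like(s.B1)
        s.U_R = np.zeros_like(s.U_R)
        s.Yw = s.cache.to_working(tm.values)
        s.sigma2 = np.full(t, 1e-8)
        s.shrinkage.lam_phi2 = np.full((K, t), 1e12)  # effectively flat
        smp.sample_loadings(s)
        lsq = np.linalg.lstsq(F_true, tm.values, rcond=None)[0]
        assert np.allclose(s.Lambda, lsq, atol=1e-2)


class TestLocationEffects:
    def test_zero_variance_grid_point_gives_zero_u(self):
        s = _state(n=8, t=2, K=0, seed=8)
        g0 = int(np.where(s.grid.points[:, 0] == 0.0)[0][0])
        s.gi_traits[:] = g0
        smp.sample_location_effects(s)
        assert np.allclose(s.U_R, 0.0)

    def test_intercept_mean_is_column_mean_at_zero_h(self):
        s = _state(n=50, t=2, K=0, seed=9)
        g0 = int(np.where(s.grid.points[:, 0] == 0.0)[0][0])
        s.gi_traits[:] = g0
        draws = np.stack([smp.sample_location_effects(s).B1.copy() for _ in range(3000)])
        col_mean = (np.linalg.pinv(s.X1w) @ s.Yw)[0]
        se = np.sqrt(s.sigma2 / 50 / 3000)
        assert np.all(np.abs(draws.mean(axis=0)[0] - col_mean) < 4 * se)

    def test_joint_draw_mean_matches_dense_conditional(self):
        s = _state(n=8, t=2, K=0, seed=10)
        gi = s.gi_traits.copy()
        B_draws, U_draws = [], []
        for _ in range(4000):
            s.gi_traits = gi.copy()
            smp.sample_location_effects(s)
            B_draws.append(s.B1.copy())
            U_draws.append(s.U_R.copy())
        B_draws, U_draws = np.stack(B_draws), np.stack(U_draws)
        Kmat = s.spec.terms[0].Kmat.matrix
        d, Q = s.spec.terms[0].Kmat.eigendecomposition()
        j = 0
        h = s.grid.points[gi[j], 0]
        Sigma = h * np.diag(d) + (1 - h) * np.eye(8)  # working basis
        X = s.X1w
        y = s.Yw[:, j]
        # B marginal conditional (flat prior): GLS estimate
        Si = np.linalg.inv(Sigma)
        B_mean = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        assert np.all(
            np.abs(B_draws[:, 0, j].mean() - B_mean)
            < 4 * np.sqrt(s.sigma2[j] * np.linalg.inv(X.T @ Si @ X)[0, 0] / 4000) + 1e-3
        )
        # E[u | y] = h D Sigma^-1 (y - X E[B]) in the rotated basis
        u_mean = h * d * (Si @ (y - X @ B_mean))
        sd_u = np.sqrt(s.sigma2[j] * h * d * (1 - h) / np.diag(Sigma))
        se = sd_u / np.sqrt(4000) + 1e-4
        assert np.all(np.abs(U_draws[:, :, j].mean(axis=0) - u_mean) < 5 * se)


class TestVarianceProportions:
    def test_single_point_grid_always_selected(self):
        from factorlmm import build_variance_grid, cache_grid_factorizations
        from factorlmm.priors import VarianceGrid

        n = 8
        Kmat = simulate_kinship(n, seed=9)
        grid = VarianceGrid(np.array([[0.3]]), np.array([1.0]), 0.3)
        cache_grid_factorizations(grid, [RandomEffectTerm(Kmat=Kmat)], n)
        tm = _complete_tm(n, 2)
        spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=0)
        s = initialize_state(tm, spec, seed=0, grid=grid)
        smp.sample_variance_proportions(s)
        assert np.all(s.gi_traits == 0)

    def test_equal_likelihood_points_selected_evenly(self):
        # symmetric two-point grid with K = I: both points give identical
        # marginal likelihoods, so selection frequency must be ~1/2
        from factorlmm.priors import VarianceGrid, cache_grid_factorizations

        n = 10
        Kmat = RelationshipMatrix(np.eye(n))
        grid = VarianceGrid(np.array([[0.2], [0.2]]), np.array([0.5, 0.5]), 0.2)
        cache_grid_factorizations(grid, [RandomEffectTerm(Kmat=Kmat)], n)
        tm = _complete_tm(n, 1)
        spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=0)
        s = initialize_state(tm, spec, seed=1, grid=grid)
        picks = []
        for _ in range(10000):
            smp.sample_variance_proportions(s)
            picks.append(s.gi_traits[0])
        freq = np.mean(picks)
        assert abs(freq - 0.5) < 4 * np.sqrt(0.25 / 10000)


class TestResidualVariances:
    def test_conditional_matches_inverse_gamma_closed_form(self):
        s = _state(n=5, t=1, K=0, seed=11)
        g0 = int(np.where(s.grid.points[:, 0] == 0.0)[0][0])
        s.gi_traits[:] = g0
        s.U_R[:] = 0.0
        s.B1[:] = 0.0
        resid = s.Yw[:, 0]
        a0 = s.shrinkage.hyper["sigma2_shape"]
        b0 = s.shrinkage.hyper["sigma2_rate"]
        a_post = a0 + 5 / 2
        b_post = b0 + 0.5 * np.sum(resid**2)
        draws = np.array(
            [smp.sample_residual_variances(s).sigma2[0] for _ in range(20000)]
        )
        mean_th = b_post / (a_post - 1)
        var_th = b_post**2 / ((a_post - 1) ** 2 * (a_post - 2))
        assert abs(draws.mean() - mean_th) < 5 * np.sqrt(var_th / 20000)

    def test_known_variance_recovered(self):
        rng = np.random.default_rng(12)
        n = 10_000
        tm = TraitMatrix(
            rng.normal(0, np.sqrt(2.0), size=(n, 1)), np.ones((n, 1), bool),
            [f"u{i}" for i in range(n)], ["y"],
        )
        Kmat = RelationshipMatrix(np.eye(n))
        # identity spectrum is known; preload it so no O(n^3) eigh runs
        Kmat._eigvals = np.ones(n)
        Kmat._eigvecs = np.eye(n)
        spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=0)
        s = initialize_state(tm, spec, seed=12)
        g0 = int(np.where(s.grid.points[:, 0] == 0.0)[0][0])
        s.gi_traits[:] = g0
        s.U_R[:] = 0.0
        s.B1[:] = 0.0
        smp.sample_residual_variances(s)
        assert abs(s.sigma2[0] - 2.0) / 2.0 < 0.05


class TestMissingValues:
    def test_no_missing_unchanged(self):
        s = _state(n=8, t=2, K=0, seed=13)
        before = s.Yw.copy()
        smp.sample_missing_values(s)
        assert np.array_equal(before, s.Yw)

    def test_imputation_mean_matches_conditional_mean(self):
        tm = _complete_tm(8, 2, seed=14)
        tm.mask[0, 0] = False
        tm.values[0, 0] = np.nan
        s = _state(n=8, t=2, K=0, seed=14, tm=tm)
        draws = []
        for _ in range(5000):
            smp.sample_missing_values(s)
            draws.append(s.Y_orig[0, 0])
        mean_th = s.cache.from_working(s.mean_w())[0, 0]
        sd = np.sqrt(s.psi_RE[0])
        assert abs(np.mean(draws) - mean_th) < 4 * sd / np.sqrt(5000)

    def test_zero_residual_variance_is_deterministic(self):
        tm = _complete_tm(8, 2, seed=15)
        tm.mask[3, 1] = False
        tm.values[3, 1] = np.nan
        s = _state(n=8, t=2, K=0, seed=15, tm=tm)
        s.sigma2[:] = 1e-18
        smp.sample_missing_values(s)
        v1 = s.Y_orig[3, 1]
        smp.sample_missing_values(s)
        assert np.isclose(v1, s.Y_orig[3, 1], atol=1e-7)


class TestPruneFactors:
    def test_all_above_threshold_unchanged(self):
        s = _state(n=10, t=4, K=2, seed=16)
        s.Lambda = np.array([[1.0, 1, 1, 1], [0.9, 0.9, 0.9, 0.9]])
        K_before = s.K
        smp.prune_factors(s, threshold=0.01)
        assert s.K == K_before

    def test_zero_loading_factor_removed(self):
        s = _state(n=10, t=4, K=3, seed=17)
        s.Lambda[1, :] = 0.0
        smp.prune_factors(s, threshold=0.001)
        assert s.K == 2
        assert s.shrinkage.lam_phi2.shape[0] == 2

    def test_explained_variance_never_increases(self):
        s = _state(n=10, t=4, K=3, seed=18)
        total_before = np.sum(s.Lambda**2)
        smp.prune_factors(s, threshold=0.2)
        assert np.sum(s.Lambda**2) <= total_before + 1e-12


class TestRunMcmc:
    def test_seed_determinism(self):
        tm, _ = simulate_factor_truth(20, 4, 2, seed=30)
        Kmat = simulate_kinship(20, seed=31)
        def fit():
            spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=2)
            cfg = MCMCConfig(iterations=40, burnin=20, thin=2, seed=5)
            return run_mcmc(tm, spec, cfg)
        s1, s2 = fit(), fit()
        for k in s1.draws:
            assert np.array_equal(s1.draws[k], s2.draws[k])

    def test_iterations_equal_burnin_stores_nothing(self):
        tm, _ = simulate_factor_truth(15, 3, 1, seed=32)
        Kmat = simulate_kinship(15, seed=33)
        spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=1)
        cfg = MCMCConfig(iterations=10, burnin=10, thin=2, seed=0)
        s = run_mcmc(tm, spec, cfg)
        assert s.n_samples == 0

    @pytest.mark.parametrize("iters,burn,thin,expect", [(11, 5, 2, 3), (10, 5, 5, 1)])
    def test_stored_count_formula(self, iters, burn, thin, expect):
        tm, _ = simulate_factor_truth(15, 3, 1, seed=34)
        Kmat = simulate_kinship(15, seed=35)
        spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=1)
        s = run_mcmc(tm, spec, MCMCConfig(iterations=iters, burnin=burn, thin=thin, seed=0))
        assert s.n_samples == expect

    def test_observation_cap_enforced(self):
        tm = _complete_tm(8, 2)
        Kmat = simulate_kinship(8, seed=36)
        terms = [RandomEffectTerm(Kmat=Kmat)] * 5
        spec = ModelSpec(terms=terms, K=1, hyper={"grid_step": 0.3})
        with pytest.raises(ValueError, match="caps"):
            initialize_state(tm, spec, seed=0)

    def test_multiple_random_effects_general_backend(self):
        # kernel-averaging style fit: three kernels as three random effects
        rng = np.random.default_rng(37)
        n = 20
        from factorlmm import gaussian_kernels

        X = rng.standard_normal((n, 4))
        D = np.sum((X[:, None] - X[None, :]) ** 2, axis=2)
        kernels = gaussian_kernels(D)
        tm = _complete_tm(n, 3, seed=38)
        spec = ModelSpec(
            terms=[RandomEffectTerm(Kmat=Km) for Km in kernels], K=2,
            hyper={"grid_step": 0.25},
        )
        s = run_mcmc(tm, spec, MCMCConfig(iterations=30, burnin=20, thin=1, seed=1))
        assert s.get("G").shape == (10, 3, 3, 3)  # (draws, M, t, t)


class TestScaling:
    def test_per_sweep_cost_grows_linearly_in_t(self):
        # doubling t four-fold should cost about four-fold at fixed n, K
        times = {}
        for t in (50, 200):
            Kmat = simulate_kinship(100, seed=1)
            tm, _ = simulate_factor_truth(100, t, 3, K_mats=[Kmat], seed=2)
            spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=10)
            s = initialize_state(tm, spec, seed=3)
            for _ in range(3):
                smp.gibbs_sweep(s)  # warm-up
            reps = []
            for _ in range(3):
                t0 = time.perf_counter()
                for _ in range(10):
                    smp.gibbs_sweep(s)
                reps.append(time.perf_counter() - t0)
            times[t] = min(reps)
        ratio = times[200] / times[50]
        assert abs(ratio - 4.0) <= 0.3 * 4.0
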