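"""Covariance assembly, predictions for new lines, and chain summaries."""

import numpy as np
import pytest

from factorlmm import (
    MCMCConfig,
    ModelSpec,
    RandomEffectTerm,
    RelationshipMatrix,
    effective_sample_size,
    hpd_interval,
    run_mcmc,
    simulate_factor_truth,
    simulate_kinship,
    summarize,
)
from factorlmm.posterior import (
    PosteriorSamples,
    assemble_covariance,
    factor_representation,
    predict_new_lines,
    summary_table,
)
from factorlmm.data_model import ScalingRecord


class TestAssembly:
    def test_zero_loadings_gives_diagonal(self):
        G = assemble_covariance(np.zeros((2, 3)), np.zeros(2), np.array([0.3, 0.5, 0.7]))
        assert np.allclose(G, np.diag([0.3, 0.5, 0.7]))

    def test_hand_computed_two_trait_example(self):
        # Lambda = [[1, 1]], Psi_F = diag(2), Psi_R = diag(0.5, 0.5)
        G = assemble_covariance(np.array([[1.0, 1.0]]), np.array([2.0]), np.array([0.5, 0.5]))
        assert np.allclose(G, [[2.5, 2.0], [2.0, 2.5]])

    def test_monte_carlo_covariance_matches_assembly(self):
        rng = np.random.default_rng(0)
        K, t = 3, 4
        Lam = rng.standard_normal((K, t))
        psi_F = rng.uniform(0.2, 1.0, K)
        psi_R = rng.uniform(0.2, 1.0, t)
        n = 100_000
        rows = rng.standard_normal((n, K)) * np.sqrt(psi_F) @ Lam + rng.standard_normal(
            (n, t)
        ) * np.sqrt(psi_R)
        emp = np.cov(rows.T)
        G = assemble_covariance(Lam, psi_F, psi_R)
        se = np.sqrt((np.outer(np.diag(G), np.diag(G)) + G**2) / n)
        assert np.all(np.abs(emp - G) < 4 * se)

    def test_assembled_covariances_psd_over_draws(self):
        tm, _ = simulate_factor_truth(25, 5, 2, seed=1)
        Kmat = simulate_kinship(25, seed=2)
        spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=3)
        s = run_mcmc(tm, spec, MCMCConfig(iterations=40, burnin=20, thin=2, seed=3))
        for Gd in s.get("G")[:, 0]:
            assert np.linalg.eigvalsh(Gd).min() >= -1e-8
        for Rd in s.get("R"):
            assert np.linalg.eigvalsh(Rd).min() > 0


class TestFactorRepresentation:
    def test_reproduces_random_pd_targets(self):
        rng = np.random.default_rng(4)
        t = 3
        A = rng.standard_normal((t, 2 * t))
        B = rng.standard_normal((t, 2 * t))
        G, R = A @ A.T / (2 * t), B @ B.T / (2 * t)
        rep = factor_representation([G], R)
        assert rep["Lambda"].shape == (t * 2, t)  # K = t (M + 1)
        G_hat = assemble_covariance(rep["Lambda"], rep["psi_F"][0], rep["psi_R"][0])
        R_hat = assemble_covariance(rep["Lambda"], rep["psi_FE"], rep["psi_RE"])
        assert np.linalg.norm(G_hat - G) < 1e-8
        assert np.linalg.norm(R_hat - R) < 1e-8


class TestGeneticValuesAndImputation:
    @staticmethod
    def _fitted(seed=5, mask_some=False):
        tm, truth = simulate_factor_truth(20, 4, 2, seed=seed)
        if mask_some:
            tm.mask[:5, 0] = False
            tm.values[:5, 0] = np.nan
        Kmat = simulate_kinship(20, seed=seed + 1)
        spec = ModelSpec(terms=[RandomEffectTerm(Kmat=Kmat)], K=2)
        s = run_mcmc(tm, spec, MCMCConfig(iterations=60, burnin=30, thin=2, seed=seed))
        return tm, s

    def test_zero_loadings_genetic_values_reduce_to_U_R(self):
        from factorlmm.posterior import genetic_values

        tm, s = self._fitted()
        st = s.final_state
        st.Lambda = np.zeros_like(st.Lambda)
        u = genetic_values(st, 0)
        assert np.allclose(u, st.cache.from_working(st.U_R))

    def test_single_pathway_genetic_values(self):
        from factorlmm.posterior import genetic_values

        tm, s = self._fitted()
        st = s.final_state
        st.U_R = np.zeros_like(st.U_R)
        u = genetic_values(st, 0)
        assert np.allclose(u, st.cache.from_working(st.U_F @ st.Lambda))

    def test_imputation_shape_and_alignment(self):
        tm, s = self._fitted(mask_some=True)
        imp = s.mean("imputed")
        assert imp.shape == (tm.n, tm.t)
        # imputed surface on the original trait scale: observed-cell residuals small
        obs = tm.mask
        assert np.corrcoef(imp[obs], tm.values[obs])[0, 1] > 0.5

    def test_all_effects_zero_imputation_is_fixed_effects_only(self):
        from factorlmm.posterior import impute_phenotypes

        tm, s = self._fitted()
        st = s.final_state
        st.Lambda[:] = 0.0
        st.U_R[:] = 0.0
        imp = impute_phenotypes(st)
        expected = st.cache.from_working(st.X1w @ st.B1)
        assert np.allclose(imp, expected)


class TestPredictNewLines:
    @staticmethod
    def _samples_and_joint(n_old=15, n_new=3, seed=6):
        K_joint = simulate_kinship(n_old + n_new, seed=seed)
        old_ids = K_joint.ids[:n_old]
        idx = np.arange(n_old)
        K_fit = RelationshipMatrix(
            K_joint.matrix[np.ix_(idx, idx)], ids=list(old_ids), label="K"
        )
        tm, _ = simulate_factor_truth(n_old, 3, 1, K_mats=[K_fit], seed=seed + 1)
        spec = ModelSpec(terms=[RandomEffectTerm(Kmat=K_fit)], K=1)
        s = run_mcmc(tm, spec, MCMCConfig(iterations=60, burnin=30, thin=2, seed=seed))
        return s, K_joint

    def test_duplicated_line_prediction_equals_original(self):
        s, K_joint = self._samples_and_joint()
        Km = K_joint.matrix.copy()
        dup_of = 4
        new = 15  # first "new" line duplicates old line 4's kinship row
        Km[new, :] = Km[dup_of, :]
        Km[:, new] = Km[:, dup_of]
        Km[new, new] = Km[dup_of, dup_of]
        K2 = RelationshipMatrix(Km, ids=K_joint.ids)
        res = predict_new_lines(K2, s)
        u_old_mean = s.mean("genetic_values")
        assert np.allclose(res["mean"][0], u_old_mean[dup_of], atol=1e-5)

    def test_zero_kinship_line_predicts_prior_mean_zero(self):
        s, K_joint = self._samples_and_joint()
        Km = K_joint.matrix.copy()
        new = 16
        Km[new, :15] = 0.0
        Km[:15, new] = 0.0
        K2 = RelationshipMatrix(Km, ids=K_joint.ids)
        res = predict_new_lines(K2, s)
        i = res["new_ids"].index(K_joint.ids[new])
        assert np.allclose(res["mean"][i], 0.0, atol=1e-8)

    def test_invariant_to_new_line_ordering(self):
        s, K_joint = self._samples_and_joint()
        res1 = predict_new_lines(K_joint, s)
        perm = [17, 15, 16]
        ids2 = list(K_joint.ids[:15]) + [K_joint.ids[i] for i in perm]
        order = list(range(15)) + perm
        K2 = RelationshipMatrix(
            K_joint.matrix[np.ix_(order, order)], ids=ids2
        )
        res2 = predict_new_lines(K2, s)
        for i, uid in enumerate(res2["new_ids"]):
            j = res1["new_ids"].index(uid)
            assert np.allclose(res2["mean"][i], res1["mean"][j])

    def test_absent_fitted_line_rejected(self):
        s, K_joint = self._samples_and_joint()
        K_sub = RelationshipMatrix(
            K_joint.matrix[5:, 5:], ids=K_joint.ids[5:]
        )
        with pytest.raises(ValueError, match="absent"):
            predict_new_lines(K_sub, s)


def _dummy_samples(draws: dict) -> PosteriorSamples:
    return PosteriorSamples(
        draws=draws,
        unit_ids=["u0"],
        trait_ids=["y0"],
        scaling=ScalingRecord.identity(["y0"]),
        seed=0,
        config={},
    )


class TestSummaries:
    def test_symmetric_draws_hpd_close_to_equal_tailed(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100_000)
        lo, hi = hpd_interval(x)
        assert abs(lo - (-1.96)) < 0.05 and abs(hi - 1.96) < 0.05

    def test_point_mass_zero_width(self):
        x = np.full(50, 3.14)
        lo, hi = hpd_interval(x)
        assert lo == hi == 3.14

    def test_summarize_requires_draws(self):
        s = _dummy_samples({"x": np.zeros((5, 2))})
        with pytest.raises(ValueError, match="at least 10"):
            summarize(s, "x")
        with pytest.raises(KeyError, match="not stored"):
            summarize(s, "missing_name")

    def test_summary_table_tidy_columns(self):
        rng = np.random.default_rng(8)
        s = _dummy_samples({"x": rng.standard_normal((200, 2, 2))})
        tab = summary_table(s, "x")
        assert list(tab.columns) == [
            "functional", "element", "mean", "sd", "hpd_lo", "hpd_hi", "ess",
        ]
        assert len(tab) == 4


class TestEffectiveSampleSize:
    def test_constant_chain_flagged_undefined(self):
        assert np.isnan(effective_sample_size(np.ones(100)))

    def test_iid_chain_ess_near_length(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(4000)
        ess = effective_sample_size(x)
        assert abs(ess - 4000) / 4000 < 0.15

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.array([1.0, 2.0]))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        s = _dummy_samples({"x": rng.standard_normal((20, 3))})
        path = str(tmp_path / "post.h5")
        s.save(path)
        back = PosteriorSamples.load(path)
        assert np.array_equal(back.get("x"), s.get("x"))
        assert back.unit_ids == s.unit_ids
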