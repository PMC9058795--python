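"""Design compilation and Gibbs sampler: oracles, invariants, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import songnorms as sn
from songnorms.model import (_GibbsState, invwishart_mean, prior_only_design,
                             _sample_invwishart)

from conftest import make_song_frame


class TestChainConfig:
    def test_paper_settings_retain_exactly_1000(self):
        assert sn.retained_samples(sn.ChainConfig(510_000, 10_000, 500)) == 1000
        assert sn.retained_samples(sn.ChainConfig.paper_faithful()) == 1000

    def test_no_burnin_no_thinning(self):
        assert sn.retained_samples(sn.ChainConfig(1000, 0, 1)) == 1000

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            sn.ChainConfig(1000, 1000, 1)  # burn-in consumes everything

    def test_require_inference_floor(self):
        with pytest.raises(ValueError, match="100"):
            sn.ChainConfig(600, 100, 10).require_inference()


class TestBuildDesign:
    def test_order_z_scores(self):
        df = make_song_frame(3, contexts=("male",))
        df["song_order"] = [1, 2, 3]
        design = sn.build_design(df, sn.ModelSpec(responses=("SL",)),
                                 first_recording_only=False)
        col = design.x_columns.index("order")
        np.testing.assert_allclose(design.X[:, col], [-1, 0, 1])

    def test_male_only_data_has_no_context_columns(self):
        df = make_song_frame(20, contexts=("male",))
        design = sn.build_design(df, sn.ModelSpec(responses=("SL",)),
                                 first_recording_only=False)
        assert not any("context" in c for c in design.x_columns)

    def test_default_bivariate_design_has_nine_fixed_columns(
            self, small_bivariate_data):
        songs = small_bivariate_data[0]
        design = sn.build_design(songs, sn.ModelSpec(responses=("SL", "MF")))
        assert len(design.x_columns) == 9
        assert design.x_columns == (
            "intercept", "date", "age", "order", "position",
            "context_female", "context_none",
            "order:context_female", "order:context_none")

    def test_missing_positions_dropped_and_counted(self):
        df = make_song_frame(30)
        df.loc[:4, "position"] = np.nan
        design = sn.build_design(df, sn.ModelSpec(responses=("SL",)),
                                 first_recording_only=False)
        assert design.rows_dropped["missing_values"] == 5
        assert design.n_obs == 25

    def test_unknown_context_rejected(self):
        df = make_song_frame(10)
        df.loc[0, "context"] = "juvenile"
        with pytest.raises(ValueError, match="juvenile"):
            sn.build_design(df, sn.ModelSpec(responses=("SL",)))

    def test_sparse_context_block_dropped_with_warning(self):
        df = make_song_frame(21, contexts=("male",))
        df.loc[20, "context"] = "female"  # a single female individual
        with pytest.warns(UserWarning, match="female"):
            design = sn.build_design(df, sn.ModelSpec(responses=("SL",)),
                                     first_recording_only=False)
        assert design.contexts == ("male",)
        assert (design.ind_index == -1).sum() == 1

    def test_first_recording_kept_by_default(self, small_bivariate_data):
        songs = small_bivariate_data[0]
        design = sn.build_design(songs, sn.ModelSpec(responses=("SL",)))
        assert design.rows_dropped["later_recordings"] > 0

    def test_z_block_sparse_structure(self):
        df = make_song_frame(12, contexts=("male",))
        design = sn.build_design(df, sn.ModelSpec(responses=("SL",)),
                                 first_recording_only=False)
        z = design.z_block("male", "intercept")
        assert z.shape == (12, 12)
        assert z.sum() == pytest.approx(12.0)


class ZeroNoise:
    """Stand-in RNG: zero noise makes a location draw equal its mean."""

    def standard_normal(self, size=None):
        return np.zeros(size) if size is not None else 0.0


class TestJointLocationUpdate:
    def test_matches_dense_normal_equations(self):
        """The Schur-complement joint draw with zero noise equals the exact
        conditional posterior mean from densely assembled mixed-model
        equations (fixed + year + all individual blocks, bivariate)."""
        rng = np.random.default_rng(3)
        n, n_ind = 120, 12
        ind = rng.integers(0, n_ind, n)
        df = make_song_frame(n, seed=3)
        df["individual_id"] = [f"b{i:02d}" for i in ind]
        df["context"] = [sn.CONTEXTS[i % 3] for i in ind]
        df["song_order"] = rng.integers(1, 20, n)
        spec = sn.ModelSpec(responses=("SL", "MF"))
        design = sn.build_design(df, spec, first_recording_only=False)
        state = _GibbsState(design, spec, ZeroNoise())
        a_mat = rng.normal(size=(6, 6))
        g0 = a_mat @ a_mat.T / 6 + 0.5 * np.eye(6)
        for c in design.contexts:
            state.G[c] = g0.copy()
        state.R = np.array([[1.0, 0.3], [0.3, 0.8]])
        state.V_year = np.array([[0.5, 0.1], [0.1, 0.4]])
        rinv = np.linalg.inv(state.R)
        state.update_locations(rinv)

        # dense oracle
        T, p = 2, design.X.shape[1]
        n_years = design.n_years
        q_e = p + n_years + 3 * design.n_individuals
        w_full = np.zeros((n * T, q_e * T))
        wd = np.zeros((n, p + n_years))
        wd[:, :p] = design.X
        wd[np.arange(n), p + design.year_index] = 1.0
        for i in range(n):
            for col_e in range(p + n_years):
                for t in range(T):
                    w_full[i * T + t, col_e * T + t] = wd[i, col_e]
            j = design.ind_index[i]
            for ee in range(3):
                for t in range(T):
                    col = (p + n_years) * T + j * 6 + ee * T + t
                    w_full[i * T + t, col] = design.U[i, ee]
        prior_prec = np.zeros((q_e * T, q_e * T))
        prior_prec[:p * T, :p * T] = np.eye(p * T) / 1e8
        vy_inv = np.linalg.inv(state.V_year)
        for yb in range(n_years):
            s = p * T + yb * T
            prior_prec[s:s + T, s:s + T] = vy_inv
        ginv = np.linalg.inv(g0)
        for j in range(design.n_individuals):
            s = (p + n_years) * T + j * 6
            prior_prec[s:s + 6, s:s + 6] = ginv
        rinv_full = np.kron(np.eye(n), rinv)
        q_mat = w_full.T @ rinv_full @ w_full + prior_prec
        theta = np.linalg.solve(q_mat, w_full.T @ rinv_full @ design.Y.reshape(-1))
        f_dense = theta[:(p + n_years) * T].reshape(p + n_years, T)
        a_dense = theta[(p + n_years) * T:].reshape(design.n_individuals, 3, T)
        np.testing.assert_allclose(state.beta, f_dense[:p], atol=1e-10)
        np.testing.assert_allclose(state.year_eff, f_dense[p:], atol=1e-10)
        np.testing.assert_allclose(state.A_ind, a_dense, atol=1e-10)


class TestConjugateOracles:
    def test_posterior_mean_equals_gls_with_fixed_residual(self):
        """No random blocks, known residual covariance, flat coefficient
        prior: the sampler's posterior is exactly the GLS normal posterior."""
        rng = np.random.default_rng(42)
        df = make_song_frame(100, seed=42)
        r_fix = np.array([[1.0, 0.4], [0.4, 1.5]])
        spec = sn.ModelSpec(
            responses=("SL", "MF"), include_year=False, include_individual=False,
            prior=sn.PriorConfig(beta_prior_var=None),
            fix_residual=tuple(map(tuple, r_fix)))
        design = sn.build_design(df, spec, first_recording_only=False)
        draws = sn.gibbs_sample(design, spec, sn.ChainConfig(2000, 0, 1, seed=7),
                                compute_log_posterior=False)
        rinv = np.linalg.inv(r_fix)
        q = np.kron(design.X.T @ design.X, rinv)
        gls = np.linalg.solve(q, (design.X.T @ design.Y @ rinv).reshape(-1)
                              ).reshape(design.X.shape[1], 2)
        mcse = np.sqrt(np.diag(np.linalg.inv(q)).reshape(-1, 2) / 2000)
        z = (draws.beta.mean(axis=(0, 1)) - gls) / mcse
        assert np.abs(z).max() < 3.0

    def test_no_data_limit_reproduces_prior_moments(self):
        """Zero observations: covariance draws match analytic IW moments."""
        spec = sn.ModelSpec(responses=("SL",), prior=sn.PriorConfig(
            family="inverse_wishart", g_df=3 + 6, r_df=1 + 6))
        design = prior_only_design(spec, {"male": 2}, n_years=0)
        draws = sn.gibbs_sample(design, spec, sn.ChainConfig(8000, 0, 1, seed=5),
                                compute_log_posterior=False)
        analytic = invwishart_mean(np.eye(3), 9)
        emp = draws.G["male"].mean(axis=(0, 1))
        assert np.abs(np.diag(emp) - np.diag(analytic)).max() < 0.15 * analytic[0, 0]
        r_emp = draws.R.mean()
        assert abs(r_emp - invwishart_mean(np.eye(1), 7)[0, 0]) < 0.03


class TestSamplerInvariants:
    def test_covariance_draws_are_pd_and_correlations_bounded(
            self, small_univariate_fit):
        _, _, _, draws = small_univariate_fit
        for ctx, g in draws.G.items():
            flat = g.reshape(-1, g.shape[-1], g.shape[-1])
            ev = np.linalg.eigvalsh(flat)
            assert (ev > 0).all()
            d = np.sqrt(flat[:, np.arange(3), np.arange(3)])
            corr = flat / (d[:, :, None] * d[:, None, :])
            assert (np.abs(corr) <= 1 + 1e-10).all()
        assert (draws.R.reshape(-1) > 0).all()

    def test_retained_count_matches_config(self, small_univariate_fit):
        _, _, chains, draws = small_univariate_fit
        assert draws.n_draws == chains.retained

    def test_prior_families_agree_qualitatively(self, small_bivariate_data):
        """Parameter-expanded and inverse-Wishart priors give overlapping 95%
        CIs for the male-context order-slope variance on the same data."""
        songs = small_bivariate_data[0]
        chains = sn.ChainConfig(2500, 500, 4, n_chains=1, seed=11)
        cis = []
        for family in ("parameter_expanded", "inverse_wishart"):
            spec = sn.ModelSpec(responses=("SL",),
                                prior=sn.PriorConfig(family=family))
            design = sn.build_design(songs, spec)
            draws = sn.gibbs_sample(design, spec, chains,
                                    compute_log_posterior=False)
            cis.append(sn.credible_interval(
                draws.g_draws("male", "order", "SL")))
        (lo1, hi1), (lo2, hi2) = cis
        assert max(lo1, lo2) < min(hi1, hi2)  # intervals overlap

    def test_log_posterior_is_finite(self, small_univariate_fit):
        _, _, _, draws = small_univariate_fit
        assert np.isfinite(draws.log_posterior).all()

    def test_invwishart_sampler_moments(self):
        """Bartlett-based IW draws match analytic mean (independent check of
        the conjugate building block)."""
        rng = np.random.default_rng(0)
        scale = np.array([[2.0, 0.3], [0.3, 1.0]])
        df = 10.0
        draws = np.stack([_sample_invwishart(scale, df, rng)
                          for _ in range(4000)])
        np.testing.assert_allclose(draws.mean(axis=0),
                                   invwishart_mean(scale, df), rtol=0.1)


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 10_000))
        assert sn.gelman_rubin(chains).iloc[0] < 1.01

    def test_disjoint_chains_diverge(self):
        chains = np.stack([np.random.default_rng(2).normal(0, 1, 1000),
                           np.random.default_rng(3).normal(50, 1, 1000)])
        assert sn.gelman_rubin(chains).iloc[0] > 1.5

    def test_duplicated_chain_near_one(self):
        x = np.random.default_rng(4).normal(size=1000)
        assert sn.gelman_rubin(np.stack([x, x])).iloc[0] < 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="n_chains"):
            sn.gelman_rubin(np.zeros((1, 100)))

    def test_posterior_draws_interface(self, small_univariate_fit):
        _, _, _, draws = small_univariate_fit
        rh = sn.gelman_rubin(draws)
        assert len(rh) > 10
        assert np.isfinite(rh).all()
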