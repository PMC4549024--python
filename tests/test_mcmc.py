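"""Gibbs sampler: conjugate oracles, prior machinery, diagnostics."""

import numpy as np
import pytest
from scipy import stats

import addomgs as A
from addomgs.mcmc import MCMC_METHODS


def _toy_data(seed=0, n=5, m=3):
    """Tiny instance with centered W/S columns and known generating model."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 3, size=(n, m)).astype(float)
    while np.any((x.mean(0) <= 0) | (x.mean(0) >= 2)):
        x = rng.integers(0, 3, size=(n, m)).astype(float)
    p = x.mean(axis=0) / 2
    W = A.code_additive(x, p)
    S = A.code_dominance(x, p)
    y = 2.0 + W @ rng.normal(0, 1, m) + rng.normal(0, 0.5, n)
    return y, W, S, p


class TestConjugateOracles:
    def test_single_marker_matches_closed_form_ridge_posterior(self):
        # fixed marker variance + (effectively) fixed sigma_e2: the
        # posterior mean of m_a has the conjugate-normal closed form
        rng = np.random.default_rng(1)
        n = 40
        x = rng.integers(0, 3, size=(n, 1)).astype(float)
        p = x.mean(axis=0) / 2
        W = A.code_additive(x, p)      # centered: orthogonal to intercept
        S = np.zeros((n, 1))
        y = 1.5 + W[:, 0] * 0.8 + rng.normal(0, 0.6, n)
        se2, tau2 = 0.36, 0.5
        m_closed = (W[:, 0] @ y / se2) / (W[:, 0] @ W[:, 0] / se2 + 1.0 / tau2)
        cfg = A.model_config(
            "rr-het(-2,-2)", df1=1e8, scale_e=se2,
            fixed_ta=np.array([tau2]), fixed_td=np.array([1e-8]),
            n_iter=60_000, burn_in=5_000, thin=2, seed=3,
        )
        chain = A.gibbs_run(y, W, S, cfg, p)
        assert chain.mean_ma[0] == pytest.approx(m_closed, abs=0.02)

    def test_stationary_mean_matches_joint_ridge_solution(self):
        # 5 individuals x 3 markers, fixed hyperparameters: long-run Gibbs
        # mean of (m_a, m_d) equals the analytic normal conditional mean
        y, W, S, p = _toy_data(seed=2)
        se2 = 0.25
        ta2 = np.full(3, 0.8)
        td2 = np.full(3, 0.3)
        _, ma_exact, md_exact = A.solve_marker_mme(y, W, S, ta2, td2, se2)
        cfg = A.model_config(
            "rr-het(-2,-2)", df1=1e9, scale_e=se2,
            fixed_ta=ta2, fixed_td=td2,
            n_iter=400_000, burn_in=10_000, thin=1, seed=4,
        )
        chain = A.gibbs_run(y, W, S, cfg, p)
        assert np.allclose(chain.mean_ma, ma_exact, atol=1.5e-2)
        assert np.allclose(chain.mean_md, md_exact, atol=1.5e-2)

    def test_null_data_yields_negligible_heritability(self, medium_coding):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, medium_coding.W.shape[0])
        cfg = A.model_config("bayesa*b*(-2,8)", n_iter=6000, burn_in=1000,
                             thin=5, seed=6)
        chain = A.gibbs_run(y, medium_coding.W, medium_coding.S, cfg,
                            medium_coding.p)
        s = A.posterior_summary(chain)
        assert s.h2a < 0.1
        assert s.h2d < 0.1

    def test_seed_determinism(self):
        y, W, S, p = _toy_data(seed=7)
        cfg = A.model_config("iblasso(4,2)", n_iter=2000, burn_in=500,
                             thin=5, seed=11)
        c1 = A.gibbs_run(y, W, S, cfg, p)
        c2 = A.gibbs_run(y, W, S, cfg, p)
        assert np.array_equal(c1.sigma_e2, c2.sigma_e2)
        assert np.array_equal(c1.mean_ma, c2.mean_ma)
        c3 = A.gibbs_run(y, W, S, A.model_config("iblasso(4,2)", n_iter=2000,
                                                 burn_in=500, thin=5, seed=12), p)
        assert not np.array_equal(c1.sigma_e2, c3.sigma_e2)


class TestPriorMachinery:
    def test_method_registry_matches_design(self):
        assert len(MCMC_METHODS) == 8
        assert A.model_config("BAYESA*B* (-2,8)").df1 == -2
        assert A.model_config("BAYESA*B* (-2,8)").df2 == 8
        assert A.model_config("IBLASSO (4,-2)").df1 == 4
        cfg = A.model_config("BRR (-2,-2)")
        assert cfg.n_retained == 10_000  # (120k - 20k) / 10

    @pytest.mark.parametrize(
        "method,family",
        [
            ("brr(-2,-2)", "normal"),
            ("iblasso(4,-2)", "laplace"),
            ("blasso(4,2)", "laplace"),
            ("bayesa*b*(4,6)", "student-t"),
            ("rr-het(-2,-2)", "normal"),
        ],
    )
    def test_prior_families(self, method, family):
        assert A.prior_for(method)["family"] == family

    def test_t_prior_df_matches_table(self):
        assert A.prior_for("bayesa*b*(4,6)")["df"] == 6
        assert A.prior_for("bayesa*b*(-2,8)")["df"] == 8

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            A.prior_for("bayesc")
        with pytest.raises(ValueError):
            A.model_config("bayesc")

    def test_t_prior_converges_to_normal_at_large_df(self):
        # the t-BLASSO prior family tends to the ridge (normal) prior
        big = A.sample_prior_effects("bayesa*b*(-2,8)", 50_000, df2=1e6, seed=8)
        ks = stats.kstest(big, "norm").statistic
        assert ks < 0.02
        # ... while at df = 6 the tails are visibly heavier than normal
        t6 = A.sample_prior_effects("bayesa*b*(4,6)", 50_000, seed=9)
        assert stats.kurtosis(t6) > 1.0


class TestRRHET:
    def test_variances_require_iblasso_source(self):
        y, W, S, p = _toy_data(seed=10)
        cfg = A.model_config("brr(-2,-2)", n_iter=1000, burn_in=200, thin=2, seed=1)
        chain = A.gibbs_run(y, W, S, cfg, p)
        with pytest.raises(ValueError):
            A.rr_het_variances(chain)

    def test_mismatched_locus_count_rejected(self):
        y, W, S, p = _toy_data(seed=11)
        cfg = A.model_config("rr-het(-2,-2)", fixed_ta=np.ones(5),
                             fixed_td=np.ones(3), n_iter=500, burn_in=100,
                             thin=2, seed=1)
        with pytest.raises(ValueError):
            A.gibbs_run(y, W, S, cfg, p)

    def test_equal_variances_reduce_to_homogeneous_ridge(self):
        # deterministic check on the shrinkage algebra
        y, W, S, p = _toy_data(seed=12, n=30, m=6)
        tau2 = 0.7
        _, ma_het, _ = A.solve_marker_mme(y, W, S, np.full(6, tau2),
                                          np.full(6, 0.2), 0.5)
        _, ma_hom, _ = A.solve_marker_mme(y, W, S, tau2, 0.2, 0.5)
        assert np.allclose(ma_het, ma_hom)

    def test_scale_invariance_of_shrinkage(self):
        y, W, S, p = _toy_data(seed=13, n=30, m=6)
        ta, td, se = np.full(6, 0.7), np.full(6, 0.2), 0.5
        _, ma1, md1 = A.solve_marker_mme(y, W, S, ta, td, se)
        _, ma2, md2 = A.solve_marker_mme(y, W, S, 2 * ta, 2 * td, 2 * se)
        assert np.allclose(ma1, ma2)
        assert np.allclose(md1, md2)

    def test_iblasso_variances_flag_major_genes(self, medium_map):
        # architecture learning: per-locus variances from IBLASSO(4,-2)
        # are systematically larger at the five major QTL
        ds = A.simulate_dataset(gmap=medium_map, architecture="major_genes",
                                pop_size=500, n_families=10, family_size=40,
                                n_parents=20, seed=31)
        c = A.build_coding(ds.dosages)
        cfg = A.model_config("iblasso(4,-2)", n_iter=8000, burn_in=2000,
                             thin=5, seed=32)
        chain = A.gibbs_run(ds.y, c.W, c.S, cfg, c.p)
        Da, _ = A.rr_het_variances(chain)
        major_loci = ds.trait.qtl_indices[ds.trait.major_indices]
        above_median = np.sum(Da[major_loci] > np.median(Da))
        assert above_median >= 4


class TestGeweke:
    def test_null_calibration(self):
        rng = np.random.default_rng(14)
        chains = rng.normal(0, 1, size=(10_000, 100))
        z = A.geweke(chains)
        assert np.mean(np.abs(z) < 3) >= 0.98

    def test_detects_mean_shift(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 10_000)
        x[5000:] += 1.5
        assert abs(A.geweke(x)) > 3

    def test_constant_chain_rejected(self):
        with pytest.raises(ValueError):
            A.geweke(np.ones(5000))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            A.geweke(np.arange(50.0))


class TestSummaries:
    def test_identical_samples_have_zero_sd(self):
        cfg = A.model_config("brr(-2,-2)", n_iter=200, burn_in=100, thin=10)
        chain = A.MCMCChain(
            config=cfg,
            sigma_e2=np.full(10, 1.0), sigma_a2=np.full(10, 2.0),
            sigma_d2=np.full(10, 0.5), mean_ma=np.zeros(3),
            mean_md=np.zeros(3), mean_ta2=np.ones(3), mean_td2=np.ones(3),
            p=np.full(3, 0.5),
        )
        s = A.posterior_summary(chain)
        assert s.sd_sigma_a2 == 0.0
        assert s.h2a == pytest.approx(2.0 / 3.5)
        assert s.vd_va == pytest.approx(0.25)

    def test_h2_identity_holds_per_sample(self):
        y, W, S, p = _toy_data(seed=16, n=20, m=4)
        cfg = A.model_config("brr(-2,-2)", n_iter=2000, burn_in=500, thin=5, seed=2)
        chain = A.gibbs_run(y, W, S, cfg, p)
        assert np.allclose(
            chain.h2a,
            chain.sigma_a2 / (chain.sigma_a2 + chain.sigma_d2 + chain.sigma_e2),
        )
        assert np.all(chain.sigma_e2 > 0)
        assert chain.n_retained == cfg.n_retained

    def test_invalid_iteration_counts_rejected(self):
        y, W, S, p = _toy_data(seed=17)
        cfg = A.model_config("brr(-2,-2)", n_iter=100, burn_in=200)
        with pytest.raises(ValueError):
            A.gibbs_run(y, W, S, cfg, p)

    def test_store_effects_chains(self):
        y, W, S, p = _toy_data(seed=18, n=20, m=4)
        cfg = A.model_config("bayesa*b*(-2,6)", n_iter=1000, burn_in=500,
                             thin=5, seed=3, store_effects=True)
        chain = A.gibbs_run(y, W, S, cfg, p)
        assert chain.ma_samples.shape == (cfg.n_retained, 4)
        assert np.allclose(chain.ma_samples.mean(axis=0), chain.mean_ma)
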