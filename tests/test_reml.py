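import numpy as np
import pytest
from scipy import stats

from mppqei.covstruct import IDScale, Unstructured
from mppqei.kernels import BlockedKernel, DenseKernel
from mppqei.qtl_design import build_design
from mppqei.reml import (DesignTerm, PolygenicTerm, ResidualTerm, VarianceModel,
                         aic, background_model, blup_effects, build_qtl_term,
                         kinship_from_ibd, loglik_dense_oracle,
                         lrt_mixture_pvalue, reml_fit)
from mppqei.simulate import TrueQTL
from tests.conftest import make_diallel_sim

POLY_STRUCTS = [(m, p) for m in ("id", "idh", "us") for p in ("id", "idh", "kin")]


def _rand_theta(model, rng, scale=1.0):
    theta = []
    for t in model.terms:
        if isinstance(t, PolygenicTerm):
            th_met = t.met.init(scale * rng.uniform(0.5, 1.5))
            if isinstance(t.met, Unstructured):
                th_met += 0.1 * rng.standard_normal(len(th_met))
            theta.append(th_met)
            if t.mpp_kind == "idh":
                theta.append(rng.uniform(0.5, 2.0, t.n_fam - 1))
        else:
            theta.append(rng.uniform(0.2, 1.5, t.n_params) * scale)
    return np.concatenate(theta)


class TestClosedForms:
    def test_residual_only_equals_unbiased_variance(self):
        # fixed-effects model with ID residual: REML variance is RSS/(N-p)
        rng = np.random.default_rng(0)
        N, p = 60, 3
        X = np.column_stack([np.ones(N), rng.standard_normal((N, p - 1))])
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.standard_normal(N) * 1.7
        env = np.zeros(N, dtype=int)
        model = VarianceModel(X, [ResidualTerm(env, kind="id")])
        fit = reml_fit(model, y)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        assert fit.converged
        assert fit.theta[0] == pytest.approx(rss / (N - p), rel=1e-6)

    def test_one_way_random_matches_anova_reml(self):
        # balanced one-way random model: ANOVA estimators are REML
        rng = np.random.default_rng(1)
        k, n = 12, 8
        b = rng.standard_normal(k) * 1.5
        y = np.repeat(b, n) + rng.standard_normal(k * n) * 0.9
        N = k * n
        X = np.ones((N, 1))
        Z = np.kron(np.eye(k), np.ones((n, 1)))
        model = VarianceModel(X, [
            DesignTerm("group", Z, IDScale(k)),
            ResidualTerm(np.zeros(N, dtype=int), kind="id"),
        ])
        fit = reml_fit(model, y)
        gm = y.reshape(k, n).mean(axis=1)
        msb = n * np.sum((gm - gm.mean()) ** 2) / (k - 1)
        msw = np.sum((y.reshape(k, n) - gm[:, None]) ** 2) / (k * (n - 1))
        assert fit.converged
        assert fit.theta[1] == pytest.approx(msw, rel=1e-5)
        assert fit.theta[0] == pytest.approx(max((msb - msw) / n, 0.0), rel=1e-4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("met,mpp", POLY_STRUCTS)
    def test_polygenic_structures_match_oracle(self, met, mpp):
        sim = make_diallel_sim(seed=50, n_per_family=8, grid_step=25.0)
        kin = kinship_from_ibd(sim.ibd) if mpp == "kin" else None
        model = background_model(sim.obs, sim.ibd, polygenic=(met, mpp),
                                 kinship=kin)
        rng = np.random.default_rng(hash((met, mpp)) % 2 ** 31)
        for _ in range(2):
            theta = _rand_theta(model, rng)
            kernel = DenseKernel(model, sim.obs.y)
            ll = kernel.evaluate(theta, derivs=False).loglik
            ll_o = loglik_dense_oracle(model, sim.obs.y, theta)
            assert ll == pytest.approx(ll_o, abs=1e-6)

    @pytest.mark.parametrize("effect_type", ["ecfc", "esfc", "ecfs", "esfs"])
    def test_qtl_structures_match_oracle(self, effect_type):
        sim = make_diallel_sim(seed=51, n_per_family=8, grid_step=25.0)
        dz = build_design(sim.ibd, sim.obs, grid_index=1, effect_type=effect_type)
        model = background_model(sim.obs, sim.ibd, polygenic=("us", "idh"),
                                 qtl_terms=[build_qtl_term(dz, name="q")])
        rng = np.random.default_rng(52)
        theta = _rand_theta(model, rng)
        kernel = DenseKernel(model, sim.obs.y)
        ll = kernel.evaluate(theta, derivs=False).loglik
        assert ll == pytest.approx(loglik_dense_oracle(model, sim.obs.y, theta),
                                   abs=1e-6)

    @pytest.mark.parametrize("met", ["id", "idh", "us"])
    def test_blocked_kernel_equals_dense(self, met):
        sim = make_diallel_sim(seed=53, n_per_family=10, grid_step=50.0)
        model = background_model(sim.obs, sim.ibd, polygenic=(met, "idh"))
        rng = np.random.default_rng(54)
        theta = _rand_theta(model, rng)
        d = DenseKernel(model, sim.obs.y).evaluate(theta)
        b = BlockedKernel(model, sim.obs.y).evaluate(theta)
        assert b.loglik == pytest.approx(d.loglik, abs=1e-8)
        np.testing.assert_allclose(b.score, d.score, atol=1e-6)
        np.testing.assert_allclose(b.ai, d.ai, atol=1e-6, rtol=1e-6)
        np.testing.assert_allclose(b.Py, d.Py, atol=1e-8)

    def test_zero_variance_term_leaves_likelihood_unchanged(self):
        sim = make_diallel_sim(seed=55, n_per_family=8, grid_step=50.0)
        dz = build_design(sim.ibd, sim.obs, grid_index=0, effect_type="ecfc")
        base = background_model(sim.obs, sim.ibd, polygenic=("idh", "id"))
        ext = background_model(sim.obs, sim.ibd, polygenic=("idh", "id"),
                               qtl_terms=[build_qtl_term(dz, name="q")])
        rng = np.random.default_rng(56)
        th = _rand_theta(base, rng)
        ll0 = DenseKernel(base, sim.obs.y).evaluate(th, derivs=False).loglik
        ll1 = DenseKernel(ext, sim.obs.y).evaluate(
            np.concatenate([[0.0], th]), derivs=False).loglik
        assert ll1 == pytest.approx(ll0, abs=1e-9)

    def test_permutation_invariance(self):
        sim = make_diallel_sim(seed=57, n_per_family=8, grid_step=50.0)
        model = background_model(sim.obs, sim.ibd, polygenic=("us", "idh"))
        fit = reml_fit(model, sim.obs.y)
        rng = np.random.default_rng(58)
        perm = rng.permutation(sim.obs.n_obs)
        poly, resid = model.terms
        model_p = VarianceModel(model.X[perm], [
            PolygenicTerm(poly.met, poly.mpp_kind, poly.env_idx[perm],
                          poly.geno_idx[perm], poly.fam_code, poly.n_fam),
            ResidualTerm(resid.env_idx[perm], kind=resid.kind),
        ])
        fit_p = reml_fit(model_p, sim.obs.y[perm])
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-6)
        np.testing.assert_allclose(fit_p.theta, fit.theta, atol=1e-4, rtol=1e-3)


class TestMixtureLRT:
    def test_boundary_mass(self):
        T, p = lrt_mixture_pvalue(-100.0, -100.0)
        assert T == 0.0 and p == 1.0

    def test_quantile_value(self):
        # 3.841459 is the 0.95 quantile of chi2_1: p = 0.5 * 0.05
        T, p = lrt_mixture_pvalue(-98.0792705, -100.0)
        assert p == pytest.approx(0.025, abs=1e-6)

    def test_large_statistic(self):
        T, p = lrt_mixture_pvalue(-95.0, -100.0)
        assert T == 10.0
        assert p == pytest.approx(0.5 * stats.chi2.sf(10.0, 1), rel=1e-10)

    def test_negative_statistic_warns_and_clamps(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            T, p = lrt_mixture_pvalue(-100.5, -100.0)
        assert T == 0.0 and p == 1.0

    def test_multi_df_mixture_option(self):
        T, p = lrt_mixture_pvalue(-97.0, -100.0, df=2, mixture="half_df")
        expected = 0.5 * (stats.chi2.sf(6.0, 1) + stats.chi2.sf(6.0, 2))
        assert p == pytest.approx(expected, rel=1e-10)


class TestAICAndBlups:
    def test_aic_counts_variance_parameters(self):
        sim = make_diallel_sim(seed=60, n_per_family=6, grid_step=50.0)
        m1 = background_model(sim.obs, sim.ibd, polygenic=("id", "id"),
                              residual="id")      # 2 params
        m2 = background_model(sim.obs, sim.ibd, polygenic=("us", "idh"))  # 8
        f1 = reml_fit(m1, sim.obs.y)
        f2 = reml_fit(m2, sim.obs.y)
        assert aic(f1) == pytest.approx(-2 * f1.loglik + 2 * 2)
        assert aic(f2) == pytest.approx(-2 * f2.loglik + 2 * 8)

    def test_zero_variance_gives_zero_blups(self):
        sim = make_diallel_sim(seed=61, n_per_family=8, grid_step=50.0)
        dz = build_design(sim.ibd, sim.obs, grid_index=0, effect_type="ecfc")
        model = background_model(sim.obs, sim.ibd, polygenic=("idh", "id"),
                                 qtl_terms=[build_qtl_term(dz, name="q")])
        fit = reml_fit(model, sim.obs.y)
        fit.theta[:1] = 0.0  # force the QTL variance to the boundary
        state = DenseKernel(model, sim.obs.y).evaluate(fit.theta, derivs=False)
        fit2 = type(fit)(model, fit.theta, state.loglik, state.beta, state.Py,
                         True, 1, 1, "dense")
        blups = blup_effects(fit2, "q")
        assert np.allclose(blups["blup"], 0.0)

    def test_blups_recover_simulated_contrasts_noise_free(self):
        effects = np.array([2.0, -2.0, 1.0, -1.0])
        sim = make_diallel_sim(seed=62, n_per_family=25,
                               qtls=[TrueQTL("1", 50.0, "ecfc", effects=effects)],
                               polygenic=None, residual=(1e-4, 1e-4))
        gi = sim.ibd.grid.index_of("1", 50.0)
        dz = build_design(sim.ibd, sim.obs, grid_index=gi, effect_type="ecfc")
        model = background_model(sim.obs, sim.ibd, polygenic=("id", "id"),
                                 residual="id",
                                 qtl_terms=[build_qtl_term(dz, name="q")])
        fit = reml_fit(model, sim.obs.y)
        blups = blup_effects(fit, "q")["blup"].to_numpy()
        # family-by-env means absorb per-family averages: compare contrasts
        # within the crossing structure, A-vs-C etc.; the A-B and C-D
        # contrasts are estimable
        assert blups[0] - blups[1] == pytest.approx(4.0, abs=0.2)
        assert blups[2] - blups[3] == pytest.approx(2.0, abs=0.2)


class TestKinship:
    def test_identical_mosaics_share_diagonal_entry(self):
        sim = make_diallel_sim(seed=63, n_per_family=5, grid_step=25.0)
        ibd = sim.ibd
        ibd.pi[1] = ibd.pi[0]
        K = kinship_from_ibd(ibd)
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_disjoint_families_are_unrelated(self):
        # lines from A-x-C and B-x-D share no founders: kinship 0
        sim = make_diallel_sim(seed=64, n_per_family=5, grid_step=25.0)
        fams = sim.obs.table.groupby("genotype", sort=False)["family"].first()
        g_ac = sim.ibd.genotypes.index(fams[fams == "AxC"].index[0])
        g_bd = sim.ibd.genotypes.index(fams[fams == "BxD"].index[0])
        K = kinship_from_ibd(sim.ibd)
        assert K[g_ac, g_bd] == pytest.approx(0.0, abs=1e-12)
        assert K[g_ac, g_ac] == pytest.approx(2.0, abs=1e-9)

    def test_kinship_is_psd(self):
        for seed in range(10):
            sim = make_diallel_sim(seed=seed, n_per_family=4, grid_step=25.0)
            K = kinship_from_ibd(sim.ibd)
            assert np.linalg.eigvalsh(K).min() >= -1e-10
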