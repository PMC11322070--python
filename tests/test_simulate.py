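import numpy as np
import pytest

from mppqei.core_data import GeneticMap, PopulationDesign, build_grid
from mppqei.simulate import (ChromosomeMosaic, PolygenicSpec, SimulationConfig,
                             TrueQTL, mosaics_to_ibd, simulate_dataset,
                             simulate_meiosis, simulate_population)
from tests.conftest import make_diallel_sim


def _uniform_hom(length, code):
    return ChromosomeMosaic(np.array([length]), np.array([code]))


class TestMeiosis:
    def test_identical_homologs_give_identical_gamete(self):
        rng = np.random.default_rng(0)
        a = _uniform_hom(120.0, 3)
        for _ in range(20):
            g = simulate_meiosis(a, a, rng)
            assert np.all(g.founders == 3)
            assert g.length == 120.0

    def test_zero_length_chromosome_never_recombines(self):
        rng = np.random.default_rng(1)
        a = _uniform_hom(1e-12, 0)
        b = _uniform_hom(1e-12, 1)
        for _ in range(50):
            g = simulate_meiosis(a, b, rng)
            assert len(g.founders) == 1

    def test_crossover_count_matches_poisson_mean(self):
        # 100 cM -> Poisson(1): mean segment-switch count ~1 over many meioses
        rng = np.random.default_rng(2)
        a = _uniform_hom(100.0, 0)
        b = _uniform_hom(100.0, 1)
        n = 4000
        switches = []
        for _ in range(n):
            g = simulate_meiosis(a, b, rng)
            switches.append(len(g.founders) - 1)
        # observable switches are crossovers minus even-cancellations; compare
        # against the Monte-Carlo expectation of the same functional computed
        # from raw Poisson draws with alternating strands
        mean = np.mean(switches)
        se = np.std(switches) / np.sqrt(n)
        # analytic: switch count equals crossover count for 2 distinct strands
        assert abs(mean - 1.0) < 3 * max(se, 0.02)

    def test_gamete_tiles_chromosome(self):
        rng = np.random.default_rng(3)
        a = ChromosomeMosaic(np.array([30.0, 100.0]), np.array([0, 1]))
        b = ChromosomeMosaic(np.array([50.0, 100.0]), np.array([2, 3]))
        for _ in range(50):
            g = simulate_meiosis(a, b, rng)
            assert g.ends[-1] == 100.0
            assert np.all(np.diff(g.ends) > 0)
            assert set(g.founders) <= {0, 1, 2, 3}


class TestPopulations:
    def test_dh_lines_are_homozygous_with_family_founders(self, small_map, diallel_design):
        rng = np.random.default_rng(4)
        genos, fam_of, mos = simulate_population(diallel_design, small_map, 5, rng)
        assert len(genos) == 20
        for g in genos:
            fam = fam_of[g]
            codes = {diallel_design.parents.index(p)
                     for p in diallel_design.family_parents(fam)}
            for hom1, hom2 in mos[g].values():
                assert np.array_equal(hom1.ends, hom2.ends)
                assert np.array_equal(hom1.founders, hom2.founders)
                assert set(hom1.founders) <= codes

    def test_nam_families_contain_only_their_parents(self, small_map):
        design = PopulationDesign.nam("C0", ["P1", "P2", "P3"])
        rng = np.random.default_rng(5)
        genos, fam_of, mos = simulate_population(design, small_map, 4, rng)
        for g in genos:
            fam_parents = design.family_parents(fam_of[g])
            codes = {design.parents.index(p) for p in fam_parents}
            for hom1, hom2 in mos[g].values():
                assert set(hom1.founders) | set(hom2.founders) <= codes

    def test_magic_founder_shares_are_symmetric(self):
        founders = [f"F{i:02d}" for i in range(16)]
        design = PopulationDesign.magic_funnel(founders, selfing_generations=4)
        gmap = GeneticMap.from_rows([("1", 0.0), ("1", 100.0)])
        rng = np.random.default_rng(6)
        n = 300
        genos, fam_of, mos = simulate_population(design, gmap, n, rng)
        grid = build_grid(gmap, 10.0)
        ibd = mosaics_to_ibd(genos, fam_of, mos, design, grid)
        shares = ibd.pi.mean(axis=(0, 1)) / 2.0
        # each founder's genome-wide expected share is 1/16
        se = np.sqrt((1 / 16) * (15 / 16) / (n * 2))  # conservative
        assert np.all(np.abs(shares - 1 / 16) < 4 * se + 0.01)

    def test_magic_requires_power_of_two(self, small_map):
        design = PopulationDesign.magic_funnel([f"F{i}" for i in range(6)])
        with pytest.raises(ValueError, match="power-of-two"):
            simulate_population(design, small_map, 2, np.random.default_rng(0))


class TestIBD:
    def test_blur_limits(self, small_map, diallel_design):
        rng = np.random.default_rng(7)
        genos, fam_of, mos = simulate_population(diallel_design, small_map, 3, rng)
        grid = build_grid(small_map, 20.0)
        exact = mosaics_to_ibd(genos, fam_of, mos, diallel_design, grid, blur=0.0)
        assert set(np.unique(exact.pi)) <= {0.0, 1.0, 2.0}
        heavy = mosaics_to_ibd(genos, fam_of, mos, diallel_design, grid, blur=0.999)
        # near the prior limit every row approaches (1, 1) on the family parents
        g0 = genos[0]
        fam_parents = diallel_design.family_parents(fam_of[g0])
        cols = [diallel_design.parents.index(p) for p in fam_parents]
        assert np.allclose(heavy.pi[0][:, cols], 1.0, atol=0.01)
        for blur in (0.0, 0.3, 0.999):
            ibd = mosaics_to_ibd(genos, fam_of, mos, diallel_design, grid, blur=blur)
            assert np.allclose(ibd.pi.sum(axis=2), 2.0, atol=1e-12)

    def test_blur_out_of_range(self, small_map, diallel_design):
        rng = np.random.default_rng(8)
        genos, fam_of, mos = simulate_population(diallel_design, small_map, 2, rng)
        grid = build_grid(small_map, 40.0)
        with pytest.raises(ValueError):
            mosaics_to_ibd(genos, fam_of, mos, diallel_design, grid, blur=1.0)


class TestPhenotypes:
    def test_noise_free_single_qtl_forward_model(self):
        # effects +1/-1 for the two parents of each observation's genotype:
        # a pure-A genotype scores +2, a pure-B genotype -2, in every env
        qtl = TrueQTL("1", 50.0, "ecfc", effects=np.array([1.0, -1.0, 1.0, -1.0]))
        sim = make_diallel_sim(seed=20, n_per_family=10, qtls=[qtl],
                               polygenic=None, residual=(0.0, 0.0))
        gi = sim.ibd.grid.index_of("1", 50.0)
        for o in range(sim.obs.n_obs):
            pi = sim.ibd.pi[sim.obs.geno_idx[o], gi]
            expected = pi @ np.array([1.0, -1.0, 1.0, -1.0])
            assert sim.obs.y[o] == pytest.approx(expected, abs=1e-10)

    def test_es_qtl_leaves_other_environment_untouched(self):
        effects = np.zeros((2, 4))
        effects[0] = [2.0, -2.0, 1.0, -1.0]  # environment 1 only
        qtl = TrueQTL("1", 50.0, "esfc", effects=effects)
        sim = make_diallel_sim(seed=21, n_per_family=10, qtls=[qtl],
                               polygenic=None, residual=(0.0, 0.0))
        e2 = sim.obs.env_idx == 1
        assert np.allclose(sim.obs.y[e2], 0.0, atol=1e-12)
        assert not np.allclose(sim.obs.y[~e2], 0.0)

    def test_polygenic_covariance_matches_kronecker_target(self):
        # empirical covariance of simulated polygenic values over replicates
        met = np.array([[1.0, 0.6], [0.6, 2.0]])
        weights = np.array([1.0, 2.0, 0.5, 1.0])
        draws = []
        for seed in range(150):
            sim = make_diallel_sim(
                seed=seed, n_per_family=6, grid_step=50.0,
                polygenic=PolygenicSpec(met, mpp_weights=weights),
                residual=(0.0, 0.0))
            g = sim.true_polygenic
            fam0 = sim.obs.fam_idx == 0
            g0 = g[fam0].reshape(2, -1)  # env x genotypes of family 1
            draws.append([np.mean(g0[0] ** 2), np.mean(g0[1] ** 2),
                          np.mean(g0[0] * g0[1])])
        draws = np.array(draws)
        mean = draws.mean(axis=0)
        se = draws.std(axis=0) / np.sqrt(len(draws))
        target = np.array([met[0, 0], met[1, 1], met[0, 1]])
        assert np.all(np.abs(mean - target) < 3.5 * se)

    def test_seeded_determinism(self):
        a = make_diallel_sim(seed=33, n_per_family=5)
        b = make_diallel_sim(seed=33, n_per_family=5)
        assert np.array_equal(a.obs.y, b.obs.y)
        assert np.array_equal(a.ibd.pi, b.ibd.pi)
        c = make_diallel_sim(seed=34, n_per_family=5)
        assert not np.array_equal(a.obs.y, c.obs.y)
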