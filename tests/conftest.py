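import numpy as np
import pytest

from mppqei.core_data import GeneticMap, PopulationDesign, build_grid
from mppqei.simulate import (PolygenicSpec, SimulationConfig, TrueQTL,
                             simulate_dataset)


DIALLEL_PARENTS = ["A", "B", "C", "D"]
DIALLEL_CROSSES = [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]


@pytest.fixture(scope="session")
def small_map():
    return GeneticMap.from_rows([("1", 0.0), ("1", 100.0), ("2", 0.0), ("2", 80.0)])


@pytest.fixture(scope="session")
def diallel_design():
    return PopulationDesign.diallel(DIALLEL_PARENTS, DIALLEL_CROSSES)


def make_diallel_sim(seed=0, n_per_family=25, n_env=2, qtls=(), gmap=None,
                     polygenic="default", residual=(0.5, 0.8), grid_step=10.0,
                     **kw):
    """Small diallel MET simulation shared across tests."""
    if gmap is None:
        gmap = GeneticMap.from_rows([("1", 0.0), ("1", 100.0)])
    if polygenic == "default":
        polygenic = PolygenicSpec.from_corr(
            [1.0] * n_env, 0.5, mpp_weights=[1.0, 1.3, 0.8, 1.1])
    design = PopulationDesign.diallel(DIALLEL_PARENTS, DIALLEL_CROSSES)
    cfg = SimulationConfig(design=design, gmap=gmap, n_per_family=n_per_family,
                           n_env=n_env, qtls=list(qtls), polygenic=polygenic,
                           residual_var=np.asarray(residual, dtype=float),
                           grid_step=grid_step, seed=seed, **kw)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def diallel_sim():
    """One cached small diallel dataset with a known EC&FC QTL."""
    return make_diallel_sim(
        seed=42, n_per_family=30,
        qtls=[TrueQTL("1", 50.0, "ecfc", effects=np.array([1.0, -1.0, 0.5, -0.5]))])
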