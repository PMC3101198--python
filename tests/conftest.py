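import numpy as np
import pytest

from caperisk import phylo
from caperisk.synthetic import SimulationConfig, simulate_birth_death_tree, synth_cape_like_dataset

BALANCED4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def balanced4() -> phylo.PhyloTree:
    return phylo.read_newick(BALANCED4)


@pytest.fixture(scope="session")
def small_trees() -> list[phylo.PhyloTree]:
    """Fixture set of pure-birth trees with 4-12 tips (dense-oracle scale)."""
    trees = []
    for i, n in enumerate([4, 5, 6, 7, 8, 9, 10, 11, 12, 6, 8, 12]):
        trees.append(simulate_birth_death_tree(1.0, 0.0, n_tips=n, seed=100 + i))
    return trees


@pytest.fixture(scope="session")
def tree64() -> phylo.PhyloTree:
    t = simulate_birth_death_tree(1.0, 0.0, n_tips=64, seed=5)
    return t.scale_branches(10.0 / t.crown_age())


@pytest.fixture(scope="session")
def tree128() -> phylo.PhyloTree:
    return simulate_birth_death_tree(1.0, 0.0, n_tips=128, seed=7)


@pytest.fixture(scope="session")
def dataset_small() -> dict:
    cfg = SimulationConfig(seed=3, n_genera=40, n_tree_genera=4,
                           grid_shape=(15, 15))
    return synth_cape_like_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
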