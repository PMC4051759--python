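import numpy as np
import pytest

from phylorates import read_newick
from phylorates.simulate import SimConfig, make_dataset, simulate_tree


@pytest.fixture
def toy_tree():
    """3-taxon worked example: d(A,B)=2, d(A,C)=d(B,C)=4, root age 2."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star4():
    return read_newick("(A:1,B:1,C:1,D:1);")


def random_tree(n_tips: int, seed: int, root_age: float = 100.0):
    """Pure-birth ultrametric tree (binary by construction)."""
    return simulate_tree(
        SimConfig(n_tips=n_tips, root_age=root_age, seed=seed,
                  target_counts=None)
    )


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """Default synthetic dataset: 63 lianas + 71 trees, traits with holes."""
    return make_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """Small unconditioned dataset for fast end-to-end checks."""
    return make_dataset(
        SimConfig(n_tips=40, root_age=100.0, seed=5, target_counts=None,
                  missingness={})
    )
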