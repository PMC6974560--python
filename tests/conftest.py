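import numpy as np
import pandas as pd
import pytest

from cuephylo import growth_cue as gc
from cuephylo import phylocomp as pc
from cuephylo import synthetic_data as sd


@pytest.fixture(scope="session")
def balanced_tree():
    """((a:1,b:1):1,(c:1,d:1):1) — V is hand-computable."""
    return pc.read_tree("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture(scope="session")
def yule16():
    return sd.simulate_tree(sd.TreeSimParams(n_tips=16, seed=42))


@pytest.fixture(scope="session")
def yule16_vcv(yule16):
    return pc.vcv_matrix(yule16)


@pytest.fixture(scope="session")
def constants():
    return gc.AssayConstants()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def star_vcv(n: int, depth: float = 1.0):
    labels = [f"s{i}" for i in range(1, n + 1)]
    return depth * np.eye(n), labels


@pytest.fixture(scope="session")
def two_clade_tree():
    """Deep split, shallow within-clade divergence: strong signal substrate."""
    return pc.read_tree(
        "((a:0.1,b:0.1,c:0.1,d:0.1):2.0,(e:0.1,f:0.1,g:0.1,h:0.1):2.0);"
    )
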