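import pytest

from fragscreen import build_library, parse_smiles
from fragscreen.fixtures import FixtureSpec, gen_benchmark, gen_combinatorial


def mol(smiles, id="m"):
    return parse_smiles(smiles, id=id)


@pytest.fixture(scope="session")
def grid_10x10():
    """The 100-compound combinatorial fixture (10 cores x 10 substituents)."""
    spec = FixtureSpec(n_cores=10, n_substituents=10)
    return [parse_smiles(s, id=i) for i, s in gen_combinatorial(spec)]


@pytest.fixture(scope="session")
def grid_library(grid_10x10):
    return build_library(grid_10x10)


@pytest.fixture(scope="session")
def benchmark():
    """Planted-signal benchmark at the default effect size."""
    return gen_benchmark(FixtureSpec(seed=11))
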