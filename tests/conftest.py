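import numpy as np
import pytest

from phylorc.alignment_io import Alignment, compress_patterns
from phylorc.scoring import GTRModel
from phylorc.simdata import make_benchmark
from phylorc.trees import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark8():
    """Small ground-truthed dataset: 8 taxa x 200 sites."""
    return make_benchmark(8, 200, seed=7)


@pytest.fixture(scope="session")
def benchmark20():
    """The fixed end-to-end benchmark: 20 taxa x 500 sites, seed 42."""
    return make_benchmark(20, 500, seed=42)


@pytest.fixture
def quartet():
    return parse_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")


@pytest.fixture
def jc_model():
    return GTRModel(n_categories=1)


def random_alignment(taxa, n_sites, rng):
    mat = rng.integers(0, 4, size=(len(taxa), n_sites))
    return Alignment(
        labels=tuple(taxa),
        sequences=tuple("".join("ACGT"[s] for s in row) for row in mat),
    )


def random_model(rng, n_categories=1):
    return GTRModel(
        freqs=tuple(rng.dirichlet([10.0] * 4)),
        exchangeabilities=tuple(rng.uniform(0.3, 3.0, 6)),
        alpha=float(rng.uniform(0.5, 2.0)),
        n_categories=n_categories,
    )
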