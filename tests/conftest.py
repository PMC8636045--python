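import numpy as np
import pytest

from cisclust import SyntheticSpec, simulate
from cisclust.io_formats import ExpressionMatrix, GeneAnnotation


@pytest.fixture
def genes_chr1():
    """Five ranked genes on one chromosome with irregular spacing."""
    starts = [100, 500, 2_000, 2_100, 9_000]
    return [
        GeneAnnotation(f"g{i}", "chr1", s, rank=i) for i, s in enumerate(starts)
    ]


@pytest.fixture
def small_matrix(genes_chr1):
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        genes=genes_chr1,
        samples=[f"s{j}" for j in range(20)],
        values=rng.standard_normal((5, 20)),
        phenotype="test",
    )


@pytest.fixture
def blocks_matrix():
    """Blocks-mode chromosome with planted truth (5 contiguous blocks)."""
    spec = SyntheticSpec(
        n_genes=100, n_samples=300, mode="blocks", n_blocks=5, loading=0.7, seed=11
    )
    m, truth = simulate(spec)
    return m, truth, spec
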