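import numpy as np
import pytest

from polyfam.annotation_io import assign_ranks
from polyfam.models import GeneModel


def make_genes(specs):
    """GeneModels with ranks from (gene_id, chrom, start[, end]) tuples."""
    genes = []
    for spec in specs:
        gid, chrom, start = spec[:3]
        end = spec[3] if len(spec) > 3 else start + 999
        genes.append(GeneModel(gid, chrom, start, end, "+", ((start, end),)))
    return assign_ranks(genes)


@pytest.fixture
def toy_genome():
    """A 10-gene chromosome with regular 30 kb spacing."""
    return make_genes([(f"g{i}", "Chr01", 1 + 30_000 * i) for i in range(10)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
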