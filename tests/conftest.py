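import numpy as np
import pytest
import scipy.sparse as sp

from creglink.genomics_io import (
    CountMatrix,
    FragmentRecord,
    FragmentSet,
    GeneModel,
    GenomicInterval,
)
from creglink.synthetic import SimulationSpec, simulate_sample


def frag(chrom, start, end, barcode="BC1", count=1):
    return FragmentRecord(GenomicInterval(chrom, start, end), barcode, count)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts():
    """3 genes x 4 cells raw matrix with known values."""
    values = sp.csr_matrix(
        np.array(
            [
                [9, 0, 2, 1],
                [0, 3, 3, 3],
                [1, 1, 1, 5],
            ]
        )
    )
    return CountMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"], "raw")


@pytest.fixture
def simple_genes():
    return [
        GeneModel("gA", GenomicInterval("chr1", 100_000, 102_000, "+")),
        GeneModel("gB", GenomicInterval("chr2", 200_000, 203_000, "-")),
    ]


@pytest.fixture(scope="session")
def tiny_sample():
    """One small simulated sample shared across tests (read-only)."""
    spec = SimulationSpec(
        n_tissues=1,
        samples_per_tissue=1,
        n_cells_per_sample=80,
        n_genes=40,
        n_peaks=120,
        fraction_linked_peaks=0.5,
        seed=7,
    )
    bundle, truth = simulate_sample(spec, "tissue0", "s0")
    return bundle, truth


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_width=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + width))
    return out
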