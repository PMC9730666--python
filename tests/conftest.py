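import logging

import numpy as np
import pandas as pd
import pytest

from hicends.io import BinTable, ContactMatrix
from hicends.simulate import SimSpec, simulate_dataset

logging.getLogger("hicends").setLevel(logging.ERROR)


def make_bins(spec, bin_size=100_000):
    """Build a BinTable from {contig: n_bins}; sequential 1-based bin ids."""
    rows = []
    bin_id = 1
    for contig, n in spec.items():
        for k in range(n):
            rows.append((contig, k * bin_size, (k + 1) * bin_size, bin_id))
            bin_id += 1
    return BinTable(
        pd.DataFrame(rows, columns=["contig", "start", "end", "bin_id"]),
        bin_size=bin_size,
    )


@pytest.fixture
def two_contig_bins():
    # contigA bins 1-4, contigB bins 5-8
    return make_bins({"contigA": 4, "contigB": 4})


@pytest.fixture
def two_contig_matrix():
    entries = [(3, 5, 10), (4, 5, 20), (4, 6, 5), (1, 8, 1)]
    i, j, v = zip(*entries)
    return ContactMatrix(i, j, v)


@pytest.fixture(scope="session")
def default_sim():
    """A 5-chromosome simulated dataset under the default contact model."""
    return simulate_dataset(SimSpec(contigs_per_chrom=(3, 6), seed=3))


@pytest.fixture(scope="session")
def two_chrom_sim():
    return simulate_dataset(
        SimSpec(n_chrom=2, chrom_sizes=(40_000_000, 40_000_000),
                contigs_per_chrom=(2, 4), seed=7)
    )
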