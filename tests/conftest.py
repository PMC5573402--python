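import numpy as np
import pandas as pd
import pytest

from rarebio.tables_io import CountTable


def make_table(counts, otu_ids=None, sample_ids=None, relative=False) -> CountTable:
    counts = np.asarray(counts)
    otu_ids = otu_ids or [f"otu{i}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(counts.shape[1])]
    return CountTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
                      relative=relative)


def random_table(rng: np.random.Generator, n_otus=20, n_samples=8,
                 depth=2000) -> CountTable:
    """Random multinomial count table with a lognormal-ish abundance profile."""
    weights = np.exp(rng.normal(0, 2, size=n_otus))
    cols = []
    for _ in range(n_samples):
        p = weights * np.exp(rng.normal(0, 0.5, n_otus))
        cols.append(rng.multinomial(depth, p / p.sum()))
    # no empty columns possible: every multinomial draw has depth > 0 reads
    return make_table(np.column_stack(cols))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_table():
    """3 OTUs x 2 samples with known sums (6, 9)."""
    return make_table([[5, 0], [1, 2], [0, 7]])
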