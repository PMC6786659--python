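import numpy as np
import pytest

from driverank.io_formats import MutationRecord, MutationTable, PPINetwork


def record(gene, category, sample="S1", disease="", position=None, pp2=None):
    return MutationRecord(
        gene=gene,
        sample=sample,
        disease=disease,
        category=category,
        protein_position=position,
        polyphen2=pp2,
    )


@pytest.fixture
def tiny_table():
    """Three genes with hand-countable mutation patterns."""
    records = [
        # GENE1: 3 missense (pp2 0.9, 0.5, 0.1 at positions 10, 10, 22)
        record("GENE1", "missense", position=10, pp2=0.9),
        record("GENE1", "missense", position=10, pp2=0.5),
        record("GENE1", "missense", position=22, pp2=0.1),
        # GENE2: 2 frameshift, 1 nonsense, 1 splice_site, 5 missense
        record("GENE2", "frameshift"),
        record("GENE2", "frameshift"),
        record("GENE2", "nonsense"),
        record("GENE2", "splice_site"),
        *[record("GENE2", "missense", position=100, pp2=0.6) for _ in range(5)],
        # GENE3: silent only
        record("GENE3", "silent"),
    ]
    return MutationTable(records=records)


@pytest.fixture
def path_net():
    """Path graph A-B-C."""
    return PPINetwork(
        nodes=("A", "B", "C"),
        edges=frozenset({frozenset({"A", "B"}), frozenset({"B", "C"})}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_psd(rng, n, rank=None):
    X = rng.normal(size=(n, rank or n))
    return X @ X.T
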