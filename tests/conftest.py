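import numpy as np
import pytest

from microbeta.io_formats import OtuTable, TaxonomyMap, parse_newick
from microbeta.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [10, 0, 5, 1],
            [0, 8, 2, 0],
            [3, 3, 3, 3],
        ]
    )
    return OtuTable(("s1", "s2", "s3"), ("OtuA", "OtuB", "OtuC", "OtuD"), counts)


@pytest.fixture
def small_taxonomy():
    return TaxonomyMap(
        {
            "OtuA": ("Bacteria", "Firmicutes", "Clostridia"),
            "OtuB": ("Bacteria", "Firmicutes", "Bacilli"),
            "OtuC": ("Bacteria", "Proteobacteria"),
            "OtuD": ("Bacteria", "Actinobacteria"),
        }
    )


@pytest.fixture
def four_leaf_tree():
    # balanced tree over A..D with unit branch lengths
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def quartet_table():
    counts = np.array(
        [
            [10, 0, 0, 0],
            [0, 10, 0, 0],
            [0, 0, 10, 0],
            [5, 5, 0, 0],
        ]
    )
    return OtuTable(("sa", "sb", "sc", "sab"), ("A", "B", "C", "D"), counts)


@pytest.fixture(scope="session")
def default_dataset():
    """One modest synthetic dataset shared across tests (cheap to generate)."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_generator_config():
    return GeneratorConfig(
        n_samples=12,
        depth=800,
        otus_per_phylum={
            "Firmicutes": 12,
            "Proteobacteria": 8,
            "Actinobacteria": 6,
            "Bacteroidetes": 4,
            "Fusobacteria": 3,
            "unclassified bacteria": 2,
        },
        seed=7,
    )
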