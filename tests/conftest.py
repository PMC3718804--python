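import numpy as np
import pytest

from colonykin.genotypes import GenotypeTable
from colonykin.simulate import SourcePopulationModel


@pytest.fixture(scope="session")
def model() -> SourcePopulationModel:
    """Default source population: 8 loci, 10 equifrequent alleles."""
    return SourcePopulationModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def table_from_genotypes(colonies: dict, locus_names=None) -> GenotypeTable:
    """Build a table from {colony: [[(a1,a2) per locus], ...]} literals."""
    ids, groups, rows = [], [], []
    for colony, members in colonies.items():
        for i, member in enumerate(members):
            ids.append(f"{colony}_{i}")
            groups.append(colony)
            rows.append(member)
    arr = np.asarray(rows, dtype=np.int32)
    names = locus_names or [f"L{l + 1}" for l in range(arr.shape[1])]
    return GenotypeTable(arr, ids, names, np.array(groups, dtype=object))
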