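import numpy as np
import pytest

from gutnet.data import AbundanceTable, SampleGroups, TaxonAnnotation


@pytest.fixture
def tiny_table() -> AbundanceTable:
    """3 taxa x 4 samples, no zeros."""
    counts = np.array(
        [
            [10, 20, 30, 40],
            [5, 5, 5, 5],
            [1, 2, 3, 4],
        ]
    )
    return AbundanceTable(["Escherichia", "Bifidobacterium", "Roseburia"], ["S1", "S2", "S3", "S4"], counts)


@pytest.fixture
def random_table() -> AbundanceTable:
    """10 taxa x 20 samples of Poisson counts (fixed seed), all columns positive."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(50, size=(10, 20)) + 1
    return AbundanceTable(
        [f"T{i}" for i in range(10)], [f"S{j}" for j in range(20)], counts
    )


@pytest.fixture
def two_group_labels() -> SampleGroups:
    return SampleGroups({"S1": "Yes", "S2": "Yes", "S3": "No", "S4": "No"})


@pytest.fixture
def vs_annotation() -> TaxonAnnotation:
    return TaxonAnnotation({"Escherichia": "virulent", "Bifidobacterium": "symbiotic"})
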