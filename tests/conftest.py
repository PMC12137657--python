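import numpy as np
import pytest

from invasionscape.core_io import GenotypeMatrix, Locality, OccurrenceRecord


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """Ten individuals in two localities, four loci, hand-enterable calls."""
    calls = np.array([
        [0, 1, 2, 1],
        [1, 1, 0, 0],
        [2, 0, 1, 1],
        [0, 1, 1, 2],
        [1, 2, 0, 1],
        [2, 2, 2, 0],
        [1, 0, 1, 1],
        [0, 1, 2, 2],
        [2, 1, 0, 1],
        [1, 0, 1, 0],
    ], dtype=np.int8)
    inds = [f"i{k}" for k in range(10)]
    return GenotypeMatrix(
        individuals=inds,
        loci=["l1", "l2", "l3", "l4"],
        calls=calls,
        locality_of={ind: (1 if k < 5 else 2) for k, ind in enumerate(inds)},
    )


@pytest.fixture
def two_localities() -> list[Locality]:
    return [Locality(1, 0.0, 0.0, 5), Locality(2, 5000.0, 0.0, 5)]


def make_records(points, year=2005):
    return [OccurrenceRecord(id=f"r{i:03d}", x=x, y=y, year=year)
            for i, (x, y) in enumerate(points)]
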