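import numpy as np
import pytest

from genoclim.genotype_data import GenotypeTable
from genoclim.spatial import GridRaster, OccurrenceSet
from genoclim.synthetic_data import (
    GenotypeSimSpec,
    LandscapeSimSpec,
    sample_occurrences,
    simulate_genotypes,
    simulate_landscape,
)


@pytest.fixture
def toy_table() -> GenotypeTable:
    """Three accessions, two loci, no missing calls."""
    calls = np.array(
        [
            [[1, 1], [3, 4]],
            [[1, 2], [3, 3]],
            [[2, 2], [4, 5]],
        ]
    )
    return GenotypeTable(
        ["a1", "a2", "a3"], ["LocA", "LocB"], calls, groups=["g1", "g1", "g2"]
    )


@pytest.fixture
def two_group_table() -> GenotypeTable:
    """Two groups of two accessions with some shared and private alleles."""
    calls = np.array(
        [
            [[1, 2], [5, 5]],
            [[1, 1], [5, 6]],
            [[3, 4], [6, 6]],
            [[2, 3], [7, 7]],
        ]
    )
    return GenotypeTable(
        ["x1", "x2", "y1", "y2"],
        ["L1", "L2"],
        calls,
        groups=["gx", "gx", "gy", "gy"],
    )


@pytest.fixture(scope="session")
def bn_table():
    """Moderately differentiated 3-group Balding-Nichols draw."""
    gt, truth = simulate_genotypes(
        GenotypeSimSpec(seed=42, fst=0.2, group_sizes=(40, 40, 40), n_loci=12)
    )
    return gt, truth


@pytest.fixture(scope="session")
def landscape():
    spec = LandscapeSimSpec(
        n_rows=60, n_cols=60, n_covariates=3,
        coefficients=(1.2, -0.8, 0.5), smooth_cells=5, seed=7,
    )
    stack, suit = simulate_landscape(spec)
    occ = sample_occurrences(suit, 200, seed=8)
    return stack, suit, occ


@pytest.fixture
def template_raster() -> GridRaster:
    return GridRaster(0.0, 0.0, 0.1, np.zeros((20, 20)))


@pytest.fixture
def square_occurrences() -> OccurrenceSet:
    rng = np.random.default_rng(3)
    n = 40
    return OccurrenceSet(
        [f"p{i}" for i in range(n)], rng.uniform(0, 2, n), rng.uniform(0, 2, n)
    )
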