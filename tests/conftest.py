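import numpy as np
import pytest

from gsblup import (
    AdjustedPhenotypes,
    AdjustMethod,
    Encoding,
    GenotypeMatrix,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture
def small_population():
    """60 individuals x 200 markers with an additive trait at h2 = 0.5."""
    g = simulate_genotypes(60, 200, seed=1)
    pop = simulate_phenotypes(g, n_qtl=20, h2=0.5, seed=2)
    y = AdjustedPhenotypes(
        "sim_trait", pop.phenotypes, AdjustMethod.ARITHMETIC_MEAN, ["trial1"]
    )
    return g, pop, y


@pytest.fixture
def genotypes_with_missing():
    """10 x 8 dosage matrix with 5 missing cells (fixed positions)."""
    g = simulate_genotypes(10, 8, seed=7)
    d = g.dosage.copy()
    for i, j in [(0, 2), (3, 5), (4, 0), (7, 7), (9, 3)]:
        d[i, j] = np.nan
    return GenotypeMatrix(g.individual_ids, g.marker_ids, d, Encoding.ZERO_1_2)
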