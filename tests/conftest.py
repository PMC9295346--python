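import numpy as np
import pytest

from unpairreg.types import CellMatrix, make_genes_table, make_regions_table


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def cell_matrix(values, role="accessibility", prefix="c", fprefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return CellMatrix(
        values,
        [f"{prefix}{i}" for i in range(n)],
        [f"{fprefix}{j}" for j in range(p)],
        role,
    )


@pytest.fixture
def toy_tables():
    regions = make_regions_table(
        ["r0", "r1", "r2"], ["chr1", "chr1", "chr2"], [100, 5000, 100], [300, 5400, 300]
    )
    genes = make_genes_table(
        ["g0", "g1"], ["chr1", "chr2"], [1200, 50_000], ["+", "-"]
    )
    return regions, genes
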