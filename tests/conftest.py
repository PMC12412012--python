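import numpy as np
import pandas as pd
import pytest

from glycomsi.synthetic import (
    BulkCohortSpec,
    IHCSimSpec,
    SingleCellSpec,
    default_gene_universe,
    generate_bulk_cohort,
    generate_ihc_cohort,
    generate_single_cell,
)


@pytest.fixture(scope="session")
def small_universe():
    return default_gene_universe(20)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bulk():
    """A small planted bulk cohort shared across read-only tests."""
    spec = BulkCohortSpec(n_msi=30, n_mss=60, seed=7)
    return generate_bulk_cohort(spec), spec


@pytest.fixture(scope="session")
def small_sc():
    spec = SingleCellSpec(
        n_cells_tumor_epithelial=800, n_cells_other=200, seed=7
    )
    return generate_single_cell(spec), spec


@pytest.fixture(scope="session")
def ihc_cohort():
    spec = IHCSimSpec(n=800, seed=7)
    return generate_ihc_cohort(spec), spec


@pytest.fixture()
def random_matrix(rng):
    """Random 10-gene x 8-sample log-scale matrix with MSI/MSS labels."""
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{i}" for i in range(8)]
    mat = pd.DataFrame(rng.normal(8, 1, (10, 8)), index=genes, columns=samples)
    labels = pd.Series(["MSI"] * 4 + ["MSS"] * 4, index=samples)
    return mat, labels
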