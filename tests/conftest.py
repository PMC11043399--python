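import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mosaicloy import CountMatrix, SimulationConfig, generate_expression_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One mixed-sex cohort at the default study conditions."""
    config = SimulationConfig(
        n_donors=4, donor_sexes=("male", "male", "male", "female"),
        n_cells_per_donor_tissue=300, seed=101,
    )
    matrix, cells = generate_expression_dataset(config)
    return config, matrix, cells


@pytest.fixture(scope="session")
def zero_dropout_dataset():
    """Male-only cohort without technical zeros: calls must equal truth."""
    config = SimulationConfig(n_donors=2, msy_dropout=0.0,
                              n_cells_per_donor_tissue=400, seed=202)
    matrix, cells = generate_expression_dataset(config)
    return config, matrix, cells


@pytest.fixture
def toy_matrix():
    """Hand-built 4-gene x 3-cell matrix with known MSY structure."""
    genes = ["RPS4Y1", "ZFY", "EIF1AY", "ACTB"]
    #               c1  c2  c3
    values = np.array([
        [2, 0, 0],   # RPS4Y1
        [0, 0, 0],   # ZFY
        [0, 1, 0],   # EIF1AY
        [8, 5, 3],   # ACTB
    ])
    return CountMatrix(sp.csr_matrix(values), genes, ["c1", "c2", "c3"])
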