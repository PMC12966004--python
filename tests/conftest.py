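import numpy as np
import pandas as pd
import pytest

import heattol as ht


@pytest.fixture
def small_pheno() -> ht.PhenoTable:
    """2 genotypes x 1 index x 2 conditions x 2 replicates."""
    rows = [
        ("g1", "CAT", "CK", 1, 4.0),
        ("g1", "CAT", "CK", 2, 6.0),
        ("g1", "CAT", "HS", 1, 10.0),
        ("g1", "CAT", "HS", 2, 10.0),
        ("g2", "CAT", "CK", 1, 8.0),
        ("g2", "CAT", "CK", 2, 8.0),
        ("g2", "CAT", "HS", 1, 4.0),
        ("g2", "CAT", "HS", 2, 4.0),
    ]
    return ht.PhenoTable(
        pd.DataFrame(rows, columns=["genotype", "index", "condition", "replicate", "value"])
    )


def random_coefficient_matrix(rng: np.random.Generator, n: int, p: int) -> ht.CoefficientMatrix:
    """Random non-negative genotype x index matrix with non-constant columns."""
    h = rng.uniform(0.1, 3.0, size=(n, p))
    return ht.CoefficientMatrix(
        pd.DataFrame(
            h,
            index=[f"g{i}" for i in range(n)],
            columns=[f"ix{j}" for j in range(p)],
        )
    )


@pytest.fixture
def default_trial():
    return ht.generate_trial(ht.SimulationConfig(seed=11))
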