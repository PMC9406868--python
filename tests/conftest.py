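import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracle helpers importable

from m6ascore import ExpressionMatrix, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort drawn with the generator's default parameters."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture()
def tiny_matrix():
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],
                [5.0, 1.0, 4.0, 2.0],
            ]
        ),
    )


def two_block_matrix(n_per_block=5, n_genes=10, seed=0):
    """Two blocks of near-duplicate sample profiles, trivially separable."""
    rng = np.random.default_rng(seed)
    base1 = rng.normal(0, 1, n_genes)
    base2 = -base1
    cols = [base1 + rng.normal(0, 1e-6, n_genes) for _ in range(n_per_block)]
    cols += [base2 + rng.normal(0, 1e-6, n_genes) for _ in range(n_per_block)]
    values = np.column_stack(cols)
    samples = [f"a{i}" for i in range(n_per_block)] + [f"b{i}" for i in range(n_per_block)]
    return ExpressionMatrix([f"g{i}" for i in range(n_genes)], samples, values)
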