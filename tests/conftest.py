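import numpy as np
import pytest

from bicgrn import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 3 conditions with one missing cell (r2 at c3)."""
    vals = np.array([
        [1.0, 1.0, 1.0],
        [1.0, 1.0, np.nan],
        [5.0, 5.0, 5.0],
        [9.0, 9.0, 9.0],
    ])
    return ExpressionMatrix(["r1", "r2", "r3", "r4"], ["c1", "c2", "c3"], vals)


def make_matrix(values, gene_prefix="g", cond_prefix="c") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    conds = [f"{cond_prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, conds, values)
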