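import numpy as np
import pytest

from idopnet.expression import ExpressionIndex, ExpressionMatrix


@pytest.fixture
def small_matrix():
    """2 genes x 3 samples with easily checked column sums."""
    return ExpressionMatrix(
        gene_ids=["gA", "gB"],
        sample_ids=["s1", "s2", "s3"],
        values=np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 1.0]]),
    )


@pytest.fixture
def power_law_data():
    """Noiseless power-law genes over a positive EI grid."""
    ei = np.linspace(1.0, 10.0, 40)
    e = ExpressionIndex(ei=ei, order=np.arange(40))
    y_up = 2.0 * ei**0.5
    y_down = 3.0 * ei**-0.7
    return e, y_up, y_down


@pytest.fixture
def planted_single_edge():
    """m=5 system in which only gene 2 drives gene 1 (weight +0.7)."""
    from idopnet.simulate import SimulationConfig, simulate_expression

    W = np.zeros((5, 5))
    W[0, 1] = 0.7
    sim = simulate_expression(
        SimulationConfig(n_samples=100, n_genes=5, variance=0.01, seed=42),
        adjacency=W,
    )
    return sim
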