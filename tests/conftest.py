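import numpy as np
import pytest

import goegcn as G


@pytest.fixture
def small_expr():
    """Deterministic 50-gene x 10-sample linear matrix."""
    rng = np.random.default_rng(10)
    values = rng.gamma(2.0, 10.0, size=(50, 10))
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{i}" for i in range(10)]
    return G.ExpressionMatrix(genes, samples, values, "linear")


@pytest.fixture
def two_group_design():
    return G.GroupDesign(
        {f"s{i}": ("control" if i < 5 else "experiment") for i in range(10)})
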