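import numpy as np
import pytest

from sigdriver.io import ExpressionMatrix, SubtypeAssignment


@pytest.fixture
def small_matrix():
    """4 genes x 6 samples (4 tumor + 2 normal), deterministic values."""
    rng = np.random.default_rng(42)
    values = rng.normal(0.0, 1.0, size=(4, 6))
    return ExpressionMatrix(
        ["gA", "gB", "gC", "gD"],
        ["t1", "t2", "t3", "t4", "n1", "n2"],
        values,
        ["tumor"] * 4 + ["normal"] * 2,
    )


@pytest.fixture
def two_group_matrix():
    """20 genes x 20 tumors, first 5 genes shifted +2 in group 1."""
    rng = np.random.default_rng(7)
    x = rng.normal(0.0, 1.0, size=(20, 20))
    x[:5, :10] += 2.0
    genes = [f"g{i:02d}" for i in range(20)]
    samples = [f"s{j:02d}" for j in range(20)]
    expr = ExpressionMatrix(genes, samples, x, ["tumor"] * 20)
    labels = SubtypeAssignment(
        {s: (1 if j < 10 else 2) for j, s in enumerate(samples)}, K=2
    )
    return expr, labels
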