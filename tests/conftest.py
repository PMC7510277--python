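import numpy as np
import pytest

from mcbfsnw import ExpressionDataset
from mcbfsnw.data_io import InteractionNetwork


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """6 samples x 4 genes, 2 balanced classes; gene g1 separates the classes."""
    rng = np.random.default_rng(42)
    values = rng.normal(0, 1, size=(6, 4))
    values[3:, 0] += 5.0  # g1 shifts in class "tumor"
    return ExpressionDataset(
        values=values,
        sample_ids=[f"s{i}" for i in range(6)],
        gene_ids=["g1", "g2", "g3", "g4"],
        labels=["normal"] * 3 + ["tumor"] * 3,
    )


@pytest.fixture
def path_graph() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle_graph() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
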