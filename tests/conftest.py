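import numpy as np
import pytest

from mvgst.preprocess import CountMatrix
from mvgst.simulate import TINY_CONFIG, simulate_slide


@pytest.fixture(scope="session")
def tiny_slide():
    """25-spot, 2-domain, 20-gene pinned slide for unit-level checks."""
    return simulate_slide(TINY_CONFIG)


@pytest.fixture()
def toy_counts():
    """Small hand-sized count matrix with coordinates on a line."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(3.0, size=(6, 8))
    counts[0, 0] += 20  # guarantee variation
    return CountMatrix(
        counts=counts,
        coords=np.column_stack([np.arange(6.0), np.zeros(6)]),
        spot_ids=np.array([f"s{i}" for i in range(6)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(8)], dtype=object),
        in_tissue=np.ones(6, dtype=bool),
    )
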