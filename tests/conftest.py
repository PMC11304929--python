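import numpy as np
import pandas as pd
import pytest

from scpoe.io_and_data import AssayMatrix, assemble_dataset
from scpoe.synthetic_data import default_benchmark_config, simulate_multiomics


@pytest.fixture
def tiny_dataset():
    """Two assays on 8 shared cells, no masks."""
    rng = np.random.default_rng(0)
    cells = [f"c{i}" for i in range(8)]
    meta = pd.DataFrame(
        {"donor": ["d0", "d1"] * 4, "age": np.arange(8.0)},
        index=pd.Index(cells),
    )
    a = AssayMatrix("rna", rng.poisson(3.0, (8, 5)).astype(float),
                    [f"g{i}" for i in range(5)], cells)
    b = AssayMatrix("adt", rng.normal(0, 1, (8, 3)),
                    [f"p{i}" for i in range(3)], cells)
    return assemble_dataset([a, b], meta)


@pytest.fixture(scope="session")
def small_simulation():
    """One small simulated benchmark dataset shared across tests."""
    cfg = default_benchmark_config(seed=7, n_cells=300)
    return simulate_multiomics(cfg)
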