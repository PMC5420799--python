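import numpy as np
import pandas as pd
import pytest

from ssctrn import simulate


@pytest.fixture(scope="session")
def small_matrix() -> pd.DataFrame:
    """A tiny deterministic genes x samples matrix for format/normalization tests."""
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(1, 21)]
    cols = ["SSC_1", "SSC_2", "SSC_3", "iSSC_1", "iSSC_2", "mSSC_1", "mSSC_2", "mSSC_3"]
    return pd.DataFrame(rng.normal(8.0, 1.0, (20, 8)), index=genes, columns=cols)


@pytest.fixture(scope="session")
def stage_map(small_matrix) -> dict[str, str]:
    return {c: c.split("_")[0] for c in small_matrix.columns}


@pytest.fixture(scope="session")
def planted_run():
    """A moderate planted simulation shared by power/recovery tests."""
    config = simulate.SimulationConfig(
        n_genes=1200,
        group_fractions={2: 0.1, 8: 0.1},
        seed=42,
    )
    matrix, stages, truth = simulate.simulate_expression(config)
    return matrix, stages, truth
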