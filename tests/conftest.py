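import numpy as np
import pandas as pd
import pytest

from scbench.simdata import SyntheticSpec, simulate_counts, simulate_protocol_pair


def small_spec(seed=0, **overrides):
    """Desk-scale paired-library spec: 2 types x 30 cells/protocol, 500 genes."""
    params = dict(
        n_genes=500,
        n_cell_types=2,
        cells_per_type_per_protocol=pd.DataFrame(
            {"A": [30, 30], "B": [30, 30]}, index=["type0", "type1"]),
        library_size_log_mean=float(np.log(600)),
        stress_fold=1.0,
        lowq_fraction=0.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


@pytest.fixture(scope="session")
def sim_pair():
    """One simulated molecule-level protocol pair with ground truth."""
    spec = small_spec(seed=11)
    table_a, table_b, truth = simulate_protocol_pair(spec)
    return spec, table_a, table_b, truth


@pytest.fixture(scope="session")
def counts_pair():
    """Count-matrix-level simulation (400 cells, 800 genes) with a planted 4x stress fold."""
    spec = small_spec(
        seed=21, n_genes=800, stress_fold=4.0,
        cells_per_type_per_protocol=pd.DataFrame(
            {"A": [100, 100], "B": [100, 100]}, index=["type0", "type1"]),
        library_size_log_mean=float(np.log(2000)),
    )
    adata, truth = simulate_counts(spec)
    return spec, adata, truth
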