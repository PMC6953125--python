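import numpy as np
import pandas as pd
import pytest

from zonepipe import SimConfig, simulate_bulk_timecourse, simulate_layered_cells


@pytest.fixture(scope="session")
def small_layered():
    """A small layered single-cell simulation with planted zonation."""
    cfg = SimConfig(n_genes=200, n_cells=360, frac_pericentral=0.1,
                    frac_periportal=0.1, base_mean=2.0, seed=11)
    matrix, truth = simulate_layered_cells(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_bulk():
    """A small bulk time course with the default planted effects."""
    cfg = SimConfig(n_genes=400, frac_pericentral=0.1, frac_periportal=0.1, seed=21)
    bulk, truth = simulate_bulk_timecourse(cfg)
    return cfg, bulk, truth


@pytest.fixture()
def toy_design():
    """Full six-group design with 3 replicates per group."""
    rows = []
    for treatment, month in [("untreated", 0), ("oil", 2), ("oil", 12),
                             ("ccl4", 2), ("ccl4", 6), ("ccl4", 12)]:
        for r in range(1, 4):
            rows.append({"sample": f"{treatment}_m{month}_r{r}",
                         "treatment": treatment, "month": month, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")
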