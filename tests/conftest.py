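import numpy as np
import pandas as pd
import pytest

from exocargo import simulate


@pytest.fixture()
def small_cfg() -> simulate.SimConfig:
    """A small, error-free study configuration for fast exact-recovery tests."""
    return simulate.SimConfig(
        seed=11, n_proteins=40, n_mirnas=15, mean_log_range=(1.0, 2.5),
        error_rate=0.0, gene_universe_size=60, n_true_dags=5,
    )


@pytest.fixture()
def toy_evidence() -> pd.DataFrame:
    """Three proteins in three replicates with hand-checkable metrics."""
    rows = []
    for acc, score, cov, area in [("A", 100.0, 50.0, 1e9),
                                  ("B", 60.0, 20.0, 5e8),
                                  ("C", 20.0, 10.0, 1e8)]:
        for rep in (1, 2, 3):
            rows.append({"accession": acc, "gene": acc.lower(), "replicate": rep,
                         "score": score, "coverage": cov, "area": area})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
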