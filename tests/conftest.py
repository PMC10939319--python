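import numpy as np
import pandas as pd
import pytest

from thermorev.phenotypes import BatchRecord
from thermorev.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated study shared across tests (300 genes, 6 families)."""
    cfg = SimConfig(seed=11, n_genes=300)
    gene_counts, exon_counts, sheet, truth = simulate_counts(cfg)
    return cfg, gene_counts, exon_counts, sheet, truth


@pytest.fixture(scope="session")
def trait_vector(small_sim):
    cfg = small_sim[0]
    return pd.Series(cfg.ir_values, index=list(cfg.families), dtype=float)


@pytest.fixture
def example_batches():
    """Two populations, two families each, with a clear treatment effect."""
    rows = []
    for pop, fams, p_c, p_t in (("GB", ("GB_F1", "GB_F2"), 0.5, 0.65),
                                ("GO", ("GO_F1", "GO_F2"), 0.75, 0.9)):
        for fam in fams:
            for treatment, p in (("control", p_c), ("ltherm", p_t)):
                n = 200
                rows.append(BatchRecord(pop, fam, treatment, n, int(n * 0.9),
                                        int(n * 0.85), int(n * 0.85 * p)))
    return rows


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
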