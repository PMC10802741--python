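import numpy as np
import pytest

from lnresponse import simulate as sim


@pytest.fixture(scope="session")
def bulk_small():
    """Small single-drug cohort with planted signature (shared, read-only)."""
    cfg = sim.BulkSimConfig(n_patients_per_arm=20, visits_per_patient=3,
                            n_genes=300, n_up=10, n_down=10,
                            effect_size=1.0, patient_sd=0.5, noise_sd=0.5,
                            drugs=("MMF",), seed=42)
    expr, cohort, truth = sim.generate_bulk_cohort(cfg)
    return cfg, expr, cohort, truth


@pytest.fixture(scope="session")
def sc_small():
    cfg = sim.ScSimConfig(n_cells=500, n_clusters=4,
                          fraction_low_quality=0.1, seed=7)
    adata, truth = sim.generate_single_cell(cfg)
    return cfg, adata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
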