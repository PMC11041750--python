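import numpy as np
import pandas as pd
import pytest

from pairedtcr.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small two-patient cohort shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_patients=2, cells_per_tissue=400, n_genes=5200)
    return generate_dataset(cfg)


def make_frame(rows):
    """Repertoire frame from (barcode, patient, tissue, cluster, subset, clonotype) tuples."""
    return pd.DataFrame(
        rows, columns=["barcode", "patient", "tissue", "cluster", "subset", "clonotype"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
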