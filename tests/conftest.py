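import numpy as np
import pytest

from toopanel import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic 4-class simulated dataset with ground truth."""
    cfg = SimConfig(
        n_classes=4,
        samples_per_class=[15, 15, 15, 15],
        n_genes=300,
        markers_per_class=8,
        marker_log2_fc=2.0,
        dispersion=0.1,
        seed=42,
    )
    table, labels, truth = simulate_dataset(cfg)
    return cfg, table, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
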