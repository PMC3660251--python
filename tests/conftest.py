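import numpy as np
import pandas as pd
import pytest

from colotype.sim import SimConfig, simulate_expression


@pytest.fixture(scope="session")
def small_config():
    """Desk-size cohort: 120 samples, 300 genes, 30 markers/subtype."""
    return SimConfig(n_samples=120, n_genes=300, n_markers_per_subtype=30,
                     seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def separable_cohort():
    """Strongly separated 3-subtype cohort for exact-recovery checks."""
    cfg = SimConfig(n_samples=60, n_genes=120, n_markers_per_subtype=20,
                    subtypes=("C1", "C2", "C3"),
                    prevalences=(0.4, 0.3, 0.3),
                    effect_size=4.0, noise_sd=0.3, seed=5)
    return simulate_expression(cfg)


@pytest.fixture
def planted_blocks():
    """Noise-free matrix with three identical-column blocks of samples."""
    rng = np.random.default_rng(3)
    genes = [f"G{i:03d}" for i in range(40)]
    cols = {}
    truth = {}
    for b, size in zip("ABC", (4, 5, 6)):
        proto = rng.normal(0, 1, 40)
        for i in range(size):
            sid = f"{b}{i}"
            cols[sid] = proto
            truth[sid] = b
    expr = pd.DataFrame(cols, index=genes)
    return expr, pd.Series(truth)
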