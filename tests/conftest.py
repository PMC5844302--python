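import numpy as np
import pytest

from methylome.simulate import SimulationConfig, simulate_study


def small_config(**overrides) -> SimulationConfig:
    """A fast, small study for unit tests (two short chromosomes)."""
    defaults = dict(
        chrom_lengths={"chrA": 120_000, "chrB": 80_000},
        spike_in_length=20_000,
        n_genes=10,
        gene_length_mean=8_000,
        n_islands_per_chrom=3,
        depth_mean=20.0,
        n_hypo=4,
        n_hyper=2,
        dmr_n_cpgs=6,
        mbias_calls_per_pos=2_000,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared across read-only tests."""
    return simulate_study(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(7)
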