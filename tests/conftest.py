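import numpy as np
import pytest

from polyloopsim.genome_config import (
    BoundaryElement,
    GenomeAnnotation,
    SimulationParameters,
)


def make_params(**overrides) -> SimulationParameters:
    """Small-chain parameter set for fast tests; override freely."""
    base = dict(
        chain_length_kb=120,
        monomer_size_kb=2,
        n_lef_target=2,
        velocity_kb_per_min=20.0,
        unbind_rate_per_min=0.5,
        sim_time_min=10.0,
        snapshot_interval_min=1.0,
        equilibration_time_min=1.0,
        hic_bin_kb=10,
        contact_cutoff_nm=100.0,
    )
    base.update(overrides)
    return SimulationParameters(**base)


@pytest.fixture
def small_params() -> SimulationParameters:
    return make_params()


@pytest.fixture
def bare_genome(small_params) -> GenomeAnnotation:
    return GenomeAnnotation(n_monomers=small_params.n_monomers)


def straight_chain(n: int, spacing: float = 50.0) -> np.ndarray:
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    return pos
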