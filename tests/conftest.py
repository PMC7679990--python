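import numpy as np
import pytest

from scregkit import qc
from scregkit.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured dataset reused by read-only tests."""
    cfg = SimulationConfig(
        n_states=4, cells_per_state=60, n_genes=300, n_tfs=6,
        n_planted_regulons=3, targets_per_regulon=15,
        repressive_fraction=0.34, n_dd_de=8, n_dd_dz=8, n_dd_dm=4,
        n_cycle_genes=15, seed=11)
    adata, truth = simulate_counts(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def discovery_sim():
    """More cell states (the CV gate needs enough per-type points)."""
    cfg = SimulationConfig(
        n_states=8, cells_per_state=50, n_genes=400, n_tfs=8,
        n_planted_regulons=4, targets_per_regulon=25,
        repressive_fraction=0.25, plant_dd=False, seed=13)
    adata, truth = simulate_counts(cfg)
    norm = qc.normalize_log(adata)
    return cfg, adata, truth, np.asarray(norm.X.todense())


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, adata, _ = small_sim
    norm = qc.normalize_log(adata)
    return np.asarray(norm.X.todense()), list(adata.var_names)
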