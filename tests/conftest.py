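import numpy as np
import pytest

from ratecov import (
    Module,
    SimulationConfig,
    build_erc_matrix,
    compute_rer,
    master_profile,
    simulate_branch_tables,
)

MODULE_GENES = tuple(f"G{i:04d}" for i in range(1, 11))


def rers_from_tables(tables, min_genes_per_branch=10, epsilon=1e-6):
    out = []
    for tab in tables:
        master = master_profile(tab, min_genes_per_branch)
        out.append(compute_rer(tab, master, epsilon=epsilon))
    return out


@pytest.fixture(scope="session")
def module_sim():
    """Three-clade simulation with one strongly coevolving 10-gene module."""
    cfg = SimulationConfig(
        n_genes=100,
        species_per_clade=(25, 25, 25),
        modules=(Module("M1", MODULE_GENES, 0.8),),
        missing_prob=0.1,
        seed=11,
    )
    tables, truth, trees = simulate_branch_tables(cfg)
    return cfg, tables, truth, trees


@pytest.fixture(scope="session")
def module_matrix(module_sim):
    _, tables, _, _ = module_sim
    return build_erc_matrix(rers_from_tables(tables))


@pytest.fixture(scope="session")
def null_sim():
    """Null simulation: no modules, three clades, complete data."""
    cfg = SimulationConfig(
        n_genes=80,
        species_per_clade=(20, 20, 20),
        missing_prob=0.0,
        seed=5,
    )
    tables, truth, trees = simulate_branch_tables(cfg)
    return cfg, tables, truth, trees


@pytest.fixture(scope="session")
def null_matrix(null_sim):
    _, tables, _, _ = null_sim
    return build_erc_matrix(rers_from_tables(tables))
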