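import numpy as np
import pandas as pd
import pytest
import anndata as ad
import scipy.sparse as sp

from ehtact.config import (PerturbationConfig, ReferencePanelConfig,
                           SimulationConfig)


def small_sim_config(seed: int = 0, n_cells: int = 300,
                     n_genes: int = 120) -> SimulationConfig:
    cfg = SimulationConfig(seed=seed)
    cfg.perturbation.n_cells_per_library = n_cells
    cfg.perturbation.n_genes = n_genes
    cfg.reference.n_cells_in_vivo = 400
    cfg.reference.n_cells_in_vitro = 400
    cfg.reference.n_background_genes = 80
    return cfg


def null_perturbation_config(seed: int = 0, n_cells: int = 500,
                             n_genes: int = 60) -> SimulationConfig:
    """All planted effects switched off: exchangeable libraries."""
    cfg = SimulationConfig(seed=seed)
    p: PerturbationConfig = cfg.perturbation
    p.n_cells_per_library = n_cells
    p.n_genes = n_genes
    p.activation_fold = {t: 1.0 for t in p.targets}
    p.arterial_expansion_fold_NT = 1.0
    p.arterial_expansion_fold_AGM = 1.0
    p.effector_induction_fold = 1.0
    p.driver_arterial_ratio = 1.0
    p.qc_outlier_fraction = 0.0
    return cfg


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return small_sim_config(seed=7)


@pytest.fixture(scope="session")
def small_perturbation(small_config):
    from ehtact.simulate import simulate_perturbation_experiment
    return simulate_perturbation_experiment(small_config)


@pytest.fixture(scope="session")
def small_reference(small_config):
    from ehtact.simulate import simulate_reference_panel
    return simulate_reference_panel(small_config)


def make_adata(counts, genes=None, obs=None) -> ad.AnnData:
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[1])]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs if obs is not None else pd.DataFrame(
            index=[f"c{i}" for i in range(counts.shape[0])]),
        var=pd.DataFrame(index=genes),
    )
    return adata
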