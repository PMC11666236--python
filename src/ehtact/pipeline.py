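"""End-to-end orchestration of the perturbation analysis on one dataset.

`run_perturbation_pipeline` chains the full read-out used throughout the
package: guide detection and library-rule filtering, QC gating,
normalisation, clustering, marker-panel annotation, then the four
perturbation statistics (activation matrix, cluster composition, guide
enrichment in the arterial cluster, differential expression of arterial
cells between the induced pool and induced control libraries).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .candidates import discover_candidates
from .config import DEFAULT_MARKER_PANELS, SimulationConfig
from .guides import detect_guides, filter_cells_by_guides
from .perturb import (ActivationProfile, CompositionResult, EnrichmentResult,
                      activation_matrix, compare_cluster_composition,
                      differential_expression, guide_enrichment)
from .preprocess import (QCThresholds, annotate_clusters, cluster_cells,
                         normalise_log, qc_filter)
from .simulate import (PerturbationData, simulate_perturbation_experiment,
                       simulate_reference_panel)

def synthetic_qc_for(n_genes: int) -> QCThresholds:
    """QC gates scaled to the synthetic gene panel.

    Healthy simulated cells detect roughly a fifth of the panel, planted
    low-coverage outliers far less; the same closed-interval rule used for
    real droplet data, with bounds proportional to panel size (and the usual
    1-15% mitochondrial window).
    """
    return QCThresholds(min_genes=max(5, int(0.13 * n_genes)),
                        max_genes=max(10, int(0.85 * n_genes)),
                        min_pct_mito=1.0, max_pct_mito=15.0)


#: gates for the default 300-gene panel
SYNTHETIC_QC = synthetic_qc_for(300)


@dataclass
class PerturbationPipelineResult:
    data: PerturbationData
    adata: ad.AnnData                  # QC-passed, normalised, clustered
    assignment: pd.DataFrame           # keep-decided guide assignment
    cluster_labels: pd.Series          # per-cell annotation base labels
    activation: ActivationProfile
    composition: CompositionResult
    enrichment: EnrichmentResult
    de: pd.DataFrame
    de_contrast: tuple[str, str]


def run_perturbation_pipeline(config: SimulationConfig,
                              qc: QCThresholds | None = None,
                              min_umi: int = 1,
                              resolution: float = 0.5,
                              alpha: float = 0.05,
                              data: PerturbationData | None = None,
                              ) -> PerturbationPipelineResult:
    """Simulate (or take) one perturbation dataset and run every read-out."""
    p = config.perturbation
    if data is None:
        data = simulate_perturbation_experiment(config)
    qc = qc or synthetic_qc_for(data.adata.n_vars)

    assignment = detect_guides(data.guide_capture, data.guide_library,
                               min_umi=min_umi,
                               barcodes=data.adata.obs_names)
    assignment = filter_cells_by_guides(assignment,
                                        data.adata.obs["library_type"])

    adata = qc_filter(data.adata, qc)
    kept = assignment.loc[assignment["keep"]].index.intersection(adata.obs_names)
    adata = adata[kept].copy()
    adata = normalise_log(adata)

    clusters = cluster_cells(adata, resolution=resolution, seed=config.seed)
    annotation = annotate_clusters(adata, clusters, DEFAULT_MARKER_PANELS)
    labels = annotation.cell_labels(clusters, base=True)
    adata.obs["cluster"] = clusters
    adata.obs["cluster_label"] = labels

    activation = activation_matrix(adata, assignment, list(p.targets))

    composition = compare_cluster_composition(
        adata.obs, cluster_col="cluster_label", alpha=alpha)

    agm_dox = adata.obs["library"] == "iSAM_AGM_DOX"
    enr_cells = assignment.loc[adata.obs_names[agm_dox]]
    enrichment = guide_enrichment(enr_cells, labels[agm_dox.to_numpy()],
                                  cluster="arterial", alpha=alpha)

    arterial = (labels == "arterial").to_numpy()
    mask_a = arterial & agm_dox.to_numpy()
    mask_b = arterial & (adata.obs["library"] == "iSAM_NT_DOX").to_numpy()
    de = differential_expression(adata, mask_a, mask_b)

    return PerturbationPipelineResult(
        data=data, adata=adata, assignment=assignment, cluster_labels=labels,
        activation=activation, composition=composition, enrichment=enrichment,
        de=de, de_contrast=("iSAM_AGM_DOX/arterial", "iSAM_NT_DOX/arterial"))


def run_candidate_discovery(config: SimulationConfig, tf_list=None,
                            **kwargs) -> pd.DataFrame:
    """Simulate the reference panel pair and run candidate discovery."""
    panel = simulate_reference_panel(config)
    tf_list = tf_list if tf_list is not None else config.reference.tf_list()
    return discover_candidates(panel.in_vivo, panel.in_vitro, tf_list, **kwargs)
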