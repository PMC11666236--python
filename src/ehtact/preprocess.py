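"""QC gating, normalisation, clustering, and marker-panel cluster annotation.

The QC gates follow the study design this package models: cells are retained
when both the number of detected genes and the mitochondrial-count percentage
fall inside closed intervals (defaults 1000-7500 genes and 1-15% mito for
real droplet data; the synthetic drivers use intervals scaled to the
generator's gene panel). Mitochondrial genes are identified by symbol prefix
(``MT-`` under the GRCh38 naming convention), configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_MITO_PREFIX = "MT-"


@dataclass
class QCThresholds:
    """Closed-interval QC gates on detected genes and mitochondrial %."""

    min_genes: int = 1000
    max_genes: int = 7500
    min_pct_mito: float = 1.0
    max_pct_mito: float = 15.0

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not self.min_pct_mito < self.max_pct_mito:
            raise ValueError("min_pct_mito must be < max_pct_mito")


def _counts_matrix(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.layers.get("counts", adata.X)
    return sp.csr_matrix(X)


def qc_metrics(adata: ad.AnnData, mito_prefix: str = DEFAULT_MITO_PREFIX) -> pd.DataFrame:
    """Per-cell n_genes_detected and pct_mito (in percent, 0-100)."""
    X = _counts_matrix(adata)
    if (X.data < 0).any():
        raise ValueError("counts must be non-negative")
    mito = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    if not mito.any():
        raise ValueError(
            f"no mitochondrial genes found with symbol prefix {mito_prefix!r}; "
            "set mito_prefix to match the gene namespace"
        )
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)
    return pd.DataFrame({"n_genes_detected": n_genes, "pct_mito": pct},
                        index=adata.obs_names)


def qc_filter(adata: ad.AnnData, thresholds: QCThresholds | None = None,
              mito_prefix: str = DEFAULT_MITO_PREFIX) -> ad.AnnData:
    """Retain cells inside both QC gates (bounds inclusive); genes unchanged.

    The returned object carries a ``uns["qc_report"]`` dict with cells
    before/after and per-rule drop counts. An empty result is a warning,
    not an error.
    """
    thresholds = thresholds or QCThresholds()
    metrics = qc_metrics(adata, mito_prefix=mito_prefix)
    genes_ok = metrics["n_genes_detected"].between(
        thresholds.min_genes, thresholds.max_genes, inclusive="both")
    mito_ok = metrics["pct_mito"].between(
        thresholds.min_pct_mito, thresholds.max_pct_mito, inclusive="both")
    keep = (genes_ok & mito_ok).to_numpy()
    report = {
        "n_before": int(adata.n_obs),
        "n_after": int(keep.sum()),
        "dropped_genes_gate": int((~genes_ok).sum()),
        "dropped_mito_gate": int((~mito_ok).sum()),
        "thresholds": vars(thresholds).copy(),
    }
    logger.info("QC: kept %d/%d cells (%d failed gene gate, %d failed mito gate)",
                report["n_after"], report["n_before"],
                report["dropped_genes_gate"], report["dropped_mito_gate"])
    if report["n_after"] == 0:
        logger.warning("QC removed every cell")
    out = adata[keep].copy()
    out.obs = out.obs.drop(columns=metrics.columns, errors="ignore").join(
        metrics.loc[keep])
    out.uns["qc_report"] = report
    return out


def normalise_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Depth-normalise to a common target sum and log1p-transform.

    Raw counts are preserved in ``layers["counts"]``, the linear normalised
    matrix in ``layers["normalised"]``, and ``X`` becomes
    ``log1p(target_sum * count / cell_total)``. Cells with zero total counts
    are an error (they cannot survive any sensible QC gate).
    """
    out = adata.copy()
    X = sp.csr_matrix(out.X)
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError(f"{int((totals == 0).sum())} cells have zero total counts")
    out.layers["counts"] = X.copy()
    norm = sp.diags(target_sum / totals) @ X
    out.layers["normalised"] = norm.tocsr()
    out.X = norm.log1p().tocsr()
    out.uns["target_sum"] = float(target_sum)
    return out


def cluster_cells(adata: ad.AnnData, resolution: float = 0.5, seed: int = 0,
                  n_pcs: int = 30, n_neighbors: int = 15) -> pd.Series:
    """Graph-based (Leiden) community detection on a PCA-reduced space.

    Deterministic given ``seed``; raises when fewer cells than the requested
    neighbourhood size are supplied. Returns per-cell string labels.
    """
    if adata.n_obs < 2:
        raise ValueError("clustering needs at least 2 cells")
    if adata.n_obs <= n_neighbors:
        raise ValueError(
            f"n_cells ({adata.n_obs}) must exceed n_neighbors ({n_neighbors})")
    work = adata.copy()
    n_comps = int(min(n_pcs, work.n_obs - 1, work.n_vars - 1))
    sc.pp.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(work, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.leiden(work, resolution=resolution, random_state=seed,
                 flavor="igraph", n_iterations=2, directed=False)
    return work.obs["leiden"].astype(str).rename("cluster")


@dataclass
class ClusterAnnotation:
    """Cluster -> label map with the marker evidence behind it.

    ``labels`` maps cluster id to a unique label (panel name, suffixed
    ``_1``, ``_2``, ... when several clusters share a winning panel);
    ``base_labels`` maps cluster id to the bare panel name; ``evidence``
    holds the mean z-scored expression of every panel marker per cluster.
    """

    labels: dict[str, str]
    base_labels: dict[str, str]
    evidence: pd.DataFrame

    def cell_labels(self, clusters: pd.Series, base: bool = True) -> pd.Series:
        mapping = self.base_labels if base else self.labels
        return clusters.map(mapping).rename("cluster_label")


def annotate_clusters(adata: ad.AnnData, clusters: pd.Series,
                      marker_panels: dict[str, list[str]]) -> ClusterAnnotation:
    """Label each cluster by its highest-scoring marker panel.

    Scores are mean z-scored (across cells) log-normalised expression of the
    panel's markers within the cluster; exact ties go to the earlier panel in
    ``marker_panels`` order. Markers absent from the matrix are an error.
    """
    if not marker_panels or any(len(v) == 0 for v in marker_panels.values()):
        raise ValueError("marker panels must be non-empty")
    all_markers = [g for panel in marker_panels.values() for g in panel]
    missing = sorted(set(all_markers) - set(adata.var_names))
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")

    X = adata[:, all_markers].X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    zdf = pd.DataFrame(Z, index=adata.obs_names, columns=pd.Index(all_markers))
    zdf = zdf.loc[:, ~zdf.columns.duplicated()]

    cluster_ids = sorted(clusters.unique(), key=str)
    evidence = pd.DataFrame(index=pd.Index(cluster_ids, name="cluster"),
                            columns=list(dict.fromkeys(all_markers)), dtype=float)
    panel_scores = pd.DataFrame(index=evidence.index,
                                columns=list(marker_panels), dtype=float)
    for cid in cluster_ids:
        mask = (clusters == cid).to_numpy()
        means = zdf.loc[mask].mean(axis=0)
        evidence.loc[cid] = means
        for pname, pgenes in marker_panels.items():
            panel_scores.loc[cid, pname] = means[list(dict.fromkeys(pgenes))].mean()

    base_labels, counts = {}, {}
    for cid in cluster_ids:
        row = panel_scores.loc[cid]
        best = row.max()
        # first panel in declaration order among exact ties
        winner = next(p for p in marker_panels if row[p] == best)
        base_labels[cid] = winner
        counts[winner] = counts.get(winner, 0) + 1
    labels, seen = {}, {}
    for cid in cluster_ids:
        b = base_labels[cid]
        if counts[b] == 1:
            labels[cid] = b
        else:
            seen[b] = seen.get(b, 0) + 1
            labels[cid] = f"{b}_{seen[b]}"
    return ClusterAnnotation(labels=labels, base_labels=base_labels,
                             evidence=evidence)
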