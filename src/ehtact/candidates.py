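"""Candidate transcription-factor discovery across a reference dataset pair.

The selection rule mirrors the cross-dataset screen this package models:
genes that mark the in vivo arterial haemogenic endothelium (two-sided
Wilcoxon rank-sum against the other in vivo endothelial cells, BH-adjusted),
restricted to annotated transcription factors, detected in more than half of
the in vivo haemogenic cells but in less than a quarter of the in vitro
derived endothelium. Detection fractions are computed within each dataset on
raw counts (count > 0), so no cross-dataset integration is required for the
gates; the marker test only ever compares cells of the in vivo panel.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._stats import bh_adjust, log2_ratio_of_means, rank_sum_test

DEFAULT_PSEUDOCOUNT = 1e-4


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def find_markers(adata: ad.AnnData, groupby: str, group: str,
                 min_cells: int = 3,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-gene rank-sum marker statistics of ``group`` vs the rest.

    Expects a log-normalised matrix in ``X`` and the linear normalised layer
    from :func:`ehtact.preprocess.normalise_log` (used for the effect size,
    a log2 ratio of group means). Returns a frame indexed by gene with
    columns ``stat``, ``log2fc``, ``pval``, ``pval_adj``, sorted by adjusted
    p then descending effect.
    """
    if groupby not in adata.obs:
        raise ValueError(f"missing obs column {groupby!r}")
    mask = (adata.obs[groupby] == group).to_numpy()
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < min_cells or n_out < min_cells:
        raise ValueError(
            f"degenerate group sizes: {n_in} in group, {n_out} in rest "
            f"(need >= {min_cells} each)")
    Xa, Xb = _dense(adata.X[mask]), _dense(adata.X[~mask])
    stat, pval = rank_sum_test(Xa, Xb)
    lin = adata.layers.get("normalised", adata.X)
    La, Lb = _dense(lin[mask]), _dense(lin[~mask])
    log2fc = log2_ratio_of_means(La.mean(axis=0), Lb.mean(axis=0), pseudocount)
    out = pd.DataFrame(
        {"stat": stat, "log2fc": log2fc, "pval": pval,
         "pval_adj": bh_adjust(pval)},
        index=adata.var_names.rename("gene"),
    )
    return out.sort_values(["pval_adj", "log2fc"], ascending=[True, False])


def fraction_detected(adata: ad.AnnData, cell_mask, gene: str) -> float:
    """Fraction of the given cells with a non-zero raw count for ``gene``."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} absent from matrix")
    return float(detection_fractions(adata, cell_mask)[gene])


def detection_fractions(adata: ad.AnnData, cell_mask) -> pd.Series:
    """Per-gene detection fraction (count > 0) over a non-empty cell subset."""
    mask = np.asarray(cell_mask)
    if mask.dtype != bool:
        raise ValueError("cell_mask must be boolean")
    if mask.sum() == 0:
        raise ValueError("empty cell subset")
    X = sp.csr_matrix(adata.layers.get("counts", adata.X))[mask]
    frac = np.asarray((X > 0).sum(axis=0)).ravel() / mask.sum()
    return pd.Series(frac, index=adata.var_names)


def select_candidates(markers: pd.DataFrame, frac_in_vivo: pd.Series,
                      frac_in_vitro: pd.Series, tf_list,
                      frac_hi: float = 0.50, frac_lo: float = 0.25,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Apply the TF + detection-fraction gates to marker statistics.

    A gene is selected iff it is a significant (BH-adjusted p < ``alpha``)
    positive marker, is an annotated TF, its in vivo haemogenic detection
    fraction strictly exceeds ``frac_hi`` and its in vitro endothelial
    fraction is strictly below ``frac_lo`` ("more than 50%" / "less than
    25%" read literally). An empty selection is a valid outcome.
    """
    if not tf_list:
        raise ValueError("tf_list must be non-empty")
    if not (0 < frac_hi < 1 and 0 < frac_lo < 1):
        raise ValueError("fraction thresholds must lie in (0, 1)")
    tf_set = set(tf_list)
    table = markers.copy()
    table["is_TF"] = [g in tf_set for g in table.index]
    table["frac_aHEC"] = frac_in_vivo.reindex(table.index)
    table["frac_IVD_Endo"] = frac_in_vitro.reindex(table.index)
    table["selected"] = (
        (table["pval_adj"] < alpha)
        & (table["log2fc"] > 0)
        & table["is_TF"]
        & (table["frac_aHEC"] > frac_hi)
        & (table["frac_IVD_Endo"] < frac_lo)
    )
    return table


def discover_candidates(in_vivo: ad.AnnData, in_vitro: ad.AnnData, tf_list,
                        hemogenic_group: str = "aHEC",
                        in_vitro_endo_group: str = "IVD_Endo",
                        frac_hi: float = 0.50, frac_lo: float = 0.25,
                        alpha: float = 0.05,
                        target_sum: float = 1e4) -> pd.DataFrame:
    """End-to-end candidate discovery on a labelled reference panel pair.

    ``in_vivo``/``in_vitro`` carry raw counts and an obs ``population``
    column. Shared gene symbols are used; fractions are computed per dataset.
    """
    from .preprocess import normalise_log

    shared = in_vivo.var_names.intersection(in_vitro.var_names)
    if len(shared) == 0:
        raise ValueError("gene namespaces do not intersect")
    vivo = normalise_log(in_vivo[:, shared].copy(), target_sum=target_sum)
    markers = find_markers(vivo, "population", hemogenic_group)
    frac_hi_series = detection_fractions(
        vivo, (vivo.obs["population"] == hemogenic_group).to_numpy())
    vitro = in_vitro[:, shared]
    frac_lo_series = detection_fractions(
        vitro, (vitro.obs["population"] == in_vitro_endo_group).to_numpy())
    return select_candidates(markers, frac_hi_series, frac_lo_series, tf_list,
                             frac_hi=frac_hi, frac_lo=frac_lo, alpha=alpha)
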