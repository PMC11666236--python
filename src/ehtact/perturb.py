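"""Perturbation statistics: activation, composition, enrichment, DE, ORA.

These are the downstream read-outs of the CRISPRa experiment: how strongly
each target gene responds to induction, whether any cell cluster expands,
whether particular guide classes concentrate in a cluster, which genes
change downstream, and which gene sets they over-represent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st

from ._stats import (bh_adjust, fisher_exact_2x2, hypergeom_overrep_p,
                     log2_ratio_of_means, rank_sum_test)

logger = logging.getLogger(__name__)

DEFAULT_COMPARISON = ("iSAM_AGM_DOX", "iSAM_NT_DOX")
DEFAULT_PAIRS = {
    "iSAM_NT": ("iSAM_NT_DOX", "iSAM_NT"),
    "iSAM_AGM": ("iSAM_AGM_DOX", "iSAM_AGM"),
}


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# activation matrix


@dataclass
class ActivationProfile:
    """Target x library activation read-out.

    ``means`` holds per-target, per-library mean linear-normalised expression
    (restricted to cells carrying a guide for the target in pool libraries);
    ``log2_ratio`` holds, per line, log2 of the +DOX mean over the matched
    -DOX mean with a stabilising pseudocount; ``missing`` flags entries with
    zero eligible cells (reported as NaN, never as zero).
    """

    means: pd.DataFrame
    log2_ratio: pd.DataFrame
    missing: pd.DataFrame
    pseudocount: float

    def activated_targets(self, line: str = "iSAM_AGM",
                          threshold: float = 0.5) -> list[str]:
        col = self.log2_ratio[line]
        return [t for t in col.index if abs(col[t]) > threshold]


def activation_matrix(adata: ad.AnnData, assignment: pd.DataFrame,
                      targets, library_col: str = "library",
                      pairs: dict | None = None,
                      restrict_carriers: bool = True,
                      pseudocount: float | None = None) -> ActivationProfile:
    """Mean target expression per library, normalised on the -DOX control.

    Only kept cells (``assignment["keep"]``) enter the means. In pool (AGM)
    libraries each target's mean runs over cells carrying at least one of
    its guides (unassigned cells would dilute the effect); set
    ``restrict_carriers=False`` for library-level means. The pseudocount
    defaults to 1/target_sum of the normalisation.
    """
    missing_t = [t for t in targets if t not in adata.var_names]
    if missing_t:
        raise ValueError(f"targets absent from gene namespace: {missing_t}")
    pairs = pairs or DEFAULT_PAIRS
    if pseudocount is None:
        pseudocount = 1.0 / adata.uns.get("target_sum", 1e4)

    kept = assignment[assignment["keep"]]
    sub = adata[adata.obs_names.isin(kept.index)]
    lin = _dense(sub[:, list(targets)].layers.get("normalised",
                                                  sub[:, list(targets)].X))
    libs = sub.obs[library_col].astype(str)
    carries = {}
    if restrict_carriers:
        det = kept["detected_targets"].reindex(sub.obs_names)
        for t in targets:
            carries[t] = np.array([t in dt for dt in det])

    lib_names = list(dict.fromkeys(libs))
    means = pd.DataFrame(index=pd.Index(targets, name="target"),
                         columns=lib_names, dtype=float)
    missing = pd.DataFrame(False, index=means.index, columns=lib_names)
    for lib in lib_names:
        in_lib = (libs == lib).to_numpy()
        is_pool = kept.loc[sub.obs_names[in_lib], "library_type"].iloc[0] == "AGM" \
            if in_lib.any() else False
        for j, t in enumerate(targets):
            mask = in_lib
            if restrict_carriers and is_pool:
                mask = in_lib & carries[t]
            if mask.sum() == 0:
                missing.loc[t, lib] = True
                means.loc[t, lib] = np.nan
            else:
                means.loc[t, lib] = lin[mask, j].mean()

    ratio = pd.DataFrame(index=means.index, columns=list(pairs), dtype=float)
    for line, (dox, ctrl) in pairs.items():
        ratio[line] = log2_ratio_of_means(
            means[dox].to_numpy(), means[ctrl].to_numpy(), pseudocount)
    return ActivationProfile(means=means, log2_ratio=ratio,
                             missing=missing, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# cluster composition


@dataclass
class CompositionResult:
    counts: pd.DataFrame          # cluster x library cell counts
    proportions: pd.DataFrame     # per-library proportions (columns sum to 1)
    table: pd.DataFrame           # per-cluster test results
    comparison: tuple[str, str]

    @property
    def expanded_clusters(self) -> list[str]:
        return list(self.table.index[self.table["expanded"]])


def compare_cluster_composition(obs: pd.DataFrame, cluster_col: str = "cluster_label",
                                library_col: str = "library",
                                alpha: float = 0.05,
                                comparison: tuple[str, str] = DEFAULT_COMPARISON,
                                min_expected: float = 5.0) -> CompositionResult:
    """Test each cluster for association between membership and library.

    Per cluster, a cluster-vs-rest x library contingency table is tested by
    chi-square (Fisher exact when the table is 2x2 and any expected count is
    below ``min_expected``); p-values are BH-adjusted across clusters. A
    cluster is flagged ``expanded`` when its adjusted p is below ``alpha``
    AND its proportion fold-change between the named ``comparison`` pair
    (perturbed over control) exceeds 1: the read-out of interest is an
    over-representation, and a significant association driven by shrinkage
    is reported as significant but not as an expansion.
    """
    libs = obs[library_col].astype(str)
    clusters = obs[cluster_col].astype(str)
    lib_names = list(dict.fromkeys(libs))
    if len(lib_names) < 2:
        raise ValueError("need at least 2 libraries")
    cluster_names = sorted(clusters.unique())
    if len(cluster_names) < 2:
        raise ValueError("need at least 2 clusters")
    for lib in comparison:
        if lib not in lib_names:
            raise ValueError(f"comparison library {lib!r} not present")

    counts = pd.crosstab(clusters, libs).reindex(
        index=cluster_names, columns=lib_names, fill_value=0)
    props = counts / counts.sum(axis=0)

    rows = []
    for cl in cluster_names:
        in_cl = counts.loc[cl].to_numpy()
        out_cl = counts.sum(axis=0).to_numpy() - in_cl
        table = np.vstack([in_cl, out_cl])
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        sparse = (expected < min_expected).any() or (table < min_expected).any()
        if table.shape == (2, 2) and sparse:
            _, p = fisher_exact_2x2(table)
            stat, method = np.nan, "fisher"
        else:
            if sparse:
                logger.warning(
                    "cluster %s: expected counts < %g in a %dx%d table; "
                    "chi-square approximation used", cl, min_expected, *table.shape)
            stat, p, _, _ = st.chi2_contingency(table, correction=False)
            method = "chi2"
        fc_num = props.loc[cl, comparison[0]]
        fc_den = props.loc[cl, comparison[1]]
        fold = np.inf if fc_den == 0 and fc_num > 0 else (
            np.nan if fc_den == 0 else fc_num / fc_den)
        rows.append({"cluster": cl, "stat": stat, "pval": p, "method": method,
                     "prop_fold_change": fold})
    table_df = pd.DataFrame(rows).set_index("cluster")
    table_df["pval_adj"] = bh_adjust(table_df["pval"])
    table_df["significant"] = table_df["pval_adj"] < alpha
    table_df["expanded"] = table_df["significant"] & (table_df["prop_fold_change"] > 1)
    return CompositionResult(counts=counts, proportions=props, table=table_df,
                             comparison=tuple(comparison))


# ---------------------------------------------------------------------------
# guide enrichment


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    cluster: str

    @property
    def enriched(self) -> list[str]:
        return list(self.table.index[self.table["enriched"]])


def guide_enrichment(assignment: pd.DataFrame, cluster_labels: pd.Series,
                     cluster: str, grouping: str = "by_target",
                     alpha: float = 0.05) -> EnrichmentResult:
    """Fisher exact test of guide (or target) carriage vs cluster membership.

    ``assignment`` must contain kept cells only or a decided ``keep`` column
    (dropped cells are excluded); ``cluster_labels`` maps the same barcodes
    to cluster labels. Per target (default) or per guide, the 2x2 table
    [carrier/non-carrier x in/out of cluster] is tested two-sided, BH across
    units, with a Haldane-corrected odds ratio; ``enriched`` requires
    adjusted p < alpha and OR > 1.
    """
    if grouping not in ("by_target", "by_guide"):
        raise ValueError("grouping must be 'by_target' or 'by_guide'")
    cells = assignment[assignment["keep"]] if "keep" in assignment.columns else assignment
    labels = cluster_labels.reindex(cells.index)
    if labels.isna().any():
        raise ValueError("cluster_labels missing for some kept cells")
    in_cluster = (labels == cluster).to_numpy()
    if in_cluster.sum() == 0:
        raise ValueError(f"cluster {cluster!r} has zero cells")

    col = "detected_targets" if grouping == "by_target" else "detected_guides"
    units = sorted({u for us in cells[col] for u in us})
    rows = []
    for u in units:
        carrier = np.array([u in us for us in cells[col]])
        a = int((carrier & in_cluster).sum())
        b = int((carrier & ~in_cluster).sum())
        c = int((~carrier & in_cluster).sum())
        d = int((~carrier & ~in_cluster).sum())
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"unit": u, "in_cluster_carriers": a,
                     "out_cluster_carriers": b, "in_cluster_noncarriers": c,
                     "out_cluster_noncarriers": d, "odds_ratio": odds, "pval": p})
    table = pd.DataFrame(rows).set_index("unit")
    table["pval_adj"] = bh_adjust(table["pval"])
    table["enriched"] = (table["pval_adj"] < alpha) & (table["odds_ratio"] > 1)
    return EnrichmentResult(table=table, cluster=cluster)


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(adata: ad.AnnData, mask_a, mask_b,
                            min_cells: int = 3,
                            pseudocount: float | None = None) -> pd.DataFrame:
    """Two-sided rank-sum DE between two disjoint cell sets.

    Returns a frame indexed by gene with ``log2fc`` (A over B on linear
    normalised means), ``pval``, ``pval_adj``, ``direction`` (up/down for
    A relative to B), sorted by adjusted p then descending effect.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if (mask_a & mask_b).any():
        raise ValueError("cell sets A and B overlap")
    if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
        raise ValueError(f"both cell sets need >= {min_cells} cells")
    if pseudocount is None:
        pseudocount = 1.0 / adata.uns.get("target_sum", 1e4)
    Xa, Xb = _dense(adata.X[mask_a]), _dense(adata.X[mask_b])
    stat, pval = rank_sum_test(Xa, Xb)
    lin = adata.layers.get("normalised", adata.X)
    log2fc = log2_ratio_of_means(_dense(lin[mask_a]).mean(axis=0),
                                 _dense(lin[mask_b]).mean(axis=0), pseudocount)
    out = pd.DataFrame(
        {"stat": stat, "log2fc": log2fc, "pval": pval,
         "pval_adj": bh_adjust(pval),
         "direction": np.where(log2fc >= 0, "up", "down")},
        index=adata.var_names.rename("gene"))
    return out.sort_values(["pval_adj", "log2fc"], ascending=[True, False])


# ---------------------------------------------------------------------------
# gene-set over-representation


def gene_set_overrepresentation(gene_list, gene_sets: dict[str, list[str]],
                                universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    ``universe`` must contain every tested gene; sets with an empty
    intersection with the universe are skipped with a warning. Returns a
    frame per set with overlap counts, p, BH-adjusted p, sorted by p.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        members_u = set(members) & universe
        if not members_u:
            logger.warning("gene set %s has no overlap with the universe; skipped", name)
            continue
        k = len(genes & members_u)
        p = hypergeom_overrep_p(k, len(members_u), len(genes), len(universe))
        rows.append({"gene_set": name, "set_size": len(members_u),
                     "n_hits": k, "n_input": len(genes), "pval": p})
    if not rows:
        return pd.DataFrame(
            columns=["set_size", "n_hits", "n_input", "pval", "pval_adj"],
            index=pd.Index([], name="gene_set"))
    out = pd.DataFrame(rows).set_index("gene_set")
    out["pval_adj"] = bh_adjust(out["pval"])
    return out.sort_values("pval")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, ""] + list(members)) + "\n")
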