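"""QC gates, normalisation arithmetic, clustering and annotation behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from ehtact.preprocess import (QCThresholds, annotate_clusters, cluster_cells,
                               normalise_log, qc_filter, qc_metrics)

from .conftest import make_adata


def _adata_with_genes_detected(n_detected_per_cell, n_genes=8000, mito_frac=0.05):
    """Cells detecting exactly the requested number of genes, ~5% mito counts."""
    genes = ["MT-X"] + [f"G{i}" for i in range(n_genes - 1)]
    rows = []
    for nd in n_detected_per_cell:
        row = np.zeros(n_genes)
        row[1:nd] = 1          # nd - 1 nuclear genes
        row[0] = max(1, round((nd - 1) * mito_frac / (1 - mito_frac)))  # mito gene
        rows.append(row)
    return make_adata(np.array(rows), genes=genes)


class TestQCFilter:
    def test_gene_gate_boundaries_inclusive(self):
        adata = _adata_with_genes_detected([999, 1000, 4000, 7500, 7501])
        out = qc_filter(adata, QCThresholds())
        kept = set(out.obs_names)
        assert kept == {"c1", "c2", "c3"}  # 1000, 4000 and 7500 kept
        assert out.uns["qc_report"]["n_before"] == 5

    def test_all_in_bounds_is_identity(self):
        adata = _adata_with_genes_detected([2000, 3000, 4000])
        out = qc_filter(adata, QCThresholds())
        assert list(out.obs_names) == list(adata.obs_names)
        assert (out.X != adata.X).nnz == 0

    def test_planted_out_of_bounds_cells_exactly_dropped(self):
        # enumerate per-cell statistics directly and compare with the filter
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(200, 400))
        counts[:, :4] = rng.poisson(3.0, size=(200, 4))  # mito genes
        genes = [f"MT-{i}" for i in range(4)] + [f"G{i}" for i in range(396)]
        adata = make_adata(counts, genes=genes)
        th = QCThresholds(min_genes=100, max_genes=300,
                          min_pct_mito=1.0, max_pct_mito=8.0)
        m = qc_metrics(adata)
        expect = (
            (m.n_genes_detected >= 100) & (m.n_genes_detected <= 300)
            & (m.pct_mito >= 1.0) & (m.pct_mito <= 8.0))
        out = qc_filter(adata, th)
        assert list(out.obs_names) == list(adata.obs_names[expect.to_numpy()])

    def test_missing_mito_genes_error_names_prefix(self):
        adata = make_adata(np.ones((3, 5)))
        with pytest.raises(ValueError, match="MT-"):
            qc_filter(adata, QCThresholds(min_genes=1, max_genes=10))

    def test_idempotent(self):
        adata = _adata_with_genes_detected([500, 2000, 9000])
        once = qc_filter(adata, QCThresholds())
        twice = qc_filter(once, QCThresholds())
        assert list(once.obs_names) == list(twice.obs_names)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(lo=hst.integers(500, 2000), width=hst.integers(1, 6000))
    def test_widening_gene_gate_monotone(self, lo, width):
        adata = _adata_with_genes_detected([700, 1500, 2500, 5000, 8000])
        narrow = qc_filter(adata, QCThresholds(lo, lo + width, 0.5, 50.0))
        wide = qc_filter(adata, QCThresholds(max(1, lo - 300), lo + width + 300,
                                             0.5, 50.0))
        assert set(narrow.obs_names) <= set(wide.obs_names)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            QCThresholds(min_genes=10, max_genes=10)
        with pytest.raises(ValueError):
            QCThresholds(min_pct_mito=15, max_pct_mito=1)


class TestNormaliseLog:
    def test_hand_3x3(self):
        counts = np.array([[1, 2, 3], [0, 5, 0], [4, 0, 4]])
        out = normalise_log(make_adata(counts), target_sum=100.0)
        totals = counts.sum(axis=1, keepdims=True)
        expect = np.log1p(100.0 * counts / totals)
        np.testing.assert_allclose(out.X.toarray(), expect, rtol=1e-12)

    def test_single_gene_cell_carries_target_sum(self):
        counts = np.array([[0, 7, 0], [1, 1, 1]])
        out = normalise_log(make_adata(counts), target_sum=1e4)
        assert out.layers["normalised"].toarray()[0, 1] == pytest.approx(1e4)

    def test_depth_scale_invariance(self):
        base = np.array([[1, 2, 3], [2, 0, 1]])
        a = normalise_log(make_adata(base))
        b = normalise_log(make_adata(base * 2))
        np.testing.assert_allclose(a.X.toarray(), b.X.toarray(), rtol=1e-12)

    def test_zero_total_cell_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            normalise_log(make_adata(np.array([[0, 0], [1, 2]])))


def _two_population_adata(n=300, shift=6.0, seed=0, n_genes=40):
    rng = np.random.default_rng(seed)
    mean = np.full(n_genes, 0.5)
    a = rng.poisson(mean, size=(n, n_genes))
    mean_b = mean.copy()
    mean_b[:5] += shift
    b = rng.poisson(mean_b, size=(n, n_genes))
    counts = np.vstack([a, b]) + 1  # avoid zero-total cells
    adata = make_adata(counts)
    adata.obs["truth"] = ["A"] * n + ["B"] * n
    return normalise_log(adata)


class TestClustering:
    def test_two_separated_populations_recovered(self):
        adata = _two_population_adata()
        labels = cluster_cells(adata, resolution=0.3, seed=0)
        assert labels.nunique() == 2
        purity = (pd.crosstab(labels, adata.obs["truth"]).max(axis=1).sum()
                  / len(labels))
        assert purity >= 0.99

    def test_homogeneous_population_single_cluster(self):
        rng = np.random.default_rng(1)
        adata = normalise_log(make_adata(rng.poisson(2.0, size=(200, 30)) + 1))
        labels = cluster_cells(adata, resolution=0.05, seed=0)
        assert labels.nunique() == 1

    def test_resolution_weakly_increases_cluster_count(self):
        adata = _two_population_adata()
        n_low = cluster_cells(adata, resolution=0.1, seed=0).nunique()
        n_high = cluster_cells(adata, resolution=1.5, seed=0).nunique()
        assert n_low <= n_high

    def test_deterministic_given_seed(self):
        adata = _two_population_adata()
        l1 = cluster_cells(adata, resolution=0.5, seed=3)
        l2 = cluster_cells(adata, resolution=0.5, seed=3)
        assert (l1 == l2).all()

    def test_cell_permutation_invariant_up_to_renaming(self):
        from sklearn.metrics import adjusted_rand_score
        adata = _two_population_adata()
        perm = np.random.default_rng(5).permutation(adata.n_obs)
        l1 = cluster_cells(adata, resolution=0.3, seed=0)
        l2 = cluster_cells(adata[perm].copy(), resolution=0.3, seed=0)
        assert adjusted_rand_score(l1.to_numpy(),
                                   l2.reindex(l1.index).to_numpy()) >= 0.99

    def test_too_few_cells_errors(self):
        adata = _two_population_adata(n=5)
        with pytest.raises(ValueError, match="n_neighbors"):
            cluster_cells(adata, n_neighbors=15)


class TestAnnotation:
    PANELS = {"arterial": ["GJA4", "DLL4"], "venous": ["NRP2", "APLNR"]}

    def _adata(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = ["GJA4", "DLL4", "NRP2", "APLNR"] + [f"G{i}" for i in range(6)]
        art = rng.poisson([5, 5, 0.2, 0.2] + [1] * 6, size=(50, 10))
        ven = rng.poisson([0.2, 0.2, 5, 5] + [1] * 6, size=(50, 10))
        adata = make_adata(np.vstack([art, ven]) + 1, genes=genes)
        return normalise_log(adata)

    def test_planted_marker_programs_recovered(self):
        adata = self._adata()
        clusters = pd.Series(["0"] * 50 + ["1"] * 50, index=adata.obs_names)
        ann = annotate_clusters(adata, clusters, self.PANELS)
        assert ann.labels == {"0": "arterial", "1": "venous"}
        assert set(ann.evidence.columns) == {"GJA4", "DLL4", "NRP2", "APLNR"}

    def test_exact_tie_goes_to_first_panel(self):
        # identical expression everywhere -> all panel scores equal
        adata = normalise_log(make_adata(
            np.ones((20, 4), dtype=int), genes=["GJA4", "DLL4", "NRP2", "APLNR"]))
        clusters = pd.Series(["0"] * 10 + ["1"] * 10, index=adata.obs_names)
        ann = annotate_clusters(adata, clusters, self.PANELS)
        assert ann.base_labels["0"] == "arterial"  # first in declaration order

    def test_duplicate_winner_gets_suffixes(self):
        adata = self._adata()
        clusters = pd.Series(["0"] * 25 + ["1"] * 25 + ["2"] * 50,
                             index=adata.obs_names)
        ann = annotate_clusters(adata, clusters, self.PANELS)
        assert ann.base_labels == {"0": "arterial", "1": "arterial", "2": "venous"}
        assert ann.labels["0"] == "arterial_1" and ann.labels["1"] == "arterial_2"

    def test_missing_marker_is_error_listing_symbols(self):
        adata = self._adata()
        with pytest.raises(ValueError, match="RUNX1"):
            annotate_clusters(adata, pd.Series("0", index=adata.obs_names),
                              {"EHT": ["RUNX1", "CD44"]})
        with pytest.raises(ValueError, match="non-empty"):
            annotate_clusters(adata, pd.Series("0", index=adata.obs_names),
                              {"EHT": []})
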