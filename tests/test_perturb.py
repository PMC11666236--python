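"""Activation, composition, enrichment, DE, and over-representation tests."""

import numpy as np
import pandas as pd
import pytest

from ehtact._stats import bh_adjust, fisher_exact_2x2
from ehtact.config import SimulationConfig
from ehtact.perturb import (compare_cluster_composition,
                            differential_expression,
                            gene_set_overrepresentation, guide_enrichment,
                            read_gmt, write_gmt)
from ehtact.preprocess import normalise_log
from ehtact.simulate import simulate_timecourse

from .conftest import make_adata
from .oracles import (bh_oracle, fisher_two_sided_oracle,
                      hypergeom_upper_tail_oracle,
                      rank_sum_permutation_oracle)


class TestExactTestOracles:
    def test_extreme_2x2_table_matches_hypergeometric_tail(self):
        # (10,0 / 0,10): two-sided p is twice the single most extreme table
        _, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(1.0 / 92378, rel=1e-9)
        assert p == pytest.approx(fisher_two_sided_oracle(10, 0, 0, 10), rel=1e-9)

    @pytest.mark.parametrize("table", [(3, 7, 9, 1), (5, 5, 5, 5), (0, 8, 2, 6),
                                       (1, 0, 0, 1), (12, 3, 2, 13)])
    def test_small_tables_match_enumeration(self, table):
        a, b, c, d = table
        _, p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-8)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, size=4)
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                      rel=1e-8, abs=1e-12)

    def test_bh_matches_direct_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)
        assert (bh_adjust(np.array([0.01, 0.02, 0.5]))
                >= np.array([0.01, 0.02, 0.5])).all()


class TestComposition:
    def _obs(self, counts: dict):
        rows = []
        for (cluster, lib), n in counts.items():
            rows += [{"cluster_label": cluster, "library": lib}] * n
        return pd.DataFrame(rows)

    def test_extreme_2x2_uses_exact_test(self):
        obs = self._obs({("A", "L1"): 10, ("B", "L2"): 10})
        res = compare_cluster_composition(obs, comparison=("L1", "L2"),
                                          alpha=0.05)
        # cluster-vs-rest table per cluster is (10,0 / 0,10)
        assert (res.table["method"] == "fisher").all()
        assert res.table["pval"].iloc[0] == pytest.approx(1 / 92378, rel=1e-9)

    def test_planted_expansion_flags_only_expanded_cluster(self):
        rng = np.random.default_rng(2)
        obs = pd.concat([
            pd.DataFrame({"cluster_label": rng.choice(
                ["arterial", "venous", "EHT"], 2000, p=[0.50, 0.32, 0.18]),
                "library": "iSAM_AGM_DOX"}),
            pd.DataFrame({"cluster_label": rng.choice(
                ["arterial", "venous", "EHT"], 2000, p=[0.24, 0.49, 0.27]),
                "library": "iSAM_NT_DOX"}),
        ])
        res = compare_cluster_composition(obs)
        assert res.expanded_clusters == ["arterial"]
        # shrinking clusters are significant but not reported as expansions
        assert res.table.loc["venous", "significant"]
        assert not res.table.loc["venous", "expanded"]

    def test_proportions_sum_to_one_and_counts_integral(self):
        obs = self._obs({("A", "L1"): 5, ("B", "L1"): 7, ("A", "L2"): 3,
                         ("B", "L2"): 9})
        res = compare_cluster_composition(obs, comparison=("L1", "L2"))
        np.testing.assert_allclose(res.proportions.sum(axis=0), 1.0, atol=1e-9)
        assert res.counts.to_numpy().sum() == 24

    def test_single_library_errors(self):
        obs = self._obs({("A", "L1"): 5, ("B", "L1"): 5})
        with pytest.raises(ValueError, match="2 libraries"):
            compare_cluster_composition(obs, comparison=("L1", "L1"))

    def test_null_composition_rarely_flags(self):
        # exchangeable libraries: no cluster should be called expanded
        flags = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            obs = pd.DataFrame({
                "cluster_label": rng.choice(["A", "B", "C"], 1200, p=[0.2, 0.5, 0.3]),
                "library": rng.choice(["iSAM_AGM_DOX", "iSAM_NT_DOX"], 1200),
            })
            flags += len(compare_cluster_composition(obs).expanded_clusters)
        assert flags <= 1


def _assignment(targets_per_cell, keep=True):
    df = pd.DataFrame({
        "detected_targets": [tuple(t) for t in targets_per_cell],
        "detected_guides": [tuple(f"{x}_g1" for x in t) for t in targets_per_cell],
        "n_guides": [len(t) for t in targets_per_cell],
    }, index=[f"c{i}" for i in range(len(targets_per_cell))])
    df["keep"] = keep
    return df


class TestGuideEnrichment:
    def test_small_table_matches_enumeration(self):
        # 3 of 10 in-cluster cells carry the target vs 9 of 10 outside
        targets = [("T1",)] * 3 + [()] * 7 + [("T1",)] * 9 + [()] * 1
        labels = pd.Series(["arterial"] * 10 + ["other"] * 10,
                           index=[f"c{i}" for i in range(20)])
        res = guide_enrichment(_assignment(targets), labels, "arterial")
        assert res.table.loc["T1", "pval"] == pytest.approx(
            fisher_two_sided_oracle(3, 9, 7, 1), rel=1e-9)
        assert not res.enriched  # depletion, not enrichment

    def test_balanced_carriage_is_null(self):
        targets = ([("T1",)] * 20 + [()] * 20) * 2
        labels = pd.Series(["arterial"] * 40 + ["other"] * 40,
                           index=[f"c{i}" for i in range(80)])
        res = guide_enrichment(_assignment(targets), labels, "arterial")
        assert res.table.loc["T1", "odds_ratio"] == pytest.approx(1.0)
        assert res.table.loc["T1", "pval"] == pytest.approx(1.0)

    def test_missing_cluster_errors(self):
        targets = [("T1",), ()]
        labels = pd.Series(["a", "b"], index=["c0", "c1"])
        with pytest.raises(ValueError, match="zero cells"):
            guide_enrichment(_assignment(targets), labels, "arterial")

    def test_planted_driver_enrichment_detected(self):
        rng = np.random.default_rng(4)
        n = 2000
        arterial = rng.random(n) < 0.4
        # driver carried by 60% of arterial cells, 30% elsewhere; decoy flat 30%
        driver = np.where(arterial, rng.random(n) < 0.6, rng.random(n) < 0.3)
        decoy = rng.random(n) < 0.3
        targets = [tuple(t for t, keep in (("RUNX1T1", driver[i]), ("GATA2", decoy[i]))
                         if keep) for i in range(n)]
        labels = pd.Series(np.where(arterial, "arterial", "other"),
                           index=[f"c{i}" for i in range(n)])
        res = guide_enrichment(_assignment(targets), labels, "arterial")
        assert res.enriched == ["RUNX1T1"]


class TestDifferentialExpression:
    def test_toy_input_matches_permutation_oracle(self):
        xa, xb = [9.0, 12.0, 15.0], [1.0, 4.0, 6.0]
        counts = np.column_stack([np.concatenate([xa, xb]),
                                  np.full(6, 30.0)]).astype(int)
        adata = normalise_log(make_adata(counts, genes=["G", "CONST"]))
        table = differential_expression(adata, np.arange(6) < 3, np.arange(6) >= 3)
        assert table.loc["G", "pval"] == pytest.approx(
            rank_sum_permutation_oracle(xa, xb), rel=1e-9)
        assert table.loc["G", "direction"] == "up"

    def test_null_contrast_flags_nothing(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(2.0, size=(400, 100)) + 1
        adata = normalise_log(make_adata(counts))
        table = differential_expression(adata, np.arange(400) < 200,
                                        np.arange(400) >= 200)
        assert (table["pval_adj"] < 0.05).sum() <= 2

    def test_overlapping_sets_error(self):
        adata = normalise_log(make_adata(np.ones((6, 3), dtype=int)))
        mask = np.arange(6) < 4
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(adata, mask, mask)

    def test_planted_effector_ranks_first(self):
        cfg = SimulationConfig(seed=31)
        cfg.perturbation.n_cells_per_library = 600
        cfg.perturbation.n_genes = 120
        from ehtact.pipeline import run_perturbation_pipeline
        res = run_perturbation_pipeline(cfg)
        assert res.de.index[0] == "IGFBP2"
        assert res.de["log2fc"].iloc[0] > 0


class TestOverrepresentation:
    def test_input_list_itself_is_top_set(self):
        universe = [f"G{i}" for i in range(100)]
        sets = {"SELF": universe[:10], "OTHER": universe[50:90]}
        table = gene_set_overrepresentation(universe[:10], sets, universe)
        assert table.index[0] == "SELF"
        assert table.loc["SELF", "pval"] == pytest.approx(
            hypergeom_upper_tail_oracle(10, 10, 10, 100), rel=1e-9)

    def test_null_input_uniform_p(self):
        rng = np.random.default_rng(7)
        universe = [f"G{i}" for i in range(400)]
        sets = {f"S{i}": list(rng.choice(universe, 30, replace=False))
                for i in range(30)}
        ps = []
        for seed in range(20):
            draw = list(np.random.default_rng(seed).choice(universe, 40,
                                                           replace=False))
            ps.extend(gene_set_overrepresentation(draw, sets, universe)["pval"])
        ps = np.asarray(ps)
        # discrete p-values are stochastically >= uniform under the null
        assert (ps < 0.05).mean() < 0.08
        assert ps.mean() > 0.4

    def test_disjoint_set_skipped_and_subset_enforced(self):
        universe = ["A", "B", "C"]
        table = gene_set_overrepresentation(["A"], {"S": ["Z9"]}, universe)
        assert len(table) == 0
        with pytest.raises(ValueError, match="subset"):
            gene_set_overrepresentation(["Q"], {"S": ["A"]}, universe)

    def test_planted_oxphos_program_top_ranked(self, tmp_path):
        cfg = SimulationConfig(seed=9)
        cfg.timecourse.n_cells_per_condition = 400
        adata = normalise_log(simulate_timecourse(cfg))
        day13 = adata.obs["day"] == "day13"
        table = differential_expression(
            adata, (day13 & (adata.obs.treatment == "IGFBP2")).to_numpy(),
            (day13 & (adata.obs.treatment == "CTR")).to_numpy())
        up = list(table.index[(table.pval_adj < 0.05) & (table.log2fc > 0.5)])
        rng = np.random.default_rng(0)
        sets = {"OXPHOS": list(cfg.timecourse.oxphos_genes),
                "GLYCOLYSIS": list(cfg.timecourse.glyco_genes)}
        for i in range(10):
            sets[f"RANDOM_{i}"] = list(rng.choice(adata.var_names, 12, replace=False))
        gmt = tmp_path / "sets.gmt"
        write_gmt(sets, gmt)
        ora = gene_set_overrepresentation(up, read_gmt(gmt), list(adata.var_names))
        assert ora.index[0] == "OXPHOS"
        assert ora.loc["OXPHOS", "pval_adj"] < 0.05


class TestActivationMatrix:
    def test_identity_and_planted_folds(self):
        cfg = SimulationConfig(seed=19)
        cfg.perturbation.n_cells_per_library = 800
        cfg.perturbation.n_genes = 120
        from ehtact.pipeline import run_perturbation_pipeline
        res = run_perturbation_pipeline(cfg)
        ratio = res.activation.log2_ratio
        null_t = res.data.truth.targets.index[res.data.truth.targets.is_null][0]
        assert abs(ratio.loc[null_t, "iSAM_AGM"]) < 0.25
        active = res.data.truth.targets.index[~res.data.truth.targets.is_null]
        # 2-fold planted activation recovered within simulation tolerance
        assert ratio.loc[active, "iSAM_AGM"].between(0.5, 1.5).all()
        # NT line saw no activation at all
        assert ratio["iSAM_NT"].abs().max() < 0.4

    def test_no_eligible_cells_flagged_missing_not_zero(self):
        counts = np.ones((4, 2), dtype=int) * 3
        adata = normalise_log(make_adata(counts, genes=["T1", "CONST"]))
        adata.obs["library"] = ["iSAM_AGM", "iSAM_AGM", "iSAM_AGM_DOX", "iSAM_AGM_DOX"]
        asn = _assignment([(), (), (), ()])
        asn.index = adata.obs_names
        asn["library_type"] = "AGM"
        from ehtact.perturb import activation_matrix
        prof = activation_matrix(adata, asn, ["T1"],
                                 pairs={"iSAM_AGM": ("iSAM_AGM_DOX", "iSAM_AGM")})
        assert prof.missing.loc["T1"].all()
        assert np.isnan(prof.means.loc["T1"]).all()
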