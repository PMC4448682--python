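"""CELF/MBNL co-binding enrichment, site distances and grouped expression."""

import numpy as np
import pandas as pd
import pytest

from spliceclip.cobinding import (
    cobinding_enrichment, development_grouping, distance_shift_test,
    expression_comparison_table, locate_binding_sites, min_distance_distribution,
    proximal_pair_expression,
)
from spliceclip.events import BindingSite


class TestLocateSites:
    def test_celf_motif_scan(self):
        sites = locate_binding_sites("AATGTTAA", "CELF1", "g")
        assert sorted(s.position for s in sites) == [1, 2]  # ATGT, TGTT
        assert all(s.source == "motif_in_cluster" for s in sites)

    def test_center_fallback(self):
        (site,) = locate_binding_sites("AAAAAAAA", "MBNL1", "g")
        assert site.position == 4 and site.source == "cluster_center"

    def test_cluster_offset_applied(self):
        (site,) = locate_binding_sites("AAAAAAAA", "MBNL1", "g", cluster_offset=100)
        assert site.position == 104

    def test_empty_motif_list_rejected(self):
        with pytest.raises(ValueError, match="no motifs"):
            locate_binding_sites("ACGT", "CELF1", "g", motifs={"CELF1": []})

    def test_rna_alphabet_accepted(self):
        sites = locate_binding_sites("AAUGUUAA", "CELF1", "g")
        assert sorted(s.position for s in sites) == [1, 2]


class TestCobindingEnrichment:
    def test_all_genes_targets_ratio_one(self, rng):
        genes = [f"g{i}" for i in range(100)]
        expr = pd.Series(rng.lognormal(size=100), index=genes)
        table, summary = cobinding_enrichment(genes, genes, expr, n_bins=5)
        assert np.allclose(table["ratio"], 1.0)

    def test_independent_assignment_near_unity(self, rng):
        genes = [f"g{i}" for i in range(300)]
        expr = pd.Series(rng.lognormal(size=300), index=genes)
        ratios = []
        for _ in range(30):
            a = set(rng.choice(genes, 90, replace=False))
            b = set(rng.choice(genes, 90, replace=False))
            _, s = cobinding_enrichment(a, b, expr, n_bins=5)
            ratios.append(s["pooled_ratio"])
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_planted_cooccurrence_recovered(self):
        """Generator-planted threefold overlap is recovered from truth sets."""
        from spliceclip.synthetic import SimulationConfig, simulate_annotation
        ann = simulate_annotation(SimulationConfig(n_genes=800, seed=47))
        rng = np.random.default_rng(0)
        genes = [g.gene_id for g in ann.genes]
        expr = pd.Series(rng.lognormal(size=len(genes)), index=genes)
        _, s = cobinding_enrichment(ann.truth.celf_targets,
                                    ann.truth.mbnl_targets, expr, n_bins=10)
        assert 2.4 < s["pooled_ratio"] < 3.6

    def test_too_many_bins_rejected(self, rng):
        expr = pd.Series(rng.lognormal(size=5), index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="n_bins"):
            cobinding_enrichment([], [], expr, n_bins=10)


def brute_force_distances(sites):
    """All-pairs scan: for every site, min distance to the other protein."""
    by_gene = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)
    out = []
    for gene, ss in sorted(by_gene.items()):
        for s in ss:
            others = [t for t in ss if t.protein != s.protein]
            if others:
                out.append(min(abs(s.position - t.position) for t in others))
    return sorted(out)


class TestDistances:
    def test_single_pair_distance(self):
        sites = [BindingSite("CELF1", "g", 10, "motif_in_cluster"),
                 BindingSite("MBNL1", "g", 60, "motif_in_cluster")]
        res = min_distance_distribution(sites, {"g": 100})
        assert set(res["distances"]) == {50}

    def test_one_protein_utrs_excluded_and_counted(self):
        sites = [BindingSite("CELF1", "g1", 10, "motif_in_cluster"),
                 BindingSite("CELF1", "g2", 10, "motif_in_cluster"),
                 BindingSite("MBNL1", "g2", 30, "motif_in_cluster")]
        res = min_distance_distribution(sites, {"g1": 100, "g2": 100})
        assert res["n_excluded_utrs"] == 1

    def test_identity_shuffle_preserves_single_pair_distances(self):
        sites = [BindingSite("CELF1", "g", 10, "motif_in_cluster"),
                 BindingSite("MBNL1", "g", 60, "motif_in_cluster")]
        obs = min_distance_distribution(sites, {"g": 100})
        shuf = min_distance_distribution(sites, {"g": 100},
                                         null="identity_shuffle", seed=1)
        assert sorted(obs["distances"]) == sorted(shuf["distances"])

    def test_matches_brute_force_oracle(self, rng):
        sites = []
        for gi in range(200):
            for p, n in (("CELF1", rng.integers(1, 4)), ("MBNL1", rng.integers(1, 4))):
                for pos in rng.integers(0, 600, int(n)):
                    sites.append(BindingSite(p, f"g{gi}", int(pos),
                                             "motif_in_cluster"))
        res = min_distance_distribution(sites, {f"g{i}": 600 for i in range(200)})
        assert sorted(res["distances"]) == brute_force_distances(sites)

    def test_per_utr_min_mode(self):
        sites = [BindingSite("CELF1", "g", 10, "m"),
                 BindingSite("CELF1", "g", 200, "m"),
                 BindingSite("MBNL1", "g", 60, "m")]
        res = min_distance_distribution(sites, {"g": 300}, mode="per_utr_min")
        assert list(res["distances"]) == [50]

    def test_random_placement_seeded(self):
        sites = [BindingSite("CELF1", "g", 10, "m"),
                 BindingSite("MBNL1", "g", 60, "m")]
        a = min_distance_distribution(sites, {"g": 500},
                                      null="random_placement", seed=3)
        b = min_distance_distribution(sites, {"g": 500},
                                      null="random_placement", seed=3)
        assert list(a["distances"]) == list(b["distances"])


class TestDistanceShift:
    def test_same_distribution_no_call(self, rng):
        x = rng.uniform(0, 300, 200)
        res = distance_shift_test(x, x)
        assert not res["proximity_call"]

    def test_planted_proximity_detected(self, rng):
        obs = rng.uniform(0, 30, 300)
        null = rng.uniform(0, 300, 300)
        res = distance_shift_test(obs, null)
        assert res["p"] < 0.01 and res["median_shift"] < 0
        assert res["proximity_call"]

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            distance_shift_test([1.0], [1.0, 2.0])


class TestProximalPairs:
    def test_boundary_fifty_is_proximal(self):
        pairs = pd.DataFrame({"gene_id": ["a", "b"], "distance": [50, 51],
                              "log2_change": [-1.0, 0.5]})
        out = proximal_pair_expression(pairs)
        prox = out[out["group"].str.startswith("proximal")].iloc[0]
        assert prox["n"] == 1 and prox["mean_log2_change"] == -1.0

    def test_protection_loss_for_proximal_pairs(self, rng):
        n = 120
        dist = np.concatenate([rng.uniform(0, 50, n), rng.uniform(51, 300, n)])
        change = np.concatenate([rng.normal(-0.5, 0.3, n), rng.normal(0.0, 0.3, n)])
        pairs = pd.DataFrame({"gene_id": [f"g{i}" for i in range(2 * n)],
                              "distance": dist, "log2_change": change})
        out = proximal_pair_expression(pairs)
        prox = out.iloc[0]["mean_log2_change"]
        distal = out.iloc[1]["mean_log2_change"]
        assert prox < distal and out.iloc[0]["p_ranksum"] < 0.01


class TestExpressionComparisons:
    def test_monotone_counts_give_significant_increases(self):
        counts = pd.DataFrame({
            "gene_id": ["g"] * 3, "sample_id": ["s0", "s1", "s2"],
            "count": [1000, 2000, 4000],
        })
        comp = expression_comparison_table(counts)
        assert (comp["bayes_factor"] > 5).all()
        assert (comp["delta_psi"] > 0).all()

    def test_small_fold_changes_not_significant(self):
        counts = pd.DataFrame({
            "gene_id": ["g"] * 2, "sample_id": ["s0", "s1"],
            "count": [1000, 1100],  # 1.1-fold, below the 1.2 threshold
        })
        comp = expression_comparison_table(counts)
        assert (comp["bayes_factor"] == 0).all()


class TestDevelopmentGrouping:
    def _genes(self, rng, shift=0.0):
        n = 200
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "n_celf": rng.integers(0, 4, n),
            "n_mbnl": rng.integers(0, 4, n),
            "has_proximal_pair": rng.random(n) < 0.3,
            "log2_change": rng.normal(shift, 0.5, n),
            "expression_mz": rng.normal(0, 2, n),
        })

    def test_single_distribution_rarely_significant(self, rng):
        genes = self._genes(rng)
        _summary, tests = development_grouping(genes)
        valid = tests.dropna(subset=["p"])
        assert (valid["p"] < 0.01).mean() < 0.2

    def test_mz_filter_applied(self, rng):
        genes = self._genes(rng)
        genes["expression_mz"] = 0.0
        summary, _ = development_grouping(genes)
        assert summary.empty

    def test_empty_groups_flagged(self, rng):
        genes = self._genes(rng).head(3)
        genes["expression_mz"] = 5.0
        summary, _ = development_grouping(genes)
        assert (summary["n"] < 2).any() == (summary["flag"] == "low_n").any()
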