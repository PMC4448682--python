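"""CLIP read collapsing, cluster calling, kmer Z, CIS and density profiles."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from spliceclip.clip import (
    call_clusters, cis_profile, cluster_sequence, collapse_reads,
    density_correlation, info_content_by_cis, kmer_count_vector,
    kmer_enrichment_z, meta_density, positional_score_profile, revcomp,
    stratified_match,
)
from spliceclip.events import ClipRead
from spliceclip.synthetic import SimulationConfig, simulate_annotation, simulate_clip_reads


def read(start, end, strand="+", chrom="c", rid="r", subs=()):
    return ClipRead(chrom, start, end, strand, rid, tuple(subs))


def oracle_clusters(reads, min_height, max_gap=0):
    """Brute-force per-base coverage scan."""
    out = []
    keys = {(r.chrom, r.strand) for r in reads}
    for chrom, strand in sorted(keys):
        cov = Counter()
        for r in reads:
            if (r.chrom, r.strand) != (chrom, strand):
                continue
            for p in range(r.start, r.end):
                cov[p] += 1
        positions = sorted(p for p, c in cov.items() if c >= min_height)
        if not positions:
            continue
        runs = []
        s = prev = positions[0]
        for p in positions[1:]:
            if p - prev - 1 <= max_gap:
                prev = p
            else:
                runs.append((s, prev + 1))
                s = prev = p
        runs.append((s, prev + 1))
        out.extend((chrom, strand, a, b) for a, b in runs)
    return sorted(out)


class TestCollapse:
    def test_identical_reads_collapse_to_one(self):
        reads = [read(0, 30, rid=f"r{i}") for i in range(3)]
        assert len(collapse_reads(reads)) == 1

    def test_distinct_substitutions_kept(self):
        a = read(0, 30, rid="a", subs=[(5, "G", "T")])
        b = read(0, 30, rid="b", subs=[(6, "G", "T")])
        c = read(0, 30, rid="c", subs=[(5, "G", "T")])
        assert len(collapse_reads([a, b, c])) == 2

    def test_matches_generator_truth(self):
        ann = simulate_annotation(SimulationConfig(n_genes=8, duplicate_rate=0.5,
                                                   clip_reads=1500, seed=31))
        reads, n_unique = simulate_clip_reads(ann)
        assert len(collapse_reads(reads)) == n_unique


class TestCallClusters:
    def test_single_read_below_height(self):
        assert call_clusters([read(10, 40)], min_height=3) == []

    def test_three_stacked_reads(self):
        reads = [read(10, 40, rid=f"r{i}") for i in range(3)]
        (c,) = call_clusters(reads, min_height=3)
        assert (c.start, c.end, c.read_count, c.max_height) == (10, 40, 3, 3)

    def test_max_gap_merges_runs(self):
        reads = ([read(0, 10, rid=f"a{i}") for i in range(3)]
                 + [read(12, 20, rid=f"b{i}") for i in range(3)])
        assert len(call_clusters(reads, min_height=3, max_gap=0)) == 2
        assert len(call_clusters(reads, min_height=3, max_gap=2)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_reads_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reads = []
        for i in range(150):
            s = int(rng.integers(0, 300))
            L = int(rng.integers(10, 40))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(read(s, s + L, strand=strand, rid=f"r{i}"))
        got = sorted((c.chrom, c.strand, c.start, c.end)
                     for c in call_clusters(reads, min_height=3, max_gap=1))
        assert got == oracle_clusters(reads, 3, 1)

    def test_strand_mirror_symmetry(self):
        """Flipping strands and mirroring coordinates mirrors the clusters."""
        G = 500
        reads = [read(10, 40, rid="a"), read(12, 42, rid="b"), read(15, 45, rid="c")]
        mirrored = [read(G - r.end, G - r.start, strand="-", rid=r.read_id)
                    for r in reads]
        fwd = call_clusters(reads, min_height=3)
        rev = call_clusters(mirrored, min_height=3)
        assert [(G - c.end, G - c.start) for c in rev] == [(c.start, c.end) for c in fwd]

    def test_idempotent_on_collapsed_reads(self):
        reads = [read(10, 40, rid=f"r{i}") for i in range(4)]
        first = call_clusters(reads, min_height=3)
        assert call_clusters(reads, min_height=3) == first


class TestKmerZ:
    def test_self_comparison_centered(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(30)]
        z = kmer_enrichment_z(seqs, seqs, k=5, n_resample=100, seed=0)
        present = z[z["f_cluster"] > 0]
        assert present["z"].abs().max() < 3.0
        assert abs(present["z"].mean()) < 0.5

    def test_planted_ugu_kmers_on_top(self, rng):
        core = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(40)]
        planted = [s[:10] + "TGTTGT" + s[16:] for s in core]
        z = kmer_enrichment_z(planted, core, k=5, n_resample=100, seed=1)
        top = set(z.head(5)["kmer"])
        assert {"UGUUG", "GUUGU"} & top

    def test_absent_kmer_flagged(self):
        z = kmer_enrichment_z(["AAAAAA"], ["AAAAAA"], k=5, n_resample=20, seed=0)
        row = z[z["kmer"] == "CCCCC"].iloc[0]
        assert row["z"] == 0.0 and row["flag"] == "zero_variance"

    def test_k_longer_than_region_rejected(self):
        with pytest.raises(ValueError, match="shortest region"):
            kmer_enrichment_z(["ACG"], ["ACGTACGT"], k=5)


class TestCis:
    def _genome(self, seq):
        return {"c": seq}

    def test_no_substitutions_gives_zero_cis(self):
        genome = self._genome("A" * 100)
        reads = [read(0, 50, rid=f"r{i}") for i in range(12)]
        prof = cis_profile(reads, genome, min_cov=10)
        assert (prof["cis_freq"] == 0).all()

    def test_min_cov_excludes_sparse_positions(self):
        genome = self._genome("A" * 100)
        reads = [read(0, 50, rid=f"r{i}") for i in range(5)]
        assert cis_profile(reads, genome, min_cov=10).empty

    def test_planted_crosslinks_show_u_minus_one_bias(self):
        """Generator-planted UGU crosslinks put U at the -1 flank of
        high-CIS guanines."""
        ann = simulate_annotation(SimulationConfig(
            n_genes=10, substitution_prob=0.4, background_fraction=0.05,
            clip_reads=6000, seed=41))
        reads, _ = simulate_clip_reads(ann)
        info = info_content_by_cis(reads, ann.genome,
                                   bins=(0.0, 0.02, 0.15, 1.0001), min_cov=8)
        top_bin = info[info["cis_bin"] == "[0.15,1.0001)"]
        row = top_bin[top_bin["offset"] == -1]
        assert not row.empty
        assert row.iloc[0]["frac_U"] > 0.5

    def test_uniform_flanks_have_low_information(self, rng):
        genome = {"c": "".join(rng.choice(list("ACGT"), 40000))}
        reads = []
        for i in range(1500):
            s = int(rng.integers(0, 39950))
            subs = []
            if genome["c"][s + 10] == "G" and rng.random() < 0.5:
                subs = [(10, "G", "T")]
            reads.extend(read(s, s + 30, rid=f"r{i}_{j}", subs=subs)
                         for j in range(10))
        info = info_content_by_cis(reads, genome, bins=(0.3, 1.0001), min_cov=10)
        sel = info[info["offset"].abs() > 1]
        assert sel["info_bits"].mean() < 0.05


class TestDensityProfiles:
    def test_identical_inputs_correlate_perfectly(self, rng):
        reads = [read(int(s), int(s) + 20, rid=f"r{i}")
                 for i, s in enumerate(rng.integers(0, 2000, 300))]
        regions = [("c", 0, 2000, "+")]
        assert density_correlation(reads, reads, regions) == pytest.approx(1.0)

    def test_independent_reads_uncorrelated(self, rng):
        # ~2 read starts per 5-nt window so most windows are informative
        regions = [("c", 0, 100_000, "+")]
        def mk(seed):
            r = np.random.default_rng(seed)
            return [read(int(s), int(s) + 20, rid=f"x{i}")
                    for i, s in enumerate(r.integers(0, 99_000, 40_000))]
        r = density_correlation(mk(1), mk(2), regions)
        assert abs(r) < 0.1

    def test_shared_binding_truth_correlates(self):
        ann = simulate_annotation(SimulationConfig(n_genes=10, seed=51))
        ra, _ = simulate_clip_reads(ann, seed=100)
        rb, _ = simulate_clip_reads(ann, seed=200)
        regions = [(g.chrom, g.start, g.end, g.strand) for g in ann.genes]
        assert density_correlation(ra, rb, regions) > 0.5

    def test_meta_density_flat_for_uniform_reads(self, rng):
        regions = []
        reads = []
        for i in range(400):
            start = i * 1000
            regions.append(("c", start, start + 400, "+"))
            for j, s in enumerate(rng.integers(start, start + 400, 40)):
                reads.append(read(int(s), int(s) + 20, rid=f"r{i}_{j}"))
        prof = meta_density(reads, regions, anchor="utr_scaled", n_bins=20,
                            n_boot=0)
        assert prof["mean_density"].max() / prof["mean_density"].min() < 1.5

    def test_meta_density_peaks_at_planted_pas_sites(self):
        """Sites planted in the UTR give density rising upstream of the PAS."""
        ann = simulate_annotation(SimulationConfig(n_genes=12, seed=61,
                                                   background_fraction=0.05))
        reads, _ = simulate_clip_reads(ann)
        regions = []
        for g in ann.genes:
            if g.utr_type != "tandem":
                continue
            lo = min(g.regions["core"][0], g.regions["extension"][0])
            hi = max(g.regions["core"][1], g.regions["extension"][1])
            regions.append((g.chrom, lo, hi, g.strand))
        prof = meta_density(reads, regions, anchor="pas_offset", flank=150,
                            n_boot=0)
        upstream = prof[prof["position"] < 0]["mean_density"].sum()
        downstream = prof[prof["position"] >= 0]["mean_density"].sum()
        assert upstream > 2 * downstream

    def test_empty_reads_give_zero_profile(self):
        prof = meta_density([], [("c", 0, 100, "+")], anchor="utr_scaled",
                            n_bins=10, n_boot=0)
        assert (prof["mean_density"] == 0).all()


class TestScoreProfile:
    def test_identical_groups_identical_profiles(self, rng):
        scores = {"c": rng.uniform(0, 1, 5000)}
        regions = [("c", i * 100, i * 100 + 50, "+") for i in range(20)]
        prof = positional_score_profile({"a": regions, "b": regions}, scores,
                                        n_boot=0)
        a = prof[prof["group"] == "a"]["mean_score"].to_numpy()
        b = prof[prof["group"] == "b"]["mean_score"].to_numpy()
        assert np.allclose(a, b)

    def test_constant_track_gives_flat_profile(self):
        scores = {"c": np.full(1000, 0.7)}
        regions = [("c", 0, 100, "+"), ("c", 200, 300, "-")]
        prof = positional_score_profile({"g": regions}, scores, n_boot=0)
        assert np.allclose(prof["mean_score"], 0.7)

    def test_elevated_scores_under_clusters_detected(self, rng):
        scores = {"c": rng.uniform(0, 0.2, 10_000)}
        bound, control = [], []
        for i in range(25):
            s = i * 200
            bound.append(("c", s, s + 100, "+"))
            scores["c"][s + 40:s + 60] += 0.6   # elevated under the cluster
            control.append(("c", s + 5000, s + 5100, "+"))
        prof = positional_score_profile({"bound": bound, "ctl": control},
                                        scores, window=5, n_boot=0)
        b = prof[(prof["group"] == "bound")
                 & prof["window_start"].between(40, 55)]["mean_score"].mean()
        c = prof[(prof["group"] == "ctl")
                 & prof["window_start"].between(40, 55)]["mean_score"].mean()
        assert b > c + 0.3

    def test_length_mismatch_rejected(self):
        scores = {"c": np.zeros(1000)}
        with pytest.raises(ValueError, match="length"):
            positional_score_profile(
                {"g": [("c", 0, 100, "+"), ("c", 0, 60, "+")]}, scores)


def test_stratified_match_reproduces_covariate_distribution(rng):
    cand = pd.DataFrame({"x": rng.uniform(0, 1, 1000), "y": rng.uniform(0, 1, 1000)})
    ref = pd.DataFrame({"x": rng.beta(5, 2, 200), "y": rng.beta(2, 5, 200)})
    matched = stratified_match(cand, ref, ["x", "y"], n_strata=4, seed=0)
    assert len(matched) == len(ref)
    assert abs(matched["x"].mean() - ref["x"].mean()) < 0.1


def test_cluster_sequence_respects_strand():
    genome = {"c": "AACGTT"}
    from spliceclip.events import ClipCluster
    plus = ClipCluster("c", 1, 4, "+", 3, 3)
    minus = ClipCluster("c", 1, 4, "-", 3, 3)
    assert cluster_sequence(plus, genome) == "ACG"
    assert cluster_sequence(minus, genome) == revcomp("ACG") == "CGT"
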