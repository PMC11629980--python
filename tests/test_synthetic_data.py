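"""Planted-ground-truth guarantees and determinism of the generator."""

import numpy as np
import pandas as pd
import pytest

from epistates.duplicate_fate import (
    combined_profile,
    euclidean,
    to_relative,
)
from epistates.genome_core import ValidationError, find_overlaps, GenomicInterval
from epistates.synthetic_data import (
    SimulationConfig,
    config_from_dict,
    simulate_enhancer_clusters,
    simulate_expression,
    simulate_genome,
    simulate_methylome,
    simulate_qtl_snps,
    simulate_state_tracks,
    simulate_triplets,
)
from epistates.tissue_specificity import call_tissue_specific


@pytest.fixture(scope="module")
def small_cfg():
    return SimulationConfig(
        seed=42, n_chroms=2, chrom_length=500_000, n_genes=60,
        n_cpg=4_000, n_triplets=100, n_singleton_pairs=40,
        n_snps=60, n_qtl=6, qtl_length=60_000,
        n_enh_clusters_low=25, n_enh_clusters_high=5,
    )


@pytest.fixture(scope="module")
def world(small_cfg):
    genome, genes = simulate_genome(small_cfg)
    tpm, truth = simulate_expression(small_cfg, genes)
    tracks, planted = simulate_state_tracks(small_cfg, genome, genes, truth)
    return genome, genes, tpm, truth, tracks, planted


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError, match="unknown config keys"):
            config_from_dict({"seed": 1, "not_a_knob": 5})

    def test_fate_mix_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SimulationConfig(fate_mix={"conserved": 0.5, "specialized": 0.4})


class TestGenome:
    def test_gene_count_and_no_overlap(self, world):
        genome, genes, *_ = world
        assert len(genes) == 60
        by_chrom: dict = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end <= b.start

    def test_determinism(self, small_cfg):
        g1, genes1 = simulate_genome(small_cfg)
        g2, genes2 = simulate_genome(small_cfg)
        assert g1.chrom_sizes == g2.chrom_sizes
        assert [(g.gene_id, g.start, g.strand) for g in genes1] == [
            (g.gene_id, g.start, g.strand) for g in genes2
        ]

    def test_overfull_chromosome_rejected(self):
        cfg = SimulationConfig(n_chroms=1, chrom_length=100_000, n_genes=100)
        with pytest.raises(ValidationError, match="fit"):
            simulate_genome(cfg)


class TestExpression:
    def test_planted_specific_genes_pass_the_caller(self, world):
        _, _, tpm, truth, *_ = world
        calls = call_tissue_specific(tpm)
        called = {(r.gene_id, r.tissue) for r in calls.itertuples()}
        planted = {
            (r.gene_id, r.specific_tissue)
            for r in truth.itertuples()
            if r.specific_tissue
        }
        assert called == planted

    def test_all_tpm_non_negative_and_deterministic(self, small_cfg, world):
        _, genes, tpm, *_ = world
        assert (tpm.values >= 0).all()
        _, genes2 = simulate_genome(small_cfg)
        tpm2, _ = simulate_expression(small_cfg, genes2)
        assert np.array_equal(tpm.values, tpm2.values)


class TestStateTracks:
    def test_complete_tiling(self, world):
        genome, _, _, _, tracks, _ = world
        for track in tracks.values():
            by_chrom: dict = {}
            for s in track.segments:
                by_chrom.setdefault(s.chrom, []).append(s)
            for chrom, segs in by_chrom.items():
                assert segs[0].start == 0
                assert segs[-1].end == genome.chrom_sizes[chrom]
                for a, b in zip(segs, segs[1:]):
                    assert a.end == b.start
                assert sum(s.length for s in segs) == genome.chrom_sizes[chrom]

    def test_expressed_tss_overlapped_by_planted_tssa(self, world):
        _, genes, tpm, _, tracks, planted = world
        tissue = tpm.columns[0]
        track = tracks[tissue]
        mine = planted[(planted.tissue == tissue) & (planted.kind == "tss")]
        gene_by_id = {g.gene_id: g for g in genes}
        for row in mine.itertuples():
            g = gene_by_id[row.gene_id]
            probe = GenomicInterval(g.chrom, max(0, g.tss - 1), g.tss + 1)
            hit_states = {
                track.segments[si].label
                for _, si, _ in find_overlaps([probe], track.segments)
            }
            assert "TssA" in hit_states

    def test_tssa_concentrated_at_tss_windows(self, world):
        """Planted promoter states are denser near TSS than genome-wide."""
        genome, genes, tpm, _, tracks, _ = world
        tissue = tpm.columns[0]
        track = tracks[tissue]
        tssa = track.by_state("TssA")
        genome_frac = sum(s.length for s in tssa) / genome.total_length
        windows = [
            GenomicInterval(g.chrom, max(0, g.tss - 1_000), g.tss + 1_000)
            for g in genes
        ]
        in_windows = sum(bp for *_, bp in find_overlaps(windows, tssa))
        window_frac = in_windows / sum(w.length for w in windows)
        assert window_frac > 5 * genome_frac


class TestMethylome:
    def test_planted_depth_extremes_and_background(self, world, small_cfg):
        genome, genes, _, _, tracks, _ = world
        sites, truth = simulate_methylome(
            small_cfg, genome, genes, tracks[small_cfg.tissues[0]]
        )
        depth = sites.reads_c + sites.reads_t
        low = truth.planted == "planted_low_depth"
        high = truth.planted == "planted_high_depth"
        assert (depth[low] < 10).all()
        assert (depth[high] > np.quantile(depth, 0.999)).all()
        # background level away from genes ~0.75
        far = np.ones(len(sites), dtype=bool)
        for g in genes:
            far &= ~((sites.chrom == g.chrom) & (abs(sites.pos - g.tss) < 10_000))
        lvl = sites.reads_c[far & ~low.values] / depth[far & ~low.values]
        assert abs(lvl.mean() - 0.75) < 0.02


class TestTriplets:
    def test_zero_noise_distances_by_fate(self):
        cfg = SimulationConfig(seed=7, n_triplets=80, n_singleton_pairs=20, noise_sd=0.0)
        trips, dup, sister, _ = simulate_triplets(cfg)
        for t in trips.itertuples():
            anc = to_relative(sister.loc[t.anc_id].to_numpy())
            d1 = dup.loc[t.d1_id].to_numpy()
            d2 = dup.loc[t.d2_id].to_numpy()
            e1 = euclidean(to_relative(d1), anc)
            e2 = euclidean(to_relative(d2), anc)
            ec = euclidean(combined_profile(d1, d2), anc)
            if t.true_fate == "conserved":
                assert e1 < 1e-9 and e2 < 1e-9
            elif t.true_fate == "neofunctionalized":
                assert max(e1, e2) >= 0.3 and min(e1, e2) < 1e-9
            elif t.true_fate == "subfunctionalized":
                assert e1 >= 0.3 and e2 >= 0.3 and ec < 1e-9
            else:
                assert min(e1, e2, ec) >= 0.3

    def test_fate_counts_match_mix_exactly(self):
        cfg = SimulationConfig(seed=8, n_triplets=500, n_singleton_pairs=20)
        trips, *_ = simulate_triplets(cfg)
        counts = trips.true_fate.value_counts()
        assert counts["conserved"] == 368  # 0.736 * 500
        assert counts["neofunctionalized"] == 71
        assert counts["subfunctionalized"] == 1
        assert counts["specialized"] == 60

    def test_singleton_pairs_have_small_distances(self):
        cfg = SimulationConfig(seed=9, n_triplets=10, n_singleton_pairs=50, noise_sd=0.02)
        _, _, sister, pairs = simulate_triplets(cfg)
        d = [
            euclidean(
                to_relative(sister.loc[r.s1_id].to_numpy()),
                to_relative(sister.loc[r.s2_id].to_numpy()),
            )
            for r in pairs.itertuples()
        ]
        assert np.median(d) < 0.15

    def test_too_few_tissues_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(tissues=("only_one",))


class TestQtlSnps:
    def test_planted_and_decoy_bookkeeping(self, world, small_cfg):
        genome, _, _, _, tracks, _ = world
        qtl, snps, motifs, truth = simulate_qtl_snps(
            small_cfg, genome, tracks[small_cfg.tissues[0]]
        )
        n_planted = int(round(small_cfg.n_snps * small_cfg.snp_triple_fraction))
        assert truth.planted.sum() == n_planted
        assert len(snps) == small_cfg.n_snps
        fam = truth[truth.planted].family.value_counts()
        assert fam["C/EBP"] == round(0.7 * n_planted)
        assert fam["GR"] == n_planted - round(0.7 * n_planted)


class TestEnhancerClusters:
    def test_layout_shared_and_truth_counts(self, world, small_cfg):
        genome, *_ = world
        peaks, truth = simulate_enhancer_clusters(small_cfg, genome)
        per_tissue = truth.groupby("tissue").is_super.sum()
        assert (per_tissue == small_cfg.n_enh_clusters_high).all()
        t0, t1 = small_cfg.tissues[:2]
        spans0 = truth[truth.tissue == t0][["chrom", "start", "end"]].reset_index(drop=True)
        spans1 = truth[truth.tissue == t1][["chrom", "start", "end"]].reset_index(drop=True)
        assert spans0.equals(spans1)  # layout shared across tissues
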