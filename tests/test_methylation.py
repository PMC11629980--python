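"""CpG depth filters, TSS/state methylation profiles, expression coupling."""

import numpy as np
import pandas as pd
import pytest

from epistates.genome_core import GeneRecord, GenomicInterval, ValidationError
from epistates.methylation import (
    add_levels,
    filter_sites,
    methylation_expression_association,
    state_methylation_profile,
    tss_methylation_profile,
)

from conftest import make_track


def _sites(pos, reads_c, reads_t, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": "+",
            "reads_c": reads_c,
            "reads_t": reads_t,
        }
    )


class TestLevels:
    def test_level_definition_and_scale_freedom(self):
        a = add_levels(_sites([10], [3], [7]))
        assert a.level.iloc[0] == pytest.approx(0.3)
        b = add_levels(_sites([10], [30], [70]))  # 10x depth, same level
        assert b.level.iloc[0] == pytest.approx(a.level.iloc[0])

    def test_zero_depth_is_nan(self):
        out = add_levels(_sites([10], [0], [0]))
        assert np.isnan(out.level.iloc[0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            add_levels(_sites([10], [-1], [5]))


class TestFilterSites:
    def test_depth_nine_removed_depth_ten_kept(self):
        sites = _sites([1, 2], [4, 5], [5, 5])  # depths 9, 10
        out = filter_sites(sites)
        assert list(out.pos) == [2]

    def test_uniform_depth_untouched_by_quantile(self):
        sites = _sites(list(range(100)), [10] * 100, [10] * 100)
        assert len(filter_sites(sites)) == 100

    def test_extreme_outlier_removed(self):
        n = 10_000
        rng = np.random.default_rng(0)
        depth = rng.poisson(30, n) + 10
        depth[1234] = 100_000
        sites = _sites(list(range(n)), (depth * 0).tolist(), depth.tolist())
        out = filter_sites(sites)
        assert 1234 not in set(out.pos)
        # sort-based oracle: smallest depth at or above the 99.9% rank
        s = np.sort(depth)
        hi = s[int(np.ceil(0.999 * (len(s) - 1)))]
        keep = (depth >= 10) & (depth <= hi)
        assert len(out) == keep.sum()

    def test_empty_input_passes_through(self):
        out = filter_sites(_sites([], [], []))
        assert len(out) == 0

    def test_idempotent_on_typical_depth_data(self):
        """Tie-rich integer depths plus PCR outliers: one pass removes the
        outliers, a second pass changes nothing."""
        rng = np.random.default_rng(1)
        depth = np.concatenate([rng.integers(10, 40, 5_000), [1_000, 2_000, 5_000]])
        c = rng.binomial(depth, 0.7)
        sites = _sites(list(range(depth.size)), c.tolist(), (depth - c).tolist())
        once = filter_sites(sites)
        assert (once.reads_c + once.reads_t).max() < 1_000  # outliers gone
        twice = filter_sites(once)
        assert once.equals(twice)


class TestTssProfile:
    def test_uniform_methylome_is_flat(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(200_000, 5_000, replace=False))
        sites = _sites(pos.tolist(), [75] * 5_000, [25] * 5_000)
        genes = [GeneRecord("g", "chr1", 100_000, 120_000, "+")]
        prof = tss_methylation_profile(sites, genes, window=5_000, bin_size=500)
        vals = prof.mean_level.dropna()
        assert np.allclose(vals, 0.75)

    def test_single_site_bookkeeping(self):
        sites = _sites([10_150], [4], [6])
        genes = [GeneRecord("g", "chr1", 10_000, 20_000, "+")]
        prof = tss_methylation_profile(sites, genes, window=1_000, bin_size=100)
        row = prof.set_index("offset").loc[100]
        assert row.mean_level == pytest.approx(0.4)
        assert row.n_genes == 1

    def test_strand_mirror_symmetry(self):
        """The same site lands at the mirrored offset for a minus-strand gene."""
        sites = _sites([10_300], [8], [2])
        plus = [GeneRecord("g", "chr1", 10_000, 20_000, "+")]
        minus = [GeneRecord("g", "chr1", 1_000, 10_000, "-")]  # tss also 10,000
        p_plus = tss_methylation_profile(sites, plus, window=1_000, bin_size=100)
        p_minus = tss_methylation_profile(sites, minus, window=1_000, bin_size=100)
        assert p_plus.set_index("offset").mean_level.loc[300] == pytest.approx(0.8)
        assert p_minus.set_index("offset").mean_level.loc[-300] == pytest.approx(0.8)

    def test_gene_weighted_averaging(self):
        """A CpG-dense gene contributes the same weight as a sparse one."""
        dense = [(1_000 + i, 10, 0) for i in range(10)]  # level 1.0, 10 sites
        sparse = [(50_000, 0, 10)]  # level 0.0, 1 site
        rows = dense + sparse
        sites = _sites([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])
        genes = [
            GeneRecord("gd", "chr1", 1_000, 5_000, "+"),
            GeneRecord("gs", "chr1", 50_000, 55_000, "+"),
        ]
        prof = tss_methylation_profile(sites, genes, window=100, bin_size=100)
        assert prof.set_index("offset").mean_level.loc[0] == pytest.approx(0.5)


class TestStateProfile:
    def test_uniform_methylome_body_equals_flank(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(50_000, 3_000, replace=False))
        sites = _sites(pos.tolist(), [15] * 3_000, [5] * 3_000)
        track = make_track([GenomicInterval("chr1", 20_000, 25_000, "TssA")])
        prof = state_methylation_profile(sites, track)
        by_region = prof.groupby("region").mean_level.mean()
        assert by_region["body"] == pytest.approx(by_region["upstream"], abs=1e-9)

    def test_planted_body_hypomethylation_detected(self):
        pos = list(range(18_000, 27_000, 50))
        levels = [2 if 20_000 <= p < 25_000 else 15 for p in pos]  # of 20 reads
        sites = _sites(pos, levels, [20 - l for l in levels])
        track = make_track([GenomicInterval("chr1", 20_000, 25_000, "TssA")])
        prof = state_methylation_profile(sites, track)
        by_region = prof.groupby("region").mean_level.mean()
        assert by_region["body"] < by_region["upstream"] - 0.3

    def test_single_interior_site_fills_its_bin(self):
        sites = _sites([20_100], [4], [6])
        track = make_track([GenomicInterval("chr1", 20_000, 21_000, "TssA")])
        prof = state_methylation_profile(sites, track, n_body_bins=10)
        body = prof[(prof.state == "TssA") & (prof.region == "body")]
        filled = body.dropna(subset=["mean_level"])
        assert len(filled) == 1
        assert filled.mean_level.iloc[0] == pytest.approx(0.4)


class TestExpressionAssociation:
    def _make(self, coupling, n=60, seed=4):
        rng = np.random.default_rng(seed)
        genes, rows, tpm = [], [], {}
        for i in range(n):
            tss = 20_000 + 30_000 * i
            g = GeneRecord(f"g{i}", "chr1", tss, tss + 5_000, "+")
            genes.append(g)
            t = float(rng.lognormal(1, 1.5))
            tpm[g.gene_id] = t
            lvl = np.clip(0.8 + coupling * np.log10(t + 0.01) + rng.normal(0, 0.02), 0.01, 0.99)
            for j in range(5):
                d = 40
                rows.append((tss - 1_000 + 400 * j, int(lvl * d), int((1 - lvl) * d)))
        sites = _sites([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])
        return sites, genes, pd.Series(tpm)

    def test_negative_coupling_recovered(self):
        sites, genes, tpm = self._make(coupling=-0.15)
        _, r, r2, p = methylation_expression_association(sites, genes, tpm)
        assert r < -0.8
        assert p < 1e-6

    def test_independent_methylation_gives_small_r2(self):
        sites, genes, tpm = self._make(coupling=0.0, n=100)
        _, r, r2, p = methylation_expression_association(sites, genes, tpm)
        assert r2 < 0.1

    def test_constant_methylation_flagged(self):
        sites, genes, tpm = self._make(coupling=0.0, n=10)
        sites["reads_c"] = 10
        sites["reads_t"] = 10
        with pytest.warns(UserWarning, match="zero variance"):
            _, r, r2, p = methylation_expression_association(sites, genes, tpm)
        assert np.isnan(r)

    def test_too_few_genes_rejected(self):
        sites, genes, tpm = self._make(coupling=0.0, n=2)
        with pytest.raises(ValidationError):
            methylation_expression_association(sites, genes, tpm)
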