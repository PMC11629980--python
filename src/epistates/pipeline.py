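"""End-to-end orchestration: simulate inputs, run every stage, write TSVs.

``run_all`` executes the stages in dependency order into a run directory
and writes a manifest recording the package version, seed, parameter
values and SHA-256 checksums of every emitted file.  Outputs are
deterministic for a fixed config: rerunning produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import duplicate_fate, epidivergence, methylation, qtl_regulatory
from . import state_enrichment, superenhancers, synthetic_data, tissue_specificity
from .genome_core import (
    GenomicInterval,
    flank_tss,
    tpm_matrix,
    write_chrom_sizes,
    write_gene_table,
    write_intervals,
)
from .synthetic_data import SimulationConfig

log = logging.getLogger("epistates.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def simulate_inputs(config: SimulationConfig, outdir: Path) -> dict:
    """Generate and write every synthetic input; returns in-memory objects."""
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = synthetic_data.simulate_genome(config)
    tpm, expr_truth = synthetic_data.simulate_expression(config, genes)
    tracks, planted_states = synthetic_data.simulate_state_tracks(
        config, genome, genes, expr_truth
    )
    peaks = synthetic_data.simulate_histone_peaks(config, genome, genes, expr_truth)
    enh_peaks, se_truth = synthetic_data.simulate_enhancer_clusters(config, genome)
    ref_tissue = config.tissues[0]
    meth_sites, meth_truth = synthetic_data.simulate_methylome(
        config, genome, genes, tracks[ref_tissue]
    )
    qtl, snps, motifs, snp_truth = synthetic_data.simulate_qtl_snps(
        config, genome, tracks[ref_tissue]
    )
    triplets, dup_tpm, sister_tpm, singles = synthetic_data.simulate_triplets(config)
    pair_profiles = synthetic_data.simulate_pair_promoter_profiles(config, triplets)

    write_chrom_sizes(genome, outdir / "genome.chrom.sizes")
    write_gene_table(genes, list(config.tissues), outdir / "genes.tsv")
    _write_tsv(expr_truth, outdir / "truth_specificity.tsv")
    for tissue, track in tracks.items():
        write_intervals(track.segments, outdir / f"states_{tissue}.bed")
    _write_tsv(planted_states, outdir / "truth_states.tsv")
    for tissue in config.tissues:
        for mark, ivs in peaks[tissue].items():
            write_intervals(ivs, outdir / f"peaks_{tissue}_{mark}.bed")
        write_intervals(enh_peaks[tissue], outdir / f"peaks_{tissue}_H3K27ac_clusters.bed")
    _write_tsv(se_truth, outdir / "truth_superenhancers.tsv")
    _write_tsv(meth_sites, outdir / f"methylome_{ref_tissue}.tsv")
    _write_tsv(meth_truth, outdir / "truth_methylome.tsv")
    write_intervals(qtl, outdir / "qtl.bed")
    _write_tsv(snps, outdir / "snps.tsv")
    write_intervals(motifs, outdir / "motifs.bed")
    _write_tsv(snp_truth, outdir / "truth_snps.tsv")
    _write_tsv(triplets, outdir / "triplets.tsv")
    dup_tpm.reset_index().to_csv(outdir / "dup_tpm.tsv", sep="\t", index=False, float_format="%.6g")
    sister_tpm.reset_index().to_csv(outdir / "sister_tpm.tsv", sep="\t", index=False, float_format="%.6g")
    _write_tsv(singles, outdir / "singleton_pairs.tsv")
    _write_tsv(pair_profiles, outdir / "pair_profiles.tsv")

    return {
        "genome": genome,
        "genes": genes,
        "tpm": tpm,
        "expr_truth": expr_truth,
        "tracks": tracks,
        "peaks": peaks,
        "enh_peaks": enh_peaks,
        "se_truth": se_truth,
        "meth_sites": meth_sites,
        "qtl": qtl,
        "snps": snps,
        "motifs": motifs,
        "snp_truth": snp_truth,
        "triplets": triplets,
        "dup_tpm": dup_tpm,
        "sister_tpm": sister_tpm,
        "singles": singles,
        "pair_profiles": pair_profiles,
        "ref_tissue": ref_tissue,
    }


def run_all(config: SimulationConfig, outdir: str | Path) -> Path:
    """Run every stage on a fresh simulation; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs_dir = outdir / "inputs"
    log.info("stage=simulate outdir=%s", inputs_dir)
    data = simulate_inputs(config, inputs_dir)
    genome = data["genome"]
    genes = data["genes"]
    tpm = data["tpm"]
    tracks = data["tracks"]
    ref = data["ref_tissue"]
    track = tracks[ref]

    # --- state enrichment -------------------------------------------------
    tss_windows = [flank_tss(g, 2_000, 2_000, genome) for g in genes]
    gene_bodies = [GenomicInterval(g.chrom, g.start, g.end) for g in genes]
    expressed = [
        GenomicInterval(g.chrom, g.start, g.end)
        for g in genes
        if g.tpm.get(ref, 0.0) > 2.0
    ]
    elements = {
        "tss_2kb": tss_windows,
        "gene_body": gene_bodies,
        "expressed_genes": expressed,
        "qtl": data["qtl"],
    }
    enr = state_enrichment.enrichment_table(track, elements, genome)
    _write_tsv(enr, outdir / "state_enrichment.tsv")
    summ = state_enrichment.state_summary(track, genome)
    _write_tsv(summ, outdir / "state_summary.tsv")
    dens = state_enrichment.state_density_profile(track, genes, window=10_000, bin_size=500)
    _write_tsv(dens, outdir / "state_density_profile.tsv")
    log.info("stage=enrich rows=%d", len(enr))

    # --- tissue specificity ----------------------------------------------
    calls = tissue_specificity.call_tissue_specific(tpm)
    _write_tsv(calls, outdir / "specificity_calls.tsv")
    marks_tbl = tissue_specificity.unique_marks_near_specific_genes(
        calls, data["peaks"], genes, genome
    )
    chi_rows = []
    for row in marks_tbl.itertuples(index=False):
        try:
            res = tissue_specificity.chi_square_specific_vs_silenced(
                row.count_specific, row.total_specific,
                row.count_silenced, row.total_silenced,
            )
            chi_rows.append(
                {"mark": row.mark, "chi2": res.statistic, "pvalue": res.pvalue,
                 "low_expected": res.low_expected}
            )
        except Exception:
            chi_rows.append({"mark": row.mark, "chi2": np.nan, "pvalue": np.nan,
                             "low_expected": True})
    _write_tsv(marks_tbl, outdir / "specificity_marks.tsv")
    _write_tsv(pd.DataFrame(chi_rows), outdir / "specificity_chi2.tsv")
    bins, r2, slope = tissue_specificity.density_vs_expression(
        data["peaks"][ref]["H3K4me1"], genes, tpm[ref], genome
    )
    _write_tsv(bins, outdir / "density_vs_expression.tsv")
    log.info("stage=specificity calls=%d r2=%.4f", len(calls), r2)

    # --- super-enhancers --------------------------------------------------
    se_by_tissue: dict[str, list[GenomicInterval]] = {}
    se_rows = []
    for tissue in config.tissues:
        clusters = superenhancers.stitch(data["enh_peaks"][tissue])
        ranked = superenhancers.call_superenhancers(clusters)
        se_by_tissue[tissue] = [c.interval for c in ranked if c.is_super]
        for c in ranked:
            se_rows.append(
                {
                    "tissue": tissue,
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "signal": c.signal,
                    "rank": c.rank,
                    "is_super": c.is_super,
                }
            )
    _write_tsv(pd.DataFrame(se_rows), outdir / "enhancer_ranks.tsv")
    merged, sharing = superenhancers.merge_across_tissues(se_by_tissue)
    write_intervals(merged, outdir / "superenhancers_nonredundant.bed")
    _write_tsv(sharing, outdir / "superenhancer_sharing.tsv")
    max_tpm = tpm.max(axis=1)
    assign = superenhancers.assign_genes(merged, genes, max_tpm)
    _write_tsv(assign, outdir / "superenhancer_genes.tsv")
    log.info("stage=se nonredundant=%d", len(merged))

    # --- methylation ------------------------------------------------------
    filtered = methylation.filter_sites(data["meth_sites"])
    prof = methylation.tss_methylation_profile(filtered, genes)
    _write_tsv(prof, outdir / "methylation_tss_profile.tsv")
    state_prof = methylation.state_methylation_profile(filtered, track)
    _write_tsv(state_prof, outdir / "methylation_state_profile.tsv")
    assoc, r, r2m, p = methylation.methylation_expression_association(
        filtered, genes, tpm[ref]
    )
    _write_tsv(assoc, outdir / "methylation_expression.tsv")
    log.info("stage=methylation sites=%d->%d r=%.3f", len(data["meth_sites"]), len(filtered), r)

    # --- QTL --------------------------------------------------------------
    qtl_tbl = qtl_regulatory.qtl_enhancer_overlap(track, data["qtl"])
    _write_tsv(qtl_tbl, outdir / "qtl_enhancer_overlap.tsv")
    enh_segments = [s for s in track.segments if s.label in ("EnhG", "Str.Enh", "MidEnh")]
    obs = pd.Series(
        pd.Index([s.chrom for s in enh_segments]).value_counts().to_dict()
    )
    folds = qtl_regulatory.per_chromosome_fold(obs, genome)
    _write_tsv(folds, outdir / "per_chromosome_fold.tsv")
    hits, fam = qtl_regulatory.intersect_snp_qtl_enhancer_motif(
        data["snps"], data["qtl"], track, data["motifs"]
    )
    _write_tsv(hits, outdir / "snp_hits.tsv")
    _write_tsv(fam, outdir / "snp_family_summary.tsv")
    log.info("stage=qtl hits=%d unique_snps=%d", len(hits), hits["snp_id"].nunique() if len(hits) else 0)

    # --- duplicate fate ---------------------------------------------------
    singles = data["singles"]
    sister = data["sister_tpm"]
    pair_profiles_expr = [
        (
            duplicate_fate.to_relative(sister.loc[r.s1_id].to_numpy(dtype=float)),
            duplicate_fate.to_relative(sister.loc[r.s2_id].to_numpy(dtype=float)),
        )
        for r in singles.itertuples(index=False)
    ]
    baseline = duplicate_fate.baseline_cutoff(pair_profiles_expr)
    fates = duplicate_fate.classify_triplets(
        data["triplets"], data["dup_tpm"], sister, baseline.cutoff
    )
    _write_tsv(fates, outdir / "triplet_fates.tsv")
    props = duplicate_fate.fate_proportions(fates["fate"])
    props.rename_axis("fate").reset_index().to_csv(
        outdir / "fate_proportions.tsv", sep="\t", index=False, float_format="%.6g"
    )
    log.info("stage=fate cutoff=%.4f n=%d", baseline.cutoff, len(fates))

    # --- epigenetic divergence --------------------------------------------
    div = epidivergence.pairwise_divergence(data["pair_profiles"])
    _write_tsv(div, outdir / "pair_divergence.tsv")
    comp = epidivergence.compare_fate_categories(div)
    _write_tsv(comp, outdir / "fate_category_comparison.tsv")
    log.info("stage=epidiv pairs=%d", div["pair_id"].nunique() if len(div) else 0)

    # --- manifest ---------------------------------------------------------
    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "epistates",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
        "record_counts": {
            "genes": len(genes),
            "specificity_calls": len(calls),
            "superenhancers": len(merged),
            "snp_hits": len(hits),
            "triplets": len(fates),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
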