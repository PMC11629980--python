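"""QTL-enhancer overlap statistics and SNP/QTL/enhancer/motif intersection.

QTL here are genomic intervals previously associated with growth, fillet
quality or bacterial cold water disease.  The module measures how active
enhancer states (EnhG, Str.Enh, MidEnh) overlap QTL, computes per-
chromosome observed/expected fold enrichments under a length-proportional
null, and extracts SNPs that sit simultaneously inside a QTL, an enhancer
segment and a transcription-factor binding motif, summarized by motif
family.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .genome_core import (
    ENHANCER_STATES,
    GenomeModel,
    GenomicInterval,
    StateSegmentation,
    ValidationError,
    find_overlaps,
    merge_intervals,
)


def qtl_enhancer_overlap(
    track: StateSegmentation,
    qtl: Sequence[GenomicInterval],
    states: Sequence[str] = ENHANCER_STATES,
) -> pd.DataFrame:
    """Per-state summary of enhancer segments overlapping QTL.

    Each enhancer segment is counted once regardless of how many QTL it
    touches; its overlap length is the total bp shared with the merged QTL
    set.  Returns columns state, count, mean_overlap_bp, median_overlap_bp,
    n_chromosomes.
    """
    qtl_merged = merge_intervals(qtl)
    rows = []
    for state in states:
        segs = track.by_state(state)
        per_seg: dict[int, int] = {}
        for qi, _, bp in find_overlaps(segs, qtl_merged):
            per_seg[qi] = per_seg.get(qi, 0) + bp
        if per_seg:
            ov = np.array(list(per_seg.values()), dtype=float)
            chroms = {segs[i].chrom for i in per_seg}
            rows.append(
                {
                    "state": state,
                    "count": len(per_seg),
                    "mean_overlap_bp": float(ov.mean()),
                    "median_overlap_bp": float(np.median(ov)),
                    "n_chromosomes": len(chroms),
                }
            )
        else:
            rows.append(
                {
                    "state": state,
                    "count": 0,
                    "mean_overlap_bp": np.nan,
                    "median_overlap_bp": np.nan,
                    "n_chromosomes": 0,
                }
            )
    return pd.DataFrame(rows)


def per_chromosome_fold(
    observed_by_chrom: pd.Series | dict[str, int],
    genome: GenomeModel,
) -> pd.DataFrame:
    """Observed/expected fold per chromosome under a length-proportional null.

    Expected count on chromosome c is total_observed * length_c /
    genome_length; fold is observed/expected.  With zero total observed,
    all folds are missing.  Folds weighted by expected counts average to 1
    by construction.
    """
    obs = pd.Series(observed_by_chrom, dtype=float)
    obs = obs.reindex(list(genome.chrom_sizes), fill_value=0.0)
    total = obs.sum()
    lengths = pd.Series(genome.chrom_sizes, dtype=float)
    expected = total * lengths / genome.total_length
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(expected > 0, obs / expected, np.nan)
    return pd.DataFrame(
        {
            "chrom": obs.index,
            "observed": obs.to_numpy(),
            "expected": expected.to_numpy(),
            "fold": fold,
        }
    )


def intersect_snp_qtl_enhancer_motif(
    snps: pd.DataFrame,
    qtl: Sequence[GenomicInterval],
    track: StateSegmentation,
    motifs: Sequence[GenomicInterval],
    states: Sequence[str] = ENHANCER_STATES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNPs inside a QTL AND an enhancer-state segment AND a motif.

    ``snps`` needs columns snp_id, chrom, pos (1-based, VCF convention);
    motif labels carry 'motif_id:family'.  Returns (hits, family_summary):
    hits has one row per (snp, qtl, segment, motif) combination; the family
    summary is computed over deduplicated (snp, family) pairs and reports
    percentages, alongside both the raw hit count and the unique-SNP count.
    """
    for col in ("snp_id", "chrom", "pos"):
        if col not in snps.columns:
            raise ValidationError(f"SNP table missing column {col!r}")
    probes = [
        GenomicInterval(str(r.chrom), int(r.pos) - 1, int(r.pos), label=str(r.snp_id))
        for r in snps.itertuples(index=False)
    ]
    qtl_list = list(qtl)
    enh = [s for s in track.segments if s.label in states]
    motif_list = list(motifs)

    in_qtl: dict[int, list[int]] = {}
    for qi, si, _ in find_overlaps(probes, qtl_list):
        in_qtl.setdefault(qi, []).append(si)
    in_enh: dict[int, list[int]] = {}
    for qi, si, _ in find_overlaps(probes, enh):
        in_enh.setdefault(qi, []).append(si)
    in_motif: dict[int, list[int]] = {}
    for qi, si, _ in find_overlaps(probes, motif_list):
        in_motif.setdefault(qi, []).append(si)

    rows = []
    for i, probe in enumerate(probes):
        if i not in in_qtl or i not in in_enh or i not in in_motif:
            continue
        for q in in_qtl[i]:
            for e in in_enh[i]:
                for m in in_motif[i]:
                    motif_label = motif_list[m].label or ""
                    motif_id, _, family = motif_label.partition(":")
                    qtl_label = qtl_list[q].label or ""
                    qtl_id, _, trait = qtl_label.partition(":")
                    rows.append(
                        {
                            "snp_id": probe.label,
                            "chrom": probe.chrom,
                            "pos": probe.start + 1,
                            "qtl_id": qtl_id,
                            "trait": trait,
                            "enhancer_state": enh[e].label,
                            "motif_id": motif_id,
                            "tf_family": family,
                        }
                    )
    hits = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "qtl_id", "trait",
            "enhancer_state", "motif_id", "tf_family",
        ],
    )
    if len(hits):
        snp_fam = hits[["snp_id", "tf_family"]].drop_duplicates()
        fam_counts = snp_fam["tf_family"].value_counts()
        summary = pd.DataFrame(
            {
                "tf_family": fam_counts.index,
                "n_snps": fam_counts.to_numpy(),
                "pct": 100.0 * fam_counts.to_numpy() / len(snp_fam),
            }
        )
        summary.attrs["n_hits"] = len(hits)
        summary.attrs["n_unique_snps"] = hits["snp_id"].nunique()
    else:
        summary = pd.DataFrame(columns=["tf_family", "n_snps", "pct"])
        summary.attrs["n_hits"] = 0
        summary.attrs["n_unique_snps"] = 0
    return hits, summary
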