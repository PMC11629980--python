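"""Epigenetic divergence between duplicate gene copies.

Promoter windows (2 kb upstream of the TSS) of each gene copy are
summarized two ways: per-mark coverage profiles (binned across the window)
whose genome-normalized log2 fold enrichments are z-scored across genes,
and 10-dimensional chromatin-state segment counts.  Divergence within a
pair is measured by the Pearson correlation r of the two copies' profiles
and the dissimilarity 1 - r; fate categories are compared with the
Wilcoxon rank-sum test (exact enumeration for small samples, normal
approximation with midranks and continuity correction otherwise).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_core import (
    STATE_NAMES,
    GeneRecord,
    GenomeModel,
    GenomicInterval,
    StateSegmentation,
    ValidationError,
    find_overlaps,
)

PROMOTER_WINDOW = 2_000  # bp upstream of the TSS
LOG2_PSEUDOCOUNT = 1e-3

EXACT_MAX_N = 12  # exact rank-sum enumeration up to this combined sample size


def zscore_enrichment(log2_ratios: np.ndarray) -> np.ndarray:
    """Standardize log2 fold-enrichment ratios: Z = (x - mean) / std.

    Uses the population (n-denominator) standard deviation; the output has
    mean 0 and population std 1.  All-equal input is an error.
    """
    x = np.asarray(log2_ratios, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values to z-score")
    mu = x.mean()
    sd = x.std()  # population std (ddof=0)
    if sd == 0:
        raise ValidationError("zero standard deviation; z-scores undefined")
    return (x - mu) / sd


def pair_correlation(
    profile_a: np.ndarray, profile_b: np.ndarray
) -> tuple[float, float]:
    """Pearson r between two profile vectors and the dissimilarity 1 - r.

    Zero variance in either vector leaves r undefined (NaN, NaN).
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValidationError("profiles must be equal length >= 2")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return np.nan, np.nan
    r = float(np.corrcoef(a, b)[0, 1])
    return r, 1.0 - r


def promoter_window(gene: GeneRecord, genome: GenomeModel, window: int = PROMOTER_WINDOW) -> GenomicInterval:
    """The 2-kb (by default) region immediately upstream of the TSS."""
    if gene.strand == "+":
        lo, hi = gene.tss - window, gene.tss
    else:
        lo, hi = gene.tss, gene.tss + window
    lo = max(0, lo)
    hi = min(genome.chrom_sizes[gene.chrom], hi)
    if hi <= lo:
        raise ValidationError(f"empty promoter window for {gene.gene_id}")
    return GenomicInterval(gene.chrom, lo, hi, label=gene.gene_id)


def mark_coverage_profile(
    gene: GeneRecord,
    peaks: Sequence[GenomicInterval],
    genome: GenomeModel,
    window: int = PROMOTER_WINDOW,
    n_bins: int = 10,
) -> np.ndarray:
    """Per-bin covered fraction of the promoter window by a peak set."""
    win = promoter_window(gene, genome, window)
    edges = np.linspace(win.start, win.end, n_bins + 1)
    cov = np.zeros(n_bins)
    for _, si, _ in find_overlaps([win], list(peaks)):
        p = peaks[si]
        lo = np.maximum(edges[:-1], p.start)
        hi = np.minimum(edges[1:], p.end)
        cov += np.clip(hi - lo, 0, None)
    widths = np.diff(edges)
    prof = np.minimum(cov / widths, 1.0)
    return prof if gene.strand == "+" else prof[::-1]


def state_counts(
    gene: GeneRecord,
    track: StateSegmentation,
    genome: GenomeModel,
    window: int = PROMOTER_WINDOW,
) -> np.ndarray:
    """10-vector of state segment counts intersecting the promoter window."""
    win = promoter_window(gene, genome, window)
    counts = dict.fromkeys(STATE_NAMES, 0)
    for _, si, _ in find_overlaps([win], track.segments):
        counts[track.segments[si].label] += 1
    return np.array([counts[s] for s in STATE_NAMES], dtype=float)


def state_count_correlation(
    counts_d1: np.ndarray, counts_d2: np.ndarray
) -> tuple[float, np.ndarray]:
    """Pearson r of two 10-dim state-count vectors and per-state shared
    counts min(count_d1, count_d2).  A pair with no segments in either
    window is uninformative (r = NaN)."""
    c1 = np.asarray(counts_d1, dtype=float)
    c2 = np.asarray(counts_d2, dtype=float)
    shared = np.minimum(c1, c2)
    if c1.sum() == 0 and c2.sum() == 0:
        return np.nan, shared
    r, _ = pair_correlation(c1, c2)
    return r, shared


def wilcoxon_category_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two groups.

    Returns (rank_sum_of_a, p).  Small samples (n_a + n_b <= 12) with no
    ties use exact enumeration; otherwise the normal approximation with
    midrank ties and continuity correction.  Identical pooled values give
    p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both groups need at least 2 values")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[: a.size].sum())
    if np.allclose(pooled, pooled[0]):
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def pairwise_divergence(
    profiles: pd.DataFrame,
    value_col: str = "value",
) -> pd.DataFrame:
    """Per-pair, per-mark correlation from a long profile table.

    ``profiles`` columns: pair_id, copy ('d1'/'d2'), mark, bin, value, and
    optionally true_fate (propagated).  Returns pair_id, mark, r,
    dissimilarity (plus fate when available).
    """
    needed = {"pair_id", "copy", "mark", "bin", value_col}
    if not needed.issubset(profiles.columns):
        raise ValidationError(f"profile table needs columns {sorted(needed)}")
    has_fate = "true_fate" in profiles.columns
    rows = []
    for (pair_id, mark), grp in profiles.groupby(["pair_id", "mark"], sort=True):
        d1 = grp[grp["copy"] == "d1"].sort_values("bin")[value_col].to_numpy()
        d2 = grp[grp["copy"] == "d2"].sort_values("bin")[value_col].to_numpy()
        if d1.size != d2.size or d1.size < 2:
            continue
        r, dis = pair_correlation(d1, d2)
        row = {"pair_id": pair_id, "mark": mark, "r": r, "dissimilarity": dis}
        if has_fate:
            row["fate"] = grp["true_fate"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_fate_categories(
    divergence: pd.DataFrame,
    metric: str = "r",
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons of a divergence metric between every
    pair of fate categories, pooling marks.  Requires a 'fate' column."""
    if "fate" not in divergence.columns:
        raise ValidationError("divergence table has no fate column")
    cats = sorted(divergence["fate"].dropna().unique())
    rows = []
    for i, ca in enumerate(cats):
        for cb in cats[i + 1 :]:
            va = divergence.loc[divergence["fate"] == ca, metric].dropna().to_numpy()
            vb = divergence.loc[divergence["fate"] == cb, metric].dropna().to_numpy()
            if va.size < 2 or vb.size < 2:
                continue
            w, p = wilcoxon_category_compare(va, vb)
            rows.append(
                {
                    "category_a": ca,
                    "category_b": cb,
                    "mean_a": float(va.mean()),
                    "mean_b": float(vb.mean()),
                    "rank_sum_a": w,
                    "pvalue": p,
                }
            )
    return pd.DataFrame(rows)
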