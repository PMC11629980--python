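"""Per-CpG methylation levels, depth filtering and meta-profiles.

The methylation level of a site is reads_c / (reads_c + reads_t), i.e. the
fraction of reads calling C at a CpG after bisulfite conversion.  Sites are
filtered per sample to depth >= 10 and depth <= the sample's 99.9th
coverage percentile (computed before any filtering) to remove both
unreliable and PCR-inflated sites.  TSS profiles average per-gene, not
per-site, so CpG-dense genes do not dominate.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_core import (
    GeneRecord,
    GenomicInterval,
    StateSegmentation,
    ValidationError,
)

MIN_DEPTH = 10
MAX_QUANTILE = 0.999

REQUIRED_COLS = ("chrom", "pos", "reads_c", "reads_t")


def _check_sites(sites: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLS if c not in sites.columns]
    if missing:
        raise ValidationError(f"site table missing columns {missing}")
    if (sites["reads_c"] < 0).any() or (sites["reads_t"] < 0).any():
        raise ValidationError("negative read counts")


def add_levels(sites: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``level`` column; zero-depth level is NaN."""
    _check_sites(sites)
    out = sites.copy()
    depth = out["reads_c"] + out["reads_t"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(depth > 0, out["reads_c"] / depth, np.nan)
    return out


def filter_sites(
    sites: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    max_quantile: float = MAX_QUANTILE,
) -> pd.DataFrame:
    """Keep sites with min_depth <= depth <= the depth's upper quantile.

    The quantile is computed on the unfiltered sample, per sample.  The
    'higher' empirical quantile (the smallest attained depth at or above
    the quantile rank) is used so the threshold is always a depth the
    sample actually reached; with integer read depths this also makes the
    filter idempotent.  Empty input passes through empty.
    """
    _check_sites(sites)
    if len(sites) == 0:
        return sites.copy()
    depth = (sites["reads_c"] + sites["reads_t"]).to_numpy()
    hi = np.quantile(depth, max_quantile, method="higher")
    keep = (depth >= min_depth) & (depth <= hi)
    return sites.loc[keep].reset_index(drop=True)


def tss_methylation_profile(
    sites: pd.DataFrame,
    genes: Sequence[GeneRecord],
    window: int = 10_000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Mean methylation level per distance-to-TSS bin, gene-weighted.

    Offsets are strand-aware (upstream negative).  Within each gene, site
    levels are averaged per bin; bins are then averaged across genes with
    equal weight.  Bins no gene contributes to are reported NaN.
    Returns columns offset (bin left edge), mean_level, n_genes.
    """
    if window % bin_size != 0:
        raise ValidationError("window must be a multiple of bin_size")
    df = add_levels(sites)
    n_bins = 2 * window // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    by_chrom = {c: sub for c, sub in df.groupby("chrom")}
    for g in genes:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        off = sub["pos"].to_numpy() - g.tss
        if g.strand == "-":
            off = -off
        sel = (off >= -window) & (off < window)
        if not sel.any():
            continue
        idx = (off[sel] + window) // bin_size
        lv = sub["level"].to_numpy()[sel]
        ok = ~np.isnan(lv)
        if not ok.any():
            continue
        gene_sum = np.bincount(idx[ok], weights=lv[ok], minlength=n_bins)
        gene_cnt = np.bincount(idx[ok], minlength=n_bins)
        has = gene_cnt > 0
        sums[has] += gene_sum[has] / gene_cnt[has]
        counts[has] += 1
    offsets = np.arange(-window, window, bin_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return pd.DataFrame({"offset": offsets, "mean_level": mean, "n_genes": counts.astype(int)})


def state_methylation_profile(
    sites: pd.DataFrame,
    track: StateSegmentation,
    flank: int = 2_000,
    n_body_bins: int = 20,
    flank_bin: int = 100,
) -> pd.DataFrame:
    """Mean level across the scaled body of each state plus fixed-bp flanks.

    Each state instance's body is rescaled to ``n_body_bins`` bins; flanks
    are binned at ``flank_bin`` bp.  Per-bin means are computed within each
    instance then averaged across instances.  States with no instances are
    omitted with a warning.

    Returns a long table: state, bin (0..n_flank-1 upstream flank, then
    body bins, then downstream flank), region ('upstream'/'body'/
    'downstream'), mean_level, n_instances.
    """
    if flank % flank_bin != 0:
        raise ValidationError("flank must be a multiple of flank_bin")
    df = add_levels(sites)
    n_flank = flank // flank_bin
    total_bins = 2 * n_flank + n_body_bins
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c, sub in df.groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[c] = (sub["pos"].to_numpy(), sub["level"].to_numpy())

    rows = []
    states = sorted({s.label for s in track.segments})
    for state in states:
        instances = [s for s in track.segments if s.label == state]
        sums = np.zeros(total_bins)
        counts = np.zeros(total_bins)
        for inst in instances:
            arr = by_chrom.get(inst.chrom)
            if arr is None:
                continue
            pos, lv = arr
            lo, hi = inst.start - flank, inst.end + flank
            i0, i1 = np.searchsorted(pos, [lo, hi])
            if i1 <= i0:
                continue
            p = pos[i0:i1]
            v = lv[i0:i1]
            ok = ~np.isnan(v)
            p, v = p[ok], v[ok]
            if p.size == 0:
                continue
            bin_idx = np.empty(p.size, dtype=int)
            up = p < inst.start
            down = p >= inst.end
            body = ~(up | down)
            bin_idx[up] = (p[up] - lo) // flank_bin
            # body positions rescaled to n_body_bins
            if body.any():
                frac = (p[body] - inst.start) / inst.length
                bin_idx[body] = n_flank + np.minimum(
                    (frac * n_body_bins).astype(int), n_body_bins - 1
                )
            bin_idx[down] = n_flank + n_body_bins + (p[down] - inst.end) // flank_bin
            inst_sum = np.bincount(bin_idx, weights=v, minlength=total_bins)
            inst_cnt = np.bincount(bin_idx, minlength=total_bins)
            has = inst_cnt > 0
            sums[has] += inst_sum[has] / inst_cnt[has]
            counts[has] += 1
        if not instances:
            warnings.warn(f"state {state} has no instances; omitted", stacklevel=2)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums / counts, np.nan)
        for b in range(total_bins):
            region = (
                "upstream" if b < n_flank
                else "body" if b < n_flank + n_body_bins
                else "downstream"
            )
            rows.append(
                {
                    "state": state,
                    "bin": b,
                    "region": region,
                    "mean_level": float(mean[b]),
                    "n_instances": int(counts[b]),
                }
            )
    return pd.DataFrame(rows)


def methylation_expression_association(
    sites: pd.DataFrame,
    genes: Sequence[GeneRecord],
    tpm: pd.Series,
    window: int = 3_000,
) -> tuple[pd.DataFrame, float, float, float]:
    """Promoter methylation versus expression.

    Per gene, the mean filtered-site level within +/-window of the TSS;
    Pearson correlation of that level with log10(TPM + 0.01).  Returns
    (per-gene table, r, r_squared, p_value).  Fewer than 3 genes with data
    is an error; zero variance in either variable flags r as NaN.
    """
    from scipy import stats

    df = add_levels(sites)
    by_chrom = {c: sub for c, sub in df.groupby("chrom")}
    rows = []
    for g in genes:
        if g.gene_id not in tpm.index:
            continue
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        off = sub["pos"].to_numpy() - g.tss
        sel = (off >= -window) & (off < window)
        lv = sub["level"].to_numpy()[sel]
        lv = lv[~np.isnan(lv)]
        if lv.size == 0:
            continue
        rows.append(
            {
                "gene_id": g.gene_id,
                "mean_level": float(lv.mean()),
                "n_sites": int(lv.size),
                "log10_tpm": float(np.log10(float(tpm[g.gene_id]) + 0.01)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValidationError("fewer than 3 genes with methylation data")
    x = table["mean_level"].to_numpy()
    y = table["log10_tpm"].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return table, np.nan, np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return table, float(r), float(r**2), float(p)
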