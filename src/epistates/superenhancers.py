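"""Super-enhancer detection from H3K27ac peak calls with signal.

Peaks within 12.5 kb of each other (nearest-edge gap) are stitched into
clusters whose signal is the sum of member signals.  Clusters are ranked by
ascending signal, both axes scaled to [0, 1], and the discrete tangent
slope of the signal-vs-rank curve is estimated; the maximal suffix of ranks
whose slope stays above 1 is flagged super.  Per-tissue super-enhancer sets
are merged across tissues by single linkage when two calls overlap by at
least half the shorter call's length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_core import (
    GeneRecord,
    GenomicInterval,
    ValidationError,
    find_overlaps,
    overlap_length,
)

STITCH_GAP = 12_500
MERGE_OVERLAP_FRAC = 0.5
GENE_WINDOW = 10_000
EXPRESSED_TPM = 2.0
REPRESSED_TPM = 0.2


@dataclass
class RankedEnhancer:
    """A stitched enhancer cluster with its position on the ranked curve."""

    interval: GenomicInterval
    signal: float
    n_peaks: int
    rank: int = -1
    scaled_rank: float = np.nan
    scaled_signal: float = np.nan
    is_super: bool = False


def stitch(
    peaks: Sequence[GenomicInterval], gap: int = STITCH_GAP
) -> list[RankedEnhancer]:
    """Stitch peaks whose nearest edges are within ``gap`` bp.

    The cluster interval spans from the first member's start to the last
    member's end; its signal is the sum of member scores.  Peaks with no
    score contribute 0; a negative score is a validation error.
    """
    for p in peaks:
        if p.score is not None and p.score < 0:
            raise ValidationError(f"negative signal on peak {p.chrom}:{p.start}")
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    clusters: list[RankedEnhancer] = []
    cur: list[GenomicInterval] = []
    for p in ordered:
        if cur and p.chrom == cur[-1].chrom and p.start - max(q.end for q in cur) <= gap:
            cur.append(p)
        else:
            if cur:
                clusters.append(_close_cluster(cur))
            cur = [p]
    if cur:
        clusters.append(_close_cluster(cur))
    return clusters


def _close_cluster(members: list[GenomicInterval]) -> RankedEnhancer:
    start = min(m.start for m in members)
    end = max(m.end for m in members)
    signal = float(sum(m.score or 0.0 for m in members))
    return RankedEnhancer(
        interval=GenomicInterval(members[0].chrom, start, end),
        signal=signal,
        n_peaks=len(members),
    )


def tangent_slopes(signals: np.ndarray, half_window: int | None = None) -> np.ndarray:
    """Discrete tangent slope of the scaled signal-vs-rank curve.

    Signals must be sorted ascending.  Both axes are scaled to [0, 1] and
    the slope at rank i is the backward difference over ``half_window``
    ranks (so a rank is credited with the rise on its low side, keeping the
    flagged set a clean suffix); rank 0 uses the forward difference.
    """
    n = signals.size
    if n < 2:
        return np.zeros(n)
    h = half_window if half_window is not None else max(1, n // 100)
    x = np.arange(n) / (n - 1)
    rng = signals[-1] - signals[0]
    if rng == 0:
        return np.full(n, np.nan)
    y = (signals - signals[0]) / rng
    slopes = np.empty(n)
    for i in range(n):
        j = max(0, i - h)
        if j == i:  # first rank: one-sided forward difference
            j2 = min(n - 1, i + h)
            slopes[i] = (y[j2] - y[i]) / (x[j2] - x[i])
        else:
            slopes[i] = (y[i] - y[j]) / (x[i] - x[j])
    return slopes


def call_superenhancers(
    clusters: Sequence[RankedEnhancer],
    slope_cutoff: float = 1.0,
    half_window: int | None = None,
) -> list[RankedEnhancer]:
    """Rank clusters by ascending signal and flag the high-signal tail.

    The flagged set is the maximal suffix of ranks whose tangent slope
    exceeds ``slope_cutoff``; a slope <= cutoff anywhere after a rank
    excludes everything at or below it.  All-equal signals give no calls.
    """
    if len(clusters) < 3:
        raise ValidationError("need at least 3 clusters to rank")
    order = np.argsort([c.signal for c in clusters], kind="stable")
    ranked = [clusters[i] for i in order]
    n = len(ranked)
    signals = np.array([c.signal for c in ranked])
    slopes = tangent_slopes(signals, half_window=half_window)
    if np.isnan(slopes).all():
        warnings.warn("all cluster signals equal; no super-enhancers called", stacklevel=2)
        cut = n  # nothing flagged
    else:
        below = np.nonzero(slopes <= slope_cutoff)[0]
        cut = int(below[-1]) + 1 if below.size else 0
    for i, c in enumerate(ranked):
        c.rank = i
        c.scaled_rank = i / (n - 1)
        rng = signals[-1] - signals[0]
        c.scaled_signal = (c.signal - signals[0]) / rng if rng > 0 else np.nan
        c.is_super = i >= cut
    return ranked


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_across_tissues(
    se_by_tissue: Mapping[str, Sequence[GenomicInterval]],
    min_overlap_frac: float = MERGE_OVERLAP_FRAC,
    reciprocal: bool = False,
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Nonredundant super-enhancer set across tissues (single linkage).

    Two calls merge when their overlap is at least ``min_overlap_frac`` of
    the shorter call's length (or of both lengths with ``reciprocal``).
    Merged intervals span the union of their members.  Returns the
    nonredundant set and a sharing matrix (one row per merged SE, one
    boolean column per tissue).
    """
    tissues = list(se_by_tissue)
    flat: list[tuple[str, GenomicInterval]] = [
        (t, iv) for t in tissues for iv in se_by_tissue[t]
    ]
    n = len(flat)
    uf = _UnionFind(n)
    ivs = [iv for _, iv in flat]
    for qi, si, bp in find_overlaps(ivs, ivs):
        if qi >= si:
            continue
        a, b = ivs[qi], ivs[si]
        if reciprocal:
            ok = bp >= min_overlap_frac * a.length and bp >= min_overlap_frac * b.length
        else:
            ok = bp >= min_overlap_frac * min(a.length, b.length)
        if ok:
            uf.union(qi, si)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    merged: list[GenomicInterval] = []
    rows = []
    for root in sorted(groups, key=lambda r: (ivs[r].chrom, ivs[r].start)):
        members = groups[root]
        chrom = ivs[members[0]].chrom
        start = min(ivs[i].start for i in members)
        end = max(ivs[i].end for i in members)
        merged_iv = GenomicInterval(chrom, start, end, label=f"se{len(merged):05d}")
        merged.append(merged_iv)
        present = {t: False for t in tissues}
        for i in members:
            present[flat[i][0]] = True
        rows.append({"se_id": merged_iv.label, "chrom": chrom, "start": start, "end": end, **present})
    sharing = pd.DataFrame(rows)
    return merged, sharing


def assign_genes(
    ses: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    tpm: pd.Series,
    window: int = GENE_WINDOW,
    expressed_tpm: float = EXPRESSED_TPM,
    repressed_tpm: float = REPRESSED_TPM,
) -> pd.DataFrame:
    """Assign each super-enhancer to genes within ``window`` bp of its body.

    A gene is assigned when its body extended by +/-window intersects the
    SE.  Each assignment is annotated expressed (TPM > expressed_tpm),
    repressed (TPM < repressed_tpm) or intermediate, using the supplied
    per-gene TPM (typically the SE's tissue, or the max across tissues for
    the nonredundant set).
    """
    extended = [
        GenomicInterval(g.chrom, max(0, g.start - window), g.end + window, label=g.gene_id)
        for g in genes
    ]
    rows = []
    for qi, si, bp in find_overlaps(list(ses), extended):
        se = ses[qi]
        g = genes[si]
        t = float(tpm.get(g.gene_id, np.nan))
        if np.isnan(t):
            klass = "unknown"
        elif t > expressed_tpm:
            klass = "expressed"
        elif t < repressed_tpm:
            klass = "repressed"
        else:
            klass = "intermediate"
        rows.append(
            {
                "se_id": se.label or f"{se.chrom}:{se.start}-{se.end}",
                "gene_id": g.gene_id,
                "overlap_bp": bp,
                "tpm": t,
                "class": klass,
            }
        )
    return pd.DataFrame(rows, columns=["se_id", "gene_id", "overlap_bp", "tpm", "class"])
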