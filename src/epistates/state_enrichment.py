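"""Fold enrichment of chromatin states in genomic elements and per-state
track summaries.

The enrichment statistic is the base-level ratio (C/A)/(B/D), where A is
the number of bases in the state, B the bases in the element, C the bases
in their overlap and D the genome size.  A value of 1 means the state
covers the element at exactly its genome-wide rate.  Element intervals are
merged before B and C are counted, so the statistic is invariant to how
the element set is split into pieces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_core import (
    STATE_NAMES,
    GeneRecord,
    GenomeModel,
    GenomicInterval,
    StateSegmentation,
    ValidationError,
    intersect_bp,
    merge_intervals,
    total_bp,
)


@dataclass
class EnrichmentResult:
    """Base counts and fold enrichment of one state in one element set."""

    state: str
    element: str
    A: int  # bases in the state
    B: int  # bases in the element (after merging)
    C: int  # bases overlapping
    D: int  # bases in the genome
    fold: float | None  # (C/A)/(B/D); None when A or B is 0

    def __post_init__(self) -> None:
        if self.C > min(self.A, self.B):
            raise ValidationError("overlap C exceeds min(A, B)")


def fold_enrichment(
    track: StateSegmentation,
    element: Sequence[GenomicInterval],
    genome: GenomeModel,
    state: str,
    element_name: str = "element",
) -> EnrichmentResult:
    """Fold enrichment (C/A)/(B/D) of one state against an element set.

    The element intervals are merged before counting.  A state absent from
    the track (A = 0) or an empty element (B = 0) yields ``fold=None``
    rather than 0 or infinity.
    """
    state_ivs = track.by_state(state)
    merged_elem = merge_intervals(element)
    A = total_bp(state_ivs, merge=False)  # track segments are disjoint
    B = sum(iv.length for iv in merged_elem)
    C = intersect_bp(state_ivs, merged_elem)
    D = genome.total_length
    if A == 0 or B == 0:
        fold = None
    else:
        fold = (C / A) / (B / D)
    return EnrichmentResult(state=state, element=element_name, A=A, B=B, C=C, D=D, fold=fold)


def enrichment_table(
    track: StateSegmentation,
    elements: dict[str, Sequence[GenomicInterval]],
    genome: GenomeModel,
) -> pd.DataFrame:
    """All states x all element sets, one EnrichmentResult per row."""
    rows = []
    for name, ivs in elements.items():
        for state in STATE_NAMES:
            r = fold_enrichment(track, ivs, genome, state, element_name=name)
            rows.append(
                {
                    "state": r.state,
                    "element": r.element,
                    "A": r.A,
                    "B": r.B,
                    "C": r.C,
                    "D": r.D,
                    "fold": np.nan if r.fold is None else r.fold,
                }
            )
    return pd.DataFrame(rows)


def state_summary(track: StateSegmentation, genome: GenomeModel) -> pd.DataFrame:
    """Per-state segment count, % of genome covered, mean/median length.

    Percentages are reported against genome size; when the track is not a
    complete tiling they will not sum to 100 and a warning is emitted.
    """
    lengths: dict[str, list[int]] = {s: [] for s in STATE_NAMES}
    for seg in track.segments:
        lengths[seg.label].append(seg.length)
    covered = sum(seg.length for seg in track.segments)
    if covered != genome.total_length:
        warnings.warn(
            f"track covers {covered} of {genome.total_length} bases; "
            "percentages reported against genome size",
            stacklevel=2,
        )
    rows = []
    for state in STATE_NAMES:
        ls = np.array(lengths[state], dtype=float)
        rows.append(
            {
                "state": state,
                "count": ls.size,
                "pct_genome": 100.0 * ls.sum() / genome.total_length,
                "mean_length": ls.mean() if ls.size else np.nan,
                "median_length": float(np.median(ls)) if ls.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def state_density_profile(
    track: StateSegmentation,
    genes: Sequence[GeneRecord],
    window: int = 10_000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Per-state density of coverage versus distance to the TSS.

    For each bin offset in [-window, +window) (strand-aware: upstream is
    negative), the density is the fraction of genes whose bin overlaps a
    segment of the state by at least one base.

    Returns a long DataFrame with columns state, offset (bin left edge in
    TSS-relative coordinates), density.
    """
    if window % bin_size != 0:
        raise ValidationError("window must be a multiple of bin_size")
    if not genes:
        raise ValidationError("no genes supplied")
    n_bins = 2 * window // bin_size
    seg_by_chrom_state: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for seg in track.segments:
        key = (seg.chrom, seg.label)
        seg_by_chrom_state.setdefault(key, ([], []))  # type: ignore[arg-type]
        seg_by_chrom_state[key][0].append(seg.start)  # type: ignore[union-attr]
        seg_by_chrom_state[key][1].append(seg.end)  # type: ignore[union-attr]
    seg_arrays = {
        k: (np.asarray(v[0]), np.asarray(v[1])) for k, v in seg_by_chrom_state.items()
    }

    counts = {s: np.zeros(n_bins) for s in STATE_NAMES}
    for g in genes:
        for state in STATE_NAMES:
            arr = seg_arrays.get((g.chrom, state))
            if arr is None:
                continue
            starts, ends = arr
            # genomic span of the profile window around this TSS
            lo = g.tss - window
            hi = g.tss + window
            sel = (starts < hi) & (ends > lo)
            if not sel.any():
                continue
            hit = np.zeros(n_bins, dtype=bool)
            for s, e in zip(starts[sel], ends[sel]):
                b0 = max(0, (max(s, lo) - lo) // bin_size)
                b1 = min(n_bins, -(-(min(e, hi) - lo) // bin_size))
                hit[b0:b1] = True
            if g.strand == "-":
                hit = hit[::-1]
            counts[state] += hit
    rows = []
    offsets = np.arange(-window, window, bin_size)
    for state in STATE_NAMES:
        dens = counts[state] / len(genes)
        for off, d in zip(offsets, dens):
            rows.append({"state": state, "offset": int(off), "density": float(d)})
    return pd.DataFrame(rows)
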