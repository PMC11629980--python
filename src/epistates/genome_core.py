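"""Core genomic data types, interval arithmetic and flat-file I/O.

Coordinates are 0-based half-open ([start, end)) everywhere inside the
package; BED is read verbatim, 1-based inputs (GFF-derived tables, VCF
positions) are shifted on read.  All overlap computations in the higher
level modules go through the small interval engine defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The 10-state chromatin vocabulary used throughout: two promoter states,
#: four enhancer flavours, an accessible CpG-rich state, bivalent enhancers,
#: polycomb-repressed and quiescent chromatin.
STATE_NAMES: tuple[str, ...] = (
    "TssA",
    "TssAFlnk",
    "EnhG",
    "Str.Enh",
    "MidEnh",
    "EnhPois",
    "ATAC-CpG",
    "BivEnh",
    "ReprPC",
    "Quies",
)

#: States 1-5: active promoters and active enhancers.
ACTIVE_STATES: tuple[str, ...] = STATE_NAMES[:5]

#: The three active enhancer states used in QTL intersection analyses.
ENHANCER_STATES: tuple[str, ...] = ("EnhG", "Str.Enh", "MidEnh")

HISTONE_MARKS: tuple[str, ...] = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised for malformed input files; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A [start, end) span on a chromosome with optional label and score."""

    chrom: str
    start: int
    end: int
    label: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.score is not None and self.score < 0:
            raise ValidationError(f"negative score {self.score} on {self.chrom}:{self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.label or "")


@dataclass
class GeneRecord:
    """A gene with strand-aware TSS/TES anchors and per-tissue TPM."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        for tissue, v in self.tpm.items():
            if v < 0:
                raise ValidationError(f"gene {self.gene_id}: negative TPM in {tissue}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GenomeModel:
    """Chromosome names and lengths; total_length is the D of fold enrichment."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {chrom} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes


@dataclass
class StateSegmentation:
    """A per-tissue chromatin-state tiling: sorted, non-overlapping segments."""

    tissue: str
    segments: list[GenomicInterval]

    def __post_init__(self) -> None:
        by_chrom: dict[str, GenomicInterval] = {}
        for seg in self.segments:
            if seg.label not in STATE_NAMES:
                raise ValidationError(f"unknown state label {seg.label!r}")
            prev = by_chrom.get(seg.chrom)
            if prev is not None:
                if seg.start < prev.end:
                    raise ValidationError(
                        f"segments overlap or are unsorted on {seg.chrom} at {seg.start}"
                    )
            by_chrom[seg.chrom] = seg

    def by_state(self, state: str) -> list[GenomicInterval]:
        return [s for s in self.segments if s.label == state]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "state": [s.label for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two half-open intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _group_by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """chrom -> (starts, ends, original indices), in input order."""
    out: dict[str, list[list[int]]] = {}
    for i, iv in enumerate(intervals):
        out.setdefault(iv.chrom, [[], [], []])
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
        out[iv.chrom][2].append(i)
    return {
        c: (np.asarray(s), np.asarray(e), np.asarray(idx))
        for c, (s, e, idx) in out.items()
    }


def find_overlaps(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int, int]]:
    """All (query_index, subject_index, overlap_bp) pairs with overlap > 0.

    Equivalent to the all-pairs brute force; output ordered by query index
    then subject index.
    """
    subj = _group_by_chrom(subject)
    pairs: list[tuple[int, int, int]] = []
    for qi, q in enumerate(query):
        grp = subj.get(q.chrom)
        if grp is None:
            continue
        s_start, s_end, s_idx = grp
        hit = (s_start < q.end) & (s_end > q.start)
        if not hit.any():
            continue
        ov = np.minimum(s_end[hit], q.end) - np.maximum(s_start[hit], q.start)
        for si, bp in sorted(zip(s_idx[hit].tolist(), ov.tolist())):
            pairs.append((qi, si, int(bp)))
    return pairs


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as sorted, disjoint spans (labels dropped)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_bp(intervals: Iterable[GenomicInterval], merge: bool = True) -> int:
    ivs = merge_intervals(intervals) if merge else list(intervals)
    return sum(iv.length for iv in ivs)


def intersect_bp(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Total bp in the intersection of the unions of two interval sets."""
    a_m = merge_intervals(a)
    b_m = merge_intervals(b)
    total = 0
    for _, _, bp in find_overlaps(a_m, b_m):
        total += bp
    return total


def flank_tss(
    gene: GeneRecord, upstream: int, downstream: int, genome: GenomeModel
) -> GenomicInterval:
    """Strand-aware window around the TSS, clipped to chromosome bounds.

    On the minus strand "upstream" extends toward larger coordinates.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("upstream/downstream must be non-negative")
    if gene.chrom not in genome:
        raise ValidationError(f"unknown chromosome {gene.chrom!r} for gene {gene.gene_id}")
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    lo = max(0, lo)
    hi = min(genome.chrom_sizes[gene.chrom], hi)
    if hi <= lo:
        raise ValidationError(
            f"empty TSS window for gene {gene.gene_id} after clipping"
        )
    return GenomicInterval(gene.chrom, lo, hi, label=gene.gene_id)


# ---------------------------------------------------------------------------
# File I/O (BED3/4/5, gene tables, chrom.sizes)
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, fmt: str = "bed") -> list[GenomicInterval]:
    """Read BED3/BED4/BED5 (or an equivalent headerless TSV) into intervals.

    BED coordinates are taken verbatim as 0-based half-open.  Malformed
    lines raise :class:`ParseError` naming the 1-based line number.
    """
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            label = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: non-numeric score") from exc
            try:
                out.append(GenomicInterval(chrom, start, end, label, score))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; columns beyond chrom/start/end only if used."""
    n_cols = 3
    if any(iv.score is not None for iv in intervals):
        n_cols = 5
    elif any(iv.label is not None for iv in intervals):
        n_cols = 4
    with open(path, "w") as fh:
        for iv in intervals:
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if n_cols >= 4:
                row.append(iv.label if iv.label is not None else ".")
            if n_cols >= 5:
                row.append(format(iv.score, "g") if iv.score is not None else ".")
            fh.write("\t".join(row) + "\n")


def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Two-column chrom.sizes TSV (UCSC dialect)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer length") from exc
    return GenomeModel(sizes)


def write_chrom_sizes(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


GENE_TABLE_FIXED_COLS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_table(path: str | Path) -> tuple[list[GeneRecord], list[str]]:
    """Gene TSV with header gene_id,chrom,start,end,strand + one TPM column
    per tissue.  Coordinates are 0-based half-open (as written by this
    package); returns the genes and the tissue column order.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_FIXED_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    tissues = [c for c in df.columns if c not in GENE_TABLE_FIXED_COLS]
    genes = [
        GeneRecord(
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            tpm={t: float(getattr(row, t)) for t in tissues},
        )
        for row in df.itertuples(index=False)
    ]
    return genes, tissues


def write_gene_table(
    genes: Sequence[GeneRecord], tissues: Sequence[str], path: str | Path
) -> None:
    rows = []
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
        }
        for t in tissues:
            row[t] = g.tpm.get(t, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def tpm_matrix(genes: Sequence[GeneRecord], tissues: Sequence[str]) -> pd.DataFrame:
    """Genes x tissues TPM DataFrame indexed by gene_id."""
    return pd.DataFrame(
        [[g.tpm.get(t, 0.0) for t in tissues] for g in genes],
        index=[g.gene_id for g in genes],
        columns=list(tissues),
    )


def read_state_track(path: str | Path, tissue: str) -> StateSegmentation:
    """Read a BED4 state segmentation for one tissue."""
    segs = read_intervals(path)
    segs = sorted(segs, key=GenomicInterval.sort_key)
    return StateSegmentation(tissue=tissue, segments=segs)
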