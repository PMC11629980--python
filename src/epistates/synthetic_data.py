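"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the structure of a six-tissue functional-epigenome
study of a salmonid genome: per-tissue 10-state chromatin segmentations,
histone-mark peak sets, TPM expression tables with planted tissue-specific
genes, per-CpG bisulfite count tables with a hypomethylation dip at the
TSS, QTL/SNP/motif tables with planted triple overlaps, and ohnologue
triplets whose expression profiles follow one of the four duplicate
retention fates (conservation, neofunctionalization, subfunctionalization,
specialization).  Every stage records what was planted so downstream calls
can be scored exactly.

All randomness flows from ``SimulationConfig.seed``; each sub-generator
draws from its own stream derived from that master seed, so regenerating a
single stage is reproducible independently of the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_core import (
    ACTIVE_STATES,
    ENHANCER_STATES,
    STATE_NAMES,
    GeneRecord,
    GenomeModel,
    GenomicInterval,
    StateSegmentation,
    ValidationError,
)

DEFAULT_TISSUES = ("brain", "liver", "spleen", "muscle", "intestine", "kidney")

FATES = ("conserved", "neofunctionalized", "subfunctionalized", "specialized")

#: Mean segment length (bp) per state used to fill the tiling between
#: planted anchors; promoter/enhancer dwell times sit near 1 kb, poised
#: and polycomb states are longer, quiescent chromatin dominates.
DEFAULT_STATE_DWELL = {
    "TssA": 1200,
    "TssAFlnk": 1000,
    "EnhG": 1000,
    "Str.Enh": 1500,
    "MidEnh": 1000,
    "EnhPois": 6000,
    "ATAC-CpG": 1000,
    "BivEnh": 600,
    "ReprPC": 4500,
    "Quies": 40000,
}

#: Sampling weights for gap-filling states (planted anchors are added on
#: top of this background, so promoter states are rare in the fill).
_FILL_STATES = ("Quies", "EnhPois", "ATAC-CpG", "ReprPC", "MidEnh", "EnhG", "Str.Enh", "BivEnh")
_FILL_WEIGHTS = np.array([0.60, 0.08, 0.10, 0.06, 0.06, 0.04, 0.03, 0.03])


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror a desk-scale version
    of a six-tissue, 10-state design."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 300
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    specific_fraction: float = 0.2
    state_dwell: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_STATE_DWELL))
    # methylome
    n_cpg: int = 20_000
    background_methylation: float = 0.75
    tss_hypomethylation_depth: float = 0.10
    active_state_methylation: float = 0.50
    mean_read_depth: float = 30.0
    n_low_depth_sites: int = 50
    n_high_depth_sites: int = 5
    # ohnologue triplets
    n_triplets: int = 500
    n_singleton_pairs: int = 1000
    fate_mix: dict[str, float] = field(
        default_factory=lambda: {
            "conserved": 0.736,
            "neofunctionalized": 0.142,
            "subfunctionalized": 0.002,
            "specialized": 0.120,
        }
    )
    noise_sd: float = 0.02
    divergence_margin: float = 0.3
    # QTL / SNP / motif
    n_qtl: int = 12
    qtl_length: int = 150_000
    n_snps: int = 400
    snp_triple_fraction: float = 0.3
    motif_family_mix: dict[str, float] = field(
        default_factory=lambda: {"C/EBP": 0.7, "GR": 0.3}
    )
    # H3K27ac enhancer clusters for super-enhancer calling (per tissue)
    n_enh_clusters_low: int = 95
    n_enh_clusters_high: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.fate_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("fate_mix proportions must sum to 1")
        if abs(sum(self.motif_family_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("motif_family_mix proportions must sum to 1")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_cpg", "n_triplets",
                     "n_singleton_pairs", "n_qtl", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if len(self.tissues) < 2:
            raise ValidationError("need at least 2 tissues")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    def rng(self, stage: str) -> np.random.Generator:
        """A deterministic per-stage stream derived from the master seed."""
        tag = sum(ord(c) * (i + 1) for i, c in enumerate(stage)) % (2**16)
        return np.random.default_rng([self.seed, tag])


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a (YAML-derived) dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    kw = dict(d)
    if "tissues" in kw:
        kw["tissues"] = tuple(kw["tissues"])
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[GenomeModel, list[GeneRecord]]:
    """Place non-overlapping genes on both strands across the chromosomes."""
    rng = config.rng("genome")
    genome = GenomeModel(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1

    min_gap = 500
    genes: list[GeneRecord] = []
    gid = 0
    for ci, chrom in enumerate(genome.chrom_sizes):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        lengths = rng.integers(2_000, 8_001, size=k)
        free = config.chrom_length - int(lengths.sum()) - (k + 1) * min_gap
        if free < 0:
            raise ValidationError(
                f"{k} genes do not fit on {chrom} ({config.chrom_length} bp)"
            )
        w = rng.random(k + 1)
        gaps = np.floor(w / w.sum() * free).astype(int) + min_gap
        pos = 0
        for j in range(k):
            pos += int(gaps[j])
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"g{gid:05d}", chrom, start, end, strand))
            gid += 1
            pos = end
    return genome, genes


# ---------------------------------------------------------------------------
# Expression with planted tissue specificity
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig, genes: list[GeneRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal TPM with a planted tissue-specific subset.

    A planted fraction of genes is made specific to one tissue by the
    10-fold rule (target TPM at least 10x the sum of all other tissues) or,
    for a small sub-subset, by the >=1-TPM-vs-all-zero rule.  Background
    genes are adjusted so neither rule fires.  Returns (tpm, truth) where
    truth has columns gene_id, specific_tissue ("" if none), rule.
    """
    rng = config.rng("expression")
    tissues = list(config.tissues)
    n, k = len(genes), len(tissues)
    tpm = rng.lognormal(mean=1.0, sigma=1.0, size=(n, k))

    n_spec = int(round(config.specific_fraction * n))
    spec_idx = rng.choice(n, size=n_spec, replace=False)
    truth_tissue = np.array([""] * n, dtype=object)
    truth_rule = np.array([""] * n, dtype=object)
    n_zero_rule = n_spec // 5  # minority of planted genes use the 1-vs-zero rule

    for j, gi in enumerate(spec_idx):
        t = j % k
        if j < n_zero_rule:
            tpm[gi, :] = 0.0
            tpm[gi, t] = rng.uniform(1.0, 5.0)
            truth_rule[gi] = "one_vs_zero"
        else:
            target = rng.uniform(50.0, 200.0)
            others = rng.uniform(0.0, target / (10.0 * (k - 1)) * 0.9, size=k)
            tpm[gi, :] = others
            tpm[gi, t] = target
            truth_rule[gi] = "fold10"
        truth_tissue[gi] = tissues[t]

    # keep background genes clear of both rules
    spec_set = set(spec_idx.tolist())
    for gi in range(n):
        if gi in spec_set:
            continue
        row = tpm[gi]
        m = row.max()
        rest = row.sum() - m
        if rest < m / 9.0:  # would pass (or sit near) the 10-fold rule
            scale = (m / 8.0) / max(rest, 1e-12)
            row[row < m] *= scale
            tpm[gi] = row

    tpm_df = pd.DataFrame(tpm, index=[g.gene_id for g in genes], columns=tissues)
    tpm_df.index.name = "gene_id"
    for g, row in zip(genes, tpm):
        g.tpm = {t: float(v) for t, v in zip(tissues, row)}
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "specific_tissue": truth_tissue,
            "rule": truth_rule,
        }
    )
    return tpm_df, truth


# ---------------------------------------------------------------------------
# Chromatin-state tracks
# ---------------------------------------------------------------------------

def _fill_gap(
    rng: np.random.Generator,
    chrom: str,
    lo: int,
    hi: int,
    dwell: dict[str, int],
) -> list[GenomicInterval]:
    """Tile [lo, hi) with geometric-dwell segments from the fill states."""
    out: list[GenomicInterval] = []
    pos = lo
    while pos < hi:
        state = _FILL_STATES[rng.choice(len(_FILL_STATES), p=_FILL_WEIGHTS)]
        mean = max(dwell.get(state, 1000), 50)
        length = int(rng.geometric(1.0 / mean))
        end = min(pos + max(length, 50), hi)
        out.append(GenomicInterval(chrom, pos, end, state))
        pos = end
    return out


def simulate_state_tracks(
    config: SimulationConfig,
    genome: GenomeModel,
    genes: list[GeneRecord],
    expression_truth: pd.DataFrame,
) -> tuple[dict[str, StateSegmentation], pd.DataFrame]:
    """Complete per-tissue tilings with promoter states planted at the TSS
    of genes expressed in that tissue.

    Genes count as expressed in a tissue when TPM > 1 there (all planted
    tissue-specific genes qualify in their own tissue).  Each expressed
    gene receives a TssA segment centred on its TSS flanked by TssAFlnk,
    and an upstream active-enhancer segment; collisions with an earlier
    anchor are dropped.  Gaps are filled with geometric-dwell background
    segments so every chromosome is tiled end to end.

    Returns (tracks, planted) where planted records every anchor actually
    placed (tissue, chrom, start, end, state, gene_id, kind).
    """
    rng = config.rng("states")
    tracks: dict[str, StateSegmentation] = {}
    planted_rows: list[dict] = []
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    for tissue in config.tissues:
        segments: list[GenomicInterval] = []
        for chrom, size in genome.chrom_sizes.items():
            anchors: list[tuple[GenomicInterval, str, str]] = []  # (iv, gene, kind)
            for g in sorted(genes_by_chrom.get(chrom, []), key=lambda g: g.tss):
                if g.tpm.get(tissue, 0.0) <= 1.0:
                    continue
                tss = g.tss
                tssa = (max(0, tss - 600), min(size, tss + 600))
                flnk = (tssa[1], min(size, tssa[1] + 1000))
                enh_state = ENHANCER_STATES[int(rng.choice(3))]
                enh = (max(0, tss - 4_000), max(0, tss - 4_000) + 1_200)
                cand = []
                if tssa[0] < tssa[1]:
                    cand.append((GenomicInterval(chrom, *tssa, "TssA"), g.gene_id, "tss"))
                if flnk[0] < flnk[1]:
                    cand.append((GenomicInterval(chrom, *flnk, "TssAFlnk"), g.gene_id, "tss_flank"))
                if enh[1] <= size and enh[0] < enh[1]:
                    cand.append((GenomicInterval(chrom, *enh, enh_state), g.gene_id, "enhancer"))
                for iv, gid, kind in sorted(cand, key=lambda c: c[0].start):
                    if anchors and iv.chrom == anchors[-1][0].chrom and iv.start < anchors[-1][0].end:
                        continue  # collision with an earlier anchor: drop
                    anchors.append((iv, gid, kind))
            anchors.sort(key=lambda c: c[0].start)
            pos = 0
            for iv, gid, kind in anchors:
                if iv.start > pos:
                    segments.extend(_fill_gap(rng, chrom, pos, iv.start, config.state_dwell))
                segments.append(iv)
                planted_rows.append(
                    {
                        "tissue": tissue,
                        "chrom": chrom,
                        "start": iv.start,
                        "end": iv.end,
                        "state": iv.label,
                        "gene_id": gid,
                        "kind": kind,
                    }
                )
                pos = iv.end
            if pos < size:
                segments.extend(_fill_gap(rng, chrom, pos, size, config.state_dwell))
        tracks[tissue] = StateSegmentation(tissue=tissue, segments=segments)
    planted = pd.DataFrame(
        planted_rows,
        columns=["tissue", "chrom", "start", "end", "state", "gene_id", "kind"],
    )
    return tracks, planted


# ---------------------------------------------------------------------------
# Histone-mark peak sets
# ---------------------------------------------------------------------------

def simulate_histone_peaks(
    config: SimulationConfig,
    genome: GenomeModel,
    genes: list[GeneRecord],
    expression_truth: pd.DataFrame,
) -> dict[str, dict[str, list[GenomicInterval]]]:
    """Per-tissue, per-mark peak sets coupled to planted tissue specificity.

    H3K4me1 peaks are planted at the TSS of each tissue-specific gene only
    in its own tissue (so the peak is unique to that tissue); H3K27me3
    peaks are planted at those genes in every *other* tissue (the silenced
    context).  Background peaks for all four marks are scattered away from
    the planted windows.
    """
    rng = config.rng("peaks")
    marks = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3")
    peaks: dict[str, dict[str, list[GenomicInterval]]] = {
        t: {m: [] for m in marks} for t in config.tissues
    }
    gene_by_id = {g.gene_id: g for g in genes}
    spec = expression_truth[expression_truth.specific_tissue != ""]
    for row in spec.itertuples(index=False):
        g = gene_by_id[row.gene_id]
        lo = max(0, g.tss - 400)
        iv = GenomicInterval(g.chrom, lo, lo + 800, score=float(rng.uniform(20, 60)))
        peaks[row.specific_tissue]["H3K4me1"].append(iv)
        for t in config.tissues:
            if t != row.specific_tissue:
                peaks[t]["H3K27me3"].append(
                    GenomicInterval(g.chrom, lo, lo + 800, score=float(rng.uniform(20, 60)))
                )
    # background peaks well away from any TSS window
    tss_windows = [
        GenomicInterval(g.chrom, max(0, g.tss - 4000), g.tss + 4000) for g in genes
    ]
    from .genome_core import find_overlaps as _fo

    n_bg = 40
    for t in config.tissues:
        for m in marks:
            placed: list[GenomicInterval] = []
            tries = 0
            while len(placed) < n_bg and tries < 20 * n_bg:
                tries += 1
                chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
                start = int(rng.integers(0, genome.chrom_sizes[chrom] - 1000))
                cand = GenomicInterval(chrom, start, start + 600, score=float(rng.uniform(5, 15)))
                if _fo([cand], tss_windows):
                    continue
                placed.append(cand)
            peaks[t][m].extend(placed)
    for t in config.tissues:
        for m in marks:
            peaks[t][m].sort(key=GenomicInterval.sort_key)
    return peaks


def simulate_enhancer_clusters(
    config: SimulationConfig, genome: GenomeModel
) -> tuple[dict[str, list[GenomicInterval]], pd.DataFrame]:
    """Per-tissue H3K27ac peak sets forming stitchable clusters with a
    heavy-tailed signal distribution.

    The cluster *layout* (peak positions) is drawn once and shared across
    tissues, as real enhancer loci largely are; per tissue,
    ``n_enh_clusters_high`` clusters get high, well-separated summed
    signals (so the ranked signal curve has an unambiguous elbow) and the
    rest get low summed signal (uniform 1-5).  Most high clusters are
    common to all tissues with one rotating tissue-unique cluster, giving
    the cross-tissue merge both shared and single-tissue calls.  Clusters
    are spaced > 12.5 kb apart so stitching recovers them exactly.
    Returns (peaks_by_tissue, truth) with truth columns tissue, chrom,
    start, end, is_super.
    """
    rng = config.rng("enhancers")
    gap_between_clusters = 15_000
    chrom_names = list(genome.chrom_sizes)
    n_high = config.n_enh_clusters_high
    n_total = config.n_enh_clusters_low + n_high

    # shared layout: cluster peak positions, one draw for all tissues
    layout: list[list[GenomicInterval]] = []
    pos = {c: int(rng.integers(0, 5_000)) for c in chrom_names}
    for k in range(n_total):
        chrom = chrom_names[k % len(chrom_names)]
        n_peaks = int(rng.integers(2, 5))
        cluster_peaks: list[GenomicInterval] = []
        p = pos[chrom]
        for _ in range(n_peaks):
            w = int(rng.integers(300, 800))
            cluster_peaks.append(GenomicInterval(chrom, p, p + w))
            p += w + int(rng.integers(1_000, 5_000))  # intra-cluster gap < 12.5 kb
        span_end = cluster_peaks[-1].end
        if span_end + gap_between_clusters >= genome.chrom_sizes[chrom]:
            raise ValidationError("enhancer clusters do not fit on the genome")
        layout.append(cluster_peaks)
        pos[chrom] = span_end + gap_between_clusters

    common_high = list(rng.choice(n_total, size=max(n_high - 1, 0), replace=False))
    spare = [k for k in range(n_total) if k not in common_high]

    peaks_by_tissue: dict[str, list[GenomicInterval]] = {}
    truth_rows: list[dict] = []
    for ti, tissue in enumerate(config.tissues):
        high_set = set(common_high)
        if n_high > 0:
            high_set.add(spare[ti % len(spare)])  # one tissue-unique super cluster
        high_signals = iter(
            np.linspace(60.0, 140.0, len(high_set))
            + rng.uniform(0, 5, len(high_set))
        )
        peaks: list[GenomicInterval] = []
        for k, cluster_peaks in enumerate(layout):
            n_peaks = len(cluster_peaks)
            if k in high_set:
                total = float(next(high_signals))
            else:
                # narrow low-signal range: the gap between consecutive low
                # order statistics stays far below the high/low separation,
                # so the ranked curve's slope crosses 1 exactly once
                total = float(rng.uniform(1.0, 5.0))
            w_sig = rng.random(n_peaks)
            w_sig /= w_sig.sum()
            for pk, frac in zip(cluster_peaks, w_sig):
                peaks.append(
                    GenomicInterval(pk.chrom, pk.start, pk.end, score=float(total * frac))
                )
            truth_rows.append(
                {
                    "tissue": tissue,
                    "chrom": cluster_peaks[0].chrom,
                    "start": cluster_peaks[0].start,
                    "end": cluster_peaks[-1].end,
                    "is_super": k in high_set,
                }
            )
        peaks.sort(key=GenomicInterval.sort_key)
        peaks_by_tissue[tissue] = peaks
    truth = pd.DataFrame(truth_rows)
    return peaks_by_tissue, truth


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(
    config: SimulationConfig,
    genome: GenomeModel,
    genes: list[GeneRecord],
    track: StateSegmentation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG binomial counts for one tissue.

    Background methylation is ~0.75; sites within +/-250 bp of a TSS sit at
    the configured dip level (default 0.10) with a linear ramp back to
    background by +/-2 kb; sites inside active states (1-5) away from TSS
    are moderately hypomethylated.  Read depth is Poisson; a planted subset
    of sites is forced below depth 10 and a few far above the 99.9th depth
    percentile so the depth filters have work to do.

    Returns (sites, truth): sites has columns chrom,pos,strand,reads_c,
    reads_t; truth marks planted low/high-depth site rows.
    """
    rng = config.rng("methylome:" + track.tissue)
    chroms = list(genome.chrom_sizes)
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    n_per = np.floor(config.n_cpg * lengths / lengths.sum()).astype(int)
    n_per[0] += config.n_cpg - int(n_per.sum())

    rows_chrom: list[str] = []
    pos_all: list[np.ndarray] = []
    for c, n_c in zip(chroms, n_per):
        pos = np.sort(
            rng.choice(genome.chrom_sizes[c] - 2, size=n_c, replace=False) + 1
        )
        pos_all.append(pos)
        rows_chrom.extend([c] * n_c)
    chrom_arr = np.array(rows_chrom)
    pos_arr = np.concatenate(pos_all)

    level = np.full(pos_arr.size, config.background_methylation)

    # TSS dip: flat at the dip level within 250 bp, linear ramp to 2 kb
    dip, bg = config.tss_hypomethylation_depth, config.background_methylation
    for g in genes:
        sel = chrom_arr == g.chrom
        off = np.abs(pos_arr[sel] - g.tss)
        ramp = np.clip((off - 250) / (2_000 - 250), 0.0, 1.0)
        lvl = dip + (bg - dip) * ramp
        level[sel] = np.minimum(level[sel], lvl)

    # moderate hypomethylation inside active states, outside TSS windows
    seg_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in chroms:
        segs = [s for s in track.segments if s.chrom == c]
        seg_by_chrom[c] = (
            np.array([s.start for s in segs]),
            np.array([s.end for s in segs]),
            np.array([s.label in ACTIVE_STATES for s in segs]),
        )
    for c in chroms:
        sel = np.nonzero(chrom_arr == c)[0]
        starts, ends, active = seg_by_chrom[c]
        if starts.size == 0:
            continue
        idx = np.searchsorted(starts, pos_arr[sel], side="right") - 1
        ok = (idx >= 0) & (pos_arr[sel] < ends[np.clip(idx, 0, None)])
        in_active = np.zeros(sel.size, dtype=bool)
        in_active[ok] = active[idx[ok]]
        target = np.full(sel.size, config.active_state_methylation)
        level[sel[in_active]] = np.minimum(
            level[sel[in_active]], target[in_active]
        )

    depth = rng.poisson(config.mean_read_depth, size=pos_arr.size) + 1

    n = pos_arr.size
    # high-depth plants must stay below 0.1% of sites or they cannot sit
    # above the 99.9th depth percentile they are meant to exercise
    n_high = min(config.n_high_depth_sites, max(1, n // 1000 - 1))
    special = rng.choice(
        n, size=config.n_low_depth_sites + n_high, replace=False
    )
    low_idx = special[: config.n_low_depth_sites]
    high_idx = special[config.n_low_depth_sites :]
    depth[low_idx] = rng.integers(1, 10, size=low_idx.size)
    depth[high_idx] = int(config.mean_read_depth * 400)  # far beyond the 99.9th pct

    reads_c = rng.binomial(depth, np.clip(level, 0.0, 1.0))
    sites = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "strand": "+",
            "reads_c": reads_c,
            "reads_t": depth - reads_c,
        }
    )
    flag = np.array([""] * n, dtype=object)
    flag[low_idx] = "planted_low_depth"
    flag[high_idx] = "planted_high_depth"
    truth = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, "planted": flag})
    return sites, truth


# ---------------------------------------------------------------------------
# Ohnologue triplets
# ---------------------------------------------------------------------------

def _renorm_noisy(rng: np.random.Generator, rel: np.ndarray, sd: float) -> np.ndarray:
    """Add i.i.d. Gaussian noise on the simplex, clip at 0, renormalize."""
    if sd == 0:
        return rel.copy()
    out = np.clip(rel + rng.normal(0.0, sd, size=rel.shape), 0.0, None)
    s = out.sum()
    if s == 0:  # pathological draw: fall back to the clean profile
        return rel.copy()
    return out / s


def _redraw_divergent(
    rng: np.random.Generator, anc: np.ndarray, margin: float
) -> np.ndarray:
    """A fresh simplex profile at Euclidean distance >= margin from anc."""
    for _ in range(1000):
        cand = rng.dirichlet(np.ones(anc.size))
        if np.linalg.norm(cand - anc) >= margin:
            return cand
    raise RuntimeError("could not draw a divergent profile")  # pragma: no cover


def _fate_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_triplets across fate_mix."""
    n = config.n_triplets
    raw = {f: config.fate_mix.get(f, 0.0) * n for f in FATES}
    counts = {f: int(np.floor(v)) for f, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(FATES, key=lambda f: raw[f] - counts[f], reverse=True)
    for f in order[:short]:
        counts[f] += 1
    return counts


def simulate_triplets(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ohnologue triplets with fate-determined expression profiles.

    For each triplet an ancestral relative profile is drawn from a
    Dirichlet; the duplicate profiles follow the planted fate:

    * conserved: both copies track the ancestor;
    * neofunctionalized: one copy redrawn far from the ancestor (direction
      recorded, D1 or D2 with equal probability);
    * subfunctionalized: the ancestral profile is partitioned tissue-wise
      between the copies so their combined profile equals the ancestor;
    * specialized: both copies redrawn, with the combined profile also far
      from the ancestor.

    Gaussian noise (sd = ``noise_sd``) is added on the simplex and the
    profiles renormalized; absolute TPM vectors are the relative profiles
    scaled by log-normal totals.  Singleton pairs (ancestor + the same
    noise, twice) define the between-sister-species divergence baseline.

    Returns (triplets, dup_tpm, sister_tpm, singleton_pairs): triplets has
    d1_id, d2_id, anc_id, true_fate (pooled label) and true_direction;
    dup_tpm holds absolute TPM rows for every D1/D2 gene; sister_tpm holds
    the ancestor and singleton genes.
    """
    rng = config.rng("triplets")
    k = len(config.tissues)
    if k < 2:
        raise ValidationError("triplet profiles need at least 2 tissues")
    counts = _fate_counts(config)
    fates: list[str] = []
    for f in FATES:
        fates.extend([f] * counts[f])
    fates_arr = np.array(fates, dtype=object)
    rng.shuffle(fates_arr)

    margin = config.divergence_margin
    trip_rows, dup_rows, sister_rows = [], [], []
    for i, fate in enumerate(fates_arr):
        anc = rng.dirichlet(np.ones(k) * 1.5)
        total = float(rng.lognormal(3.0, 0.8))
        direction = ""
        if fate == "conserved":
            r1, r2 = anc.copy(), anc.copy()
        elif fate == "neofunctionalized":
            direction = "D1" if rng.random() < 0.5 else "D2"
            nov = _redraw_divergent(rng, anc, margin)
            r1, r2 = (nov, anc.copy()) if direction == "D1" else (anc.copy(), nov)
        elif fate == "subfunctionalized":
            for _ in range(1000):
                mask = rng.random(k) < 0.5
                if not mask.any() or mask.all():
                    continue
                a1, a2 = anc * mask, anc * (~mask)
                r1, r2 = a1 / a1.sum(), a2 / a2.sum()
                if (
                    np.linalg.norm(r1 - anc) >= margin
                    and np.linalg.norm(r2 - anc) >= margin
                ):
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not partition ancestral profile")
        else:  # specialized
            for _ in range(1000):
                r1 = _redraw_divergent(rng, anc, margin)
                r2 = _redraw_divergent(rng, anc, margin)
                comb = (r1 + r2) / 2.0
                if np.linalg.norm(comb / comb.sum() - anc) >= margin:
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw specialized profiles")

        if fate == "subfunctionalized":
            # tissue-wise partition of the ancestral absolute expression:
            # the absolute vectors sum exactly to the ancestral vector
            abs1 = anc * mask * total
            abs2 = anc * (~mask) * total
        else:
            abs1 = r1 * total
            abs2 = r2 * total
        # noise on the relative profile, then rescale to the absolute total
        rel1 = _renorm_noisy(rng, abs1 / abs1.sum(), config.noise_sd)
        rel2 = _renorm_noisy(rng, abs2 / abs2.sum(), config.noise_sd)
        abs1 = rel1 * abs1.sum()
        abs2 = rel2 * abs2.sum()

        d1_id, d2_id, anc_id = f"d1_{i:05d}", f"d2_{i:05d}", f"anc_{i:05d}"
        trip_rows.append(
            {
                "d1_id": d1_id,
                "d2_id": d2_id,
                "anc_id": anc_id,
                "true_fate": fate,
                "true_direction": direction,
            }
        )
        dup_rows.append([d1_id, *abs1])
        dup_rows.append([d2_id, *abs2])
        sister_rows.append([anc_id, *(anc * total)])

    pair_rows = []
    for j in range(config.n_singleton_pairs):
        base = rng.dirichlet(np.ones(k) * 1.5)
        total = float(rng.lognormal(3.0, 0.8))
        s1 = _renorm_noisy(rng, base, config.noise_sd) * total
        s2 = _renorm_noisy(rng, base, config.noise_sd) * total
        s1_id, s2_id = f"s1_{j:05d}", f"s2_{j:05d}"
        sister_rows.append([s1_id, *s1])
        sister_rows.append([s2_id, *s2])
        pair_rows.append({"s1_id": s1_id, "s2_id": s2_id})

    cols = ["gene_id", *config.tissues]
    triplets = pd.DataFrame(trip_rows)
    dup_tpm = pd.DataFrame(dup_rows, columns=cols).set_index("gene_id")
    sister_tpm = pd.DataFrame(sister_rows, columns=cols).set_index("gene_id")
    singleton_pairs = pd.DataFrame(pair_rows)
    return triplets, dup_tpm, sister_tpm, singleton_pairs


# ---------------------------------------------------------------------------
# QTL, SNPs and motifs
# ---------------------------------------------------------------------------

QTL_TRAITS = ("growth", "fillet_quality", "BCWD")


def simulate_qtl_snps(
    config: SimulationConfig,
    genome: GenomeModel,
    track: StateSegmentation,
) -> tuple[list[GenomicInterval], pd.DataFrame, list[GenomicInterval], pd.DataFrame]:
    """QTL intervals, SNPs and motif occurrences with planted triple overlaps.

    A configured fraction of SNPs is placed inside enhancer-state segments
    (EnhG/Str.Enh/MidEnh) that fall within QTL, each covered by a motif
    whose family follows ``motif_family_mix`` exactly (largest-remainder
    apportionment).  The remaining SNPs are decoys constructed to fail at
    least one of the three conditions.  Returns (qtl, snps, motifs, truth);
    SNP positions are 1-based in the emitted table.
    """
    rng = config.rng("qtl")
    chroms = list(genome.chrom_sizes)

    qtl: list[GenomicInterval] = []
    for i in range(config.n_qtl):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - config.qtl_length))
        qtl.append(
            GenomicInterval(
                chrom, start, start + config.qtl_length,
                label=f"qtl{i:03d}:{QTL_TRAITS[i % len(QTL_TRAITS)]}",
            )
        )

    # enhancer segments intersected with QTL: the planting substrate
    enh = [s for s in track.segments if s.label in ENHANCER_STATES]
    from .genome_core import find_overlaps as _fo

    triple_regions: list[tuple[int, int, str]] = []  # (lo, hi, chrom)
    for qi, si, bp in _fo(qtl, enh):
        lo = max(qtl[qi].start, enh[si].start)
        hi = min(qtl[qi].end, enh[si].end)
        if hi - lo >= 40:
            triple_regions.append((lo, hi, qtl[qi].chrom))
    if not triple_regions:
        raise ValidationError("no enhancer/QTL overlap to plant SNPs into")

    n_planted = int(round(config.n_snps * config.snp_triple_fraction))
    fam_names = list(config.motif_family_mix)
    raw = {f: config.motif_family_mix[f] * n_planted for f in fam_names}
    fam_counts = {f: int(np.floor(raw[f])) for f in fam_names}
    short = n_planted - sum(fam_counts.values())
    for f in sorted(fam_names, key=lambda f: raw[f] - fam_counts[f], reverse=True)[:short]:
        fam_counts[f] += 1
    fam_assign: list[str] = []
    for f in fam_names:
        fam_assign.extend([f] * fam_counts[f])
    fam_arr = np.array(fam_assign, dtype=object)
    rng.shuffle(fam_arr)

    snp_rows: list[dict] = []
    motifs: list[GenomicInterval] = []
    truth_rows: list[dict] = []
    used_pos: set[tuple[str, int]] = set()
    margin = 20  # keep SNPs/motifs apart so decoys cannot enter planted motifs

    def _pos_free(chrom: str, pos0: int) -> bool:
        return not any((chrom, p) in used_pos for p in range(pos0 - margin, pos0 + margin + 1))

    mi = 0
    for j in range(n_planted):
        for _ in range(1000):
            lo, hi, chrom = triple_regions[int(rng.integers(len(triple_regions)))]
            pos0 = int(rng.integers(lo + 10, hi - 10))
            if _pos_free(chrom, pos0):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place planted SNP")
        used_pos.add((chrom, pos0))
        snp_id = f"snp{j:05d}"
        family = str(fam_arr[j])
        motif_id = f"m{mi:05d}"
        mi += 1
        motifs.append(
            GenomicInterval(chrom, pos0 - 7, pos0 + 8, label=f"{motif_id}:{family}")
        )
        snp_rows.append({"snp_id": snp_id, "chrom": chrom, "pos": pos0 + 1})
        truth_rows.append({"snp_id": snp_id, "planted": True, "family": family})

    # decoys: in QTL but outside enhancers, or in enhancers outside QTL,
    # or inside both but without any covering motif
    enh_merged = enh
    qtl_merged = qtl

    def _in_any(ivs: list[GenomicInterval], chrom: str, pos0: int) -> bool:
        probe = GenomicInterval(chrom, pos0, pos0 + 1)
        return bool(_fo([probe], ivs))

    n_decoy = config.n_snps - n_planted
    kinds = ["no_enh", "no_qtl", "no_motif"]
    for j in range(n_decoy):
        kind = kinds[j % len(kinds)]
        snp_id = f"snp{n_planted + j:05d}"
        for _ in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos0 = int(rng.integers(10, genome.chrom_sizes[chrom] - 10))
            if not _pos_free(chrom, pos0):
                continue
            in_q = _in_any(qtl_merged, chrom, pos0)
            in_e = _in_any(enh_merged, chrom, pos0)
            if kind == "no_enh" and in_q and not in_e:
                break
            if kind == "no_qtl" and in_e and not in_q:
                break
            if kind == "no_motif" and in_q and in_e:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place decoy SNP")
        used_pos.add((chrom, pos0))
        if kind == "no_enh" or kind == "no_qtl":
            motif_id = f"m{mi:05d}"
            mi += 1
            motifs.append(
                GenomicInterval(chrom, pos0 - 7, pos0 + 8, label=f"{motif_id}:other")
            )
        snp_rows.append({"snp_id": snp_id, "chrom": chrom, "pos": pos0 + 1})
        truth_rows.append({"snp_id": snp_id, "planted": False, "family": ""})

    motifs.sort(key=GenomicInterval.sort_key)
    snps = pd.DataFrame(snp_rows)
    truth = pd.DataFrame(truth_rows)
    return qtl, snps, motifs, truth


# ---------------------------------------------------------------------------
# Promoter epigenetic profiles for duplicate pairs
# ---------------------------------------------------------------------------

def simulate_pair_promoter_profiles(
    config: SimulationConfig,
    triplets: pd.DataFrame,
    n_bins: int = 10,
    similarity_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Promoter histone-mark profiles for each duplicate pair, with
    fate-coupled similarity.

    Each gene copy gets a per-mark coverage profile across its 2-kb
    upstream promoter window (``n_bins`` bins per mark).  The second copy's
    profile is the first plus Gaussian noise whose sd depends on the pair's
    fate, planting the ordering conserved > specialized > neofunctionalized
    in profile similarity.  Returns a long table: pair_id, true_fate, copy
    (d1/d2), mark, bin, value.
    """
    rng = config.rng("pair_profiles")
    sd = similarity_sd or {
        "conserved": 0.15,
        "specialized": 0.6,
        "neofunctionalized": 1.2,
        "subfunctionalized": 0.6,
    }
    marks = ("H3K4me3", "H3K4me1", "H3K27ac")
    rows = []
    for i, row in enumerate(triplets.itertuples(index=False)):
        fate = row.true_fate
        for mark in marks:
            base = rng.gamma(2.0, 1.0, size=n_bins)
            other = np.clip(base + rng.normal(0.0, sd[fate], size=n_bins), 0.0, None)
            for b in range(n_bins):
                rows.append((f"pair{i:05d}", fate, "d1", mark, b, float(base[b])))
                rows.append((f"pair{i:05d}", fate, "d2", mark, b, float(other[b])))
    return pd.DataFrame(
        rows, columns=["pair_id", "true_fate", "copy", "mark", "bin", "value"]
    )
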