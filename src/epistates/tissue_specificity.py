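"""Tissue-specific gene calling and mark/state enrichment around their TSS.

A gene is called specific to a tissue when its TPM there is at least
10-fold the *sum* of its TPM in every other tissue, or when it has TPM >= 1
in that tissue and exactly zero everywhere else.  The same gene is treated
as "silenced" in the remaining tissues for contrast analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_core import (
    GeneRecord,
    GenomeModel,
    GenomicInterval,
    ValidationError,
    find_overlaps,
    flank_tss,
)

log = logging.getLogger(__name__)

LOG10_PSEUDOCOUNT = 0.01  # added to TPM before log10 so zeros stay finite


@dataclass
class ChiSquareResult:
    statistic: float
    pvalue: float
    low_expected: bool  # some expected cell < 1: asymptotics unreliable


def call_tissue_specific(tpm: pd.DataFrame) -> pd.DataFrame:
    """One row per (gene, tissue) satisfying either specificity rule.

    ``tpm`` is genes x tissues.  Returns columns gene_id, tissue, rule
    ('fold10' or 'one_vs_zero') and fold (NaN for the one_vs_zero rule).
    """
    if tpm.shape[1] < 2:
        raise ValidationError("need at least 2 tissues")
    if (tpm.values < 0).any():
        raise ValidationError("negative TPM values")
    vals = tpm.values.astype(float)
    totals = vals.sum(axis=1)
    rows = []
    for j, tissue in enumerate(tpm.columns):
        v = vals[:, j]
        rest = totals - v
        fold10 = (rest > 0) & (v >= 10.0 * rest)
        one_zero = (rest == 0) & (v >= 1.0)
        for gi in np.nonzero(fold10)[0]:
            rows.append(
                {
                    "gene_id": tpm.index[gi],
                    "tissue": tissue,
                    "rule": "fold10",
                    "fold": vals[gi, j] / rest[gi],
                }
            )
        for gi in np.nonzero(one_zero)[0]:
            rows.append(
                {
                    "gene_id": tpm.index[gi],
                    "tissue": tissue,
                    "rule": "one_vs_zero",
                    "fold": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "rule", "fold"])


def unique_marks_near_specific_genes(
    calls: pd.DataFrame,
    peaks_by_tissue: Mapping[str, Mapping[str, Sequence[GenomicInterval]]],
    genes: Sequence[GeneRecord],
    genome: GenomeModel,
    window: int = 3_000,
) -> pd.DataFrame:
    """Relative abundance of tissue-unique marks at specific vs silenced genes.

    For each mark, counts peaks that overlap the +/-window TSS region of a
    tissue-specific gene in *exactly one* tissue's peak set.  When that
    tissue is the gene's specific tissue the peak counts toward the
    specific set; when it is one of the silencing tissues it counts toward
    the silenced set.  Counts are normalized by the genome-wide peak total
    of that mark across the tissues contributing to each set.

    Returns per-mark columns: count_specific, total_specific,
    count_silenced, total_silenced, rel_specific, rel_silenced.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    tissues = list(peaks_by_tissue)
    marks: list[str] = sorted({m for t in tissues for m in peaks_by_tissue[t]})
    rows = []
    for mark in marks:
        missing = [t for t in tissues if mark not in peaks_by_tissue[t]]
        if missing:
            log.warning("mark %s missing in tissues %s; skipped there", mark, missing)
        have = [t for t in tissues if mark in peaks_by_tissue[t]]
        count_spec = 0
        count_sil = 0
        for call in calls.itertuples(index=False):
            g = gene_by_id.get(call.gene_id)
            if g is None or call.tissue not in have:
                continue
            win = flank_tss(g, window, window, genome)
            hits = {
                t: [si for _, si, _ in find_overlaps([win], list(peaks_by_tissue[t][mark]))]
                for t in have
            }
            tissues_with_hit = [t for t, h in hits.items() if h]
            if len(tissues_with_hit) != 1:
                continue  # not unique to one tissue
            t = tissues_with_hit[0]
            if t == call.tissue:
                count_spec += len(hits[t])
            else:
                count_sil += len(hits[t])
        total_spec = sum(len(peaks_by_tissue[t][mark]) for t in have)
        total_sil = total_spec  # same genome-wide pool; silencing side spans all tissues
        rows.append(
            {
                "mark": mark,
                "count_specific": count_spec,
                "total_specific": total_spec,
                "count_silenced": count_sil,
                "total_silenced": total_sil,
                "rel_specific": count_spec / total_spec if total_spec else np.nan,
                "rel_silenced": count_sil / total_sil if total_sil else np.nan,
            }
        )
    return pd.DataFrame(rows)


def chi_square_specific_vs_silenced(
    count_specific: int,
    total_specific: int,
    count_silenced: int,
    total_silenced: int,
) -> ChiSquareResult:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table

        [count_specific, total_specific - count_specific]
        [count_silenced, total_silenced - count_silenced]

    A zero row or column margin is degenerate and raises; an expected cell
    below 1 sets ``low_expected``.
    """
    if total_specific <= 0 or total_silenced <= 0:
        raise ValidationError("totals must be positive")
    a, b = count_specific, total_specific - count_specific
    c, d = count_silenced, total_silenced - count_silenced
    if min(a, b, c, d) < 0:
        raise ValidationError("counts exceed totals")
    n = a + b + c + d
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        raise ValidationError("degenerate 2x2 table: zero column margin")
    # closed form: N (ad - bc)^2 / (r1 r2 c1 c2)
    stat = n * (a * d - b * c) ** 2 / (total_specific * total_silenced * col1 * col2)
    p = float(stats.chi2.sf(stat, df=1))
    expected_min = min(
        total_specific * col1, total_specific * col2,
        total_silenced * col1, total_silenced * col2,
    ) / n
    return ChiSquareResult(statistic=float(stat), pvalue=p, low_expected=expected_min < 1)


def density_vs_expression(
    features: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    tpm: pd.Series,
    genome: GenomeModel,
    window: int = 3_000,
    n_bins: int = 20,
    mode: str = "count",
) -> tuple[pd.DataFrame, float, float]:
    """Feature density near the TSS versus expression level.

    Per gene, the density is the number of feature intervals overlapping
    the +/-window TSS region (``mode='count'``, for peak sets) or the
    covered fraction of the window (``mode='coverage'``, for states).
    Genes are binned into ``n_bins`` equal-width bins of log10(TPM +
    pseudocount); returns (bin table, r_squared, slope) from the simple
    linear regression of density on log10 TPM.
    """
    if mode not in ("count", "coverage"):
        raise ValueError(f"unknown mode {mode!r}")
    dens = []
    logtpm = []
    feats = list(features)
    for g in genes:
        if g.gene_id not in tpm.index:
            continue
        win = flank_tss(g, window, window, genome)
        hits = find_overlaps([win], feats)
        if mode == "count":
            dens.append(float(len(hits)))
        else:
            covered = sum(bp for _, _, bp in hits)
            dens.append(min(1.0, covered / win.length))
        logtpm.append(np.log10(float(tpm[g.gene_id]) + LOG10_PSEUDOCOUNT))
    dens_arr = np.asarray(dens)
    x = np.asarray(logtpm)
    if x.size < 3:
        raise ValidationError("need at least 3 genes with TPM")

    edges = np.linspace(x.min(), x.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "log10_tpm_mid": float((edges[b] + edges[b + 1]) / 2),
                "mean_density": float(dens_arr[sel].mean()),
                "n_genes": int(sel.sum()),
            }
        )
    dropped = n_bins - len(rows)
    if dropped:
        warnings.warn(f"{dropped} empty expression bins dropped", stacklevel=2)

    if np.allclose(dens_arr, dens_arr[0]) or np.allclose(x, x[0]):
        r2, slope = 0.0, 0.0
    else:
        fit = stats.linregress(x, dens_arr)
        r2, slope = float(fit.rvalue**2), float(fit.slope)
    return pd.DataFrame(rows), r2, slope
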