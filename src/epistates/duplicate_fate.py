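"""Retention-fate classification of whole-genome-duplication gene pairs.

After a genome duplication, a retained duplicate pair (ohnologues D1, D2)
can be preserved by conservation, neofunctionalization of one copy,
subfunctionalization (the ancestral expression domain partitioned between
copies) or specialization (both copies diverged, jointly departing from
the ancestral profile).  The classifier compares Euclidean distances
between relative expression profiles (proportions of total expression over
tissues):

* E_D1,A and E_D2,A: each duplicate versus the ancestral proxy profile;
* E_D1+D2,A: the combined duplicate profile (element-wise sum of the
  absolute expression vectors, renormalized) versus the ancestor.

Distances are judged against a single cutoff derived from singleton pairs
in the duplicated and sister species: median(E_S1,S2) plus the
semi-interquartile range (Q3 - Q1)/2, a spread measure robust to outliers.

Rule table (cutoff = t):
    E_D1,A <= t and E_D2,A <= t                      -> conserved
    E_D1,A  > t and E_D2,A <= t                      -> neofunctionalized (D1)
    E_D1,A <= t and E_D2,A  > t                      -> neofunctionalized (D2)
    both > t and E_D1+D2,A <= t                      -> subfunctionalized
    both > t and E_D1+D2,A  > t                      -> specialized
These rules are exhaustive and mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_core import ValidationError

FATE_LABELS = (
    "conserved",
    "neofunctionalized_D1",
    "neofunctionalized_D2",
    "subfunctionalized",
    "specialized",
)


def to_relative(absolute: np.ndarray) -> np.ndarray:
    """Convert an absolute TPM vector to proportions of total expression."""
    v = np.asarray(absolute, dtype=float)
    if (v < 0).any():
        raise ValidationError("negative expression values")
    s = v.sum()
    if s == 0:
        raise ValidationError("all-zero expression vector: gene ineligible")
    return v / s


def combined_profile(d1_abs: np.ndarray, d2_abs: np.ndarray) -> np.ndarray:
    """Relative profile of the element-wise sum of two absolute vectors."""
    return to_relative(np.asarray(d1_abs, dtype=float) + np.asarray(d2_abs, dtype=float))


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


@dataclass
class DivergenceBaseline:
    """Singleton-pair distances and the median + SIQR cutoff they define."""

    distances: np.ndarray
    median: float
    siqr: float

    @property
    def cutoff(self) -> float:
        return self.median + self.siqr


def baseline_cutoff(
    singleton_profiles: list[tuple[np.ndarray, np.ndarray]],
    quartile_method: str = "linear",
) -> DivergenceBaseline:
    """Divergence cutoff from pairs of singleton relative profiles.

    cutoff = median(E_S1,S2) + (Q3 - Q1)/2.  Quartiles use linear
    interpolation by default; ``quartile_method='tukey'`` uses Tukey
    hinges (the medians of the lower and upper halves).
    """
    if len(singleton_profiles) < 4:
        raise ValidationError("need at least 4 singleton pairs for stable quartiles")
    d = np.array([euclidean(a, b) for a, b in singleton_profiles])
    med = float(np.median(d))
    if quartile_method == "linear":
        q1, q3 = np.percentile(d, [25, 75])
    elif quartile_method == "tukey":
        s = np.sort(d)
        n = s.size
        half = n // 2
        lower = s[: half + (n % 2)]  # hinges include the median for odd n
        upper = s[half:]
        q1, q3 = float(np.median(lower)), float(np.median(upper))
    else:
        raise ValueError(f"unknown quartile method {quartile_method!r}")
    return DivergenceBaseline(distances=d, median=med, siqr=float((q3 - q1) / 2))


def classify_fate(
    e_d1a: float, e_d2a: float, e_comb: float, cutoff: float, atol: float = 1e-9
) -> str:
    """Apply the four-way rule table; boundary <= is inclusive.

    ``atol`` guards the inclusive boundary against floating-point residue:
    profiles identical up to rounding must not read as divergent when the
    cutoff is 0 (a degenerate noise-free baseline).
    """
    d1_div = e_d1a > cutoff + atol
    d2_div = e_d2a > cutoff + atol
    if not d1_div and not d2_div:
        return "conserved"
    if d1_div and not d2_div:
        return "neofunctionalized_D1"
    if not d1_div and d2_div:
        return "neofunctionalized_D2"
    return "subfunctionalized" if e_comb <= cutoff + atol else "specialized"


def classify_triplets(
    triplets: pd.DataFrame,
    dup_tpm: pd.DataFrame,
    sister_tpm: pd.DataFrame,
    cutoff: float,
) -> pd.DataFrame:
    """Distances and fate labels for a table of (d1_id, d2_id, anc_id).

    Expression tables are indexed by gene_id with one column per tissue;
    the ancestor comes from the sister-species table.  Returns the input
    columns plus e_d1a, e_d2a, e_comb and fate.
    """
    rows = []
    for t in triplets.itertuples(index=False):
        d1 = dup_tpm.loc[t.d1_id].to_numpy(dtype=float)
        d2 = dup_tpm.loc[t.d2_id].to_numpy(dtype=float)
        anc = to_relative(sister_tpm.loc[t.anc_id].to_numpy(dtype=float))
        r1, r2 = to_relative(d1), to_relative(d2)
        comb = combined_profile(d1, d2)
        e1, e2, ec = euclidean(r1, anc), euclidean(r2, anc), euclidean(comb, anc)
        rows.append(
            {
                "d1_id": t.d1_id,
                "d2_id": t.d2_id,
                "anc_id": t.anc_id,
                "e_d1a": e1,
                "e_d2a": e2,
                "e_comb": ec,
                "fate": classify_fate(e1, e2, ec, cutoff),
            }
        )
    return pd.DataFrame(rows)


def fate_proportions(labels: pd.Series | list[str]) -> pd.Series:
    """Fate proportions with the two neofunctionalization directions pooled."""
    s = pd.Series(labels)
    if len(s) == 0:
        raise ValidationError("no triplets to summarize")
    pooled = s.replace(
        {"neofunctionalized_D1": "neofunctionalized", "neofunctionalized_D2": "neofunctionalized"}
    )
    order = ["conserved", "neofunctionalized", "subfunctionalized", "specialized"]
    props = pooled.value_counts(normalize=True).reindex(order, fill_value=0.0)
    props.name = "proportion"
    return props
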