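# Methods

This note documents the statistical procedures implemented in
`epistates`, the conventions fixed where a choice was open, what the
synthetic-data generator does and does not emulate, and known
limitations.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open internally. BED input is read
verbatim; 1-based conventions (VCF-style SNP positions) are shifted on
read. The interval engine (`genome_core.find_overlaps`) is defined by its
equivalence to the all-pairs brute force, which the test suite checks on
hundreds of random instances. Interval sorts break ties by
(chrom, start, end, label) for determinism. TSS flank windows are
strand-aware (upstream of a minus-strand gene extends toward larger
coordinates) and clipped at chromosome ends; whether clipping applies was
an open convention and is fixed here as "clip".

## Fold enrichment

For a state with A bases, an element set with B bases, C overlapping
bases and genome size D, the enrichment is `(C/A)/(B/D)`: the state's
coverage rate inside the element relative to its genome-wide rate, 1 under
the null. Element intervals are merged before B and C are counted, making
the statistic invariant to how the element set is split — a base-counting
semantics. Enrichment with A = 0 or B = 0 is reported missing (NaN), not
0 or ∞, so degenerate states cannot poison downstream summaries. Under
uniform random placement of the state the statistic is unbiased; the
acceptance suite verifies a 1 000-shuffle null mean within [0.95, 1.05].

State density profiles around the TSS average a per-gene indicator
(bin overlapped by the state or not), not raw base counts, so every gene
contributes equally regardless of segment sizes.

## Tissue specificity

A gene is specific to tissue t when `TPM_t ≥ 10 · Σ_{u≠t} TPM_u`
(fold-10 rule) or `TPM_t ≥ 1` with all other tissues exactly 0. Under the
fold-10 rule a gene can be specific to at most one tissue, and calls are
invariant to a global rescaling of all tissues. The same genes are
treated as "silenced" in the remaining tissues for contrast analyses.

"Uniquely present" marks are peaks overlapping the ±3 kb TSS window of a
specific gene in exactly one tissue's peak set (any-bp overlap); counts
are normalized by the genome-wide peak total for that mark. The
specific-vs-silenced contrast uses the Pearson χ² statistic on the 2×2
table (1 df, no continuity correction), computed in closed form
`N(ad−bc)²/(r₁r₂c₁c₂)`; an expected cell below 1 flags the result, a zero
margin is rejected. Peak counts (not gene counts) are the default
counting unit; the gene-count variant can be obtained by collapsing the
calls table before counting.

Density-vs-expression uses log₁₀(TPM + 0.01) — the pseudocount keeps zero
expressors finite — with 20 equal-width bins over the observed range and
an ordinary least-squares fit for R².

## Super-enhancer calling

Peaks whose nearest edges are ≤ 12 500 bp apart are stitched transitively;
cluster signal is the sum of member signals (no length normalization by
default). Clusters are sorted by ascending signal and both axes scaled to
[0, 1]. The discrete "tangent slope" at rank i is the backward difference
of scaled signal over a smoothing half-window of max(1, n/100) ranks
(forward difference at rank 0). Backward differences attribute the rise
at the elbow to the first high-signal cluster rather than to the last
low-signal one, which keeps the flagged set a clean suffix of the ranking:
a cluster is super iff every rank from it upward has slope > 1 (the last
slope-≤ 1 crossing, scanned from low to high rank, is the cutoff). Central
differences would flag the rank immediately below an abrupt jump as well,
which contradicts the intended semantics on the canonical example
(signals 1,1,1,1,100 → exactly one call). All-equal signals yield no
calls with a warning.

Cross-tissue merging is single linkage: two calls merge when their
overlap is at least 50 % of the shorter call's length (reciprocal mode
available); merged intervals span the union. Gene assignment extends gene
bodies by ±10 kb and annotates each assignment expressed (TPM > 2),
repressed (TPM < 0.2) or intermediate.

## CpG methylation

Site level is `reads_C/(reads_C + reads_T)`; CpG context only. Filtering
keeps depth ≥ 10 and depth ≤ the sample's 99.9th coverage percentile,
computed on the unfiltered sample. The percentile uses the 'higher'
empirical quantile — the smallest depth actually attained at or above the
rank — so the threshold is a real data value; with integer depths and the
heavy ties typical of sequencing coverage this also makes the filter
idempotent (no quantile rule is exactly idempotent on a sparse continuous
tail, where each pass shaves the extreme order statistics).

TSS profiles are gene-weighted: site levels are averaged per bin within a
gene, then across genes, so CpG-dense genes do not dominate (a per-site
variant would weight by CpG density). State-body profiles rescale each
state instance to a fixed number of body bins with fixed-bp flanks, and
average per-instance bin means across instances. The
methylation-expression association reports the Pearson r (and R²) of
per-gene promoter mean level against log₁₀(TPM + 0.01), flagging
zero-variance inputs as undefined.

## QTL, SNPs and motifs

Enhancer/QTL overlap counts each enhancer-state segment once, with its
total bp shared with the merged QTL set. Per-chromosome enrichment uses a
length-proportional null: expected count on chromosome c is
`total · L_c / L_genome`; folds weighted by expected counts average to 1
by construction. A QTL-base-weighted null is a straightforward variant
(weights proportional to QTL bases per chromosome) for users who prefer
conditioning on the QTL map. SNPs are retained when their position lies
inside at least one QTL, one segment labeled EnhG/Str.Enh/MidEnh, and one
motif occurrence; one hit row is emitted per (SNP, QTL, segment, motif)
combination, and the motif-family summary is computed over deduplicated
(SNP, family) pairs, with both raw-hit and unique-SNP counts reported
(the two natural dedup levels). Motif occurrences are inputs; no PWM
scanning is performed.

## Duplicate-gene retention fates

Expression profiles are converted to proportions of total expression over
tissues (genes expressed nowhere are ineligible). For a triplet
(D1, D2, ancestor proxy) the distances `E_D1,A`, `E_D2,A` and — using the
element-wise sum of the absolute expression vectors — `E_D1+D2,A` are
Euclidean distances on the simplex. The divergence cutoff is
`median(E_S1,S2) + (Q3 − Q1)/2` over singleton-pair distances, quartiles
by linear interpolation (Tukey hinges by option); one global cutoff is
used rather than tissue-matched baselines. The rule table
(≤ is inclusive; t = cutoff):

| E_D1,A | E_D2,A | E_D1+D2,A | fate |
|---|---|---|---|
| ≤ t | ≤ t | — | conserved |
| > t | ≤ t | — | neofunctionalized (D1) |
| ≤ t | > t | — | neofunctionalized (D2) |
| > t | > t | ≤ t | subfunctionalized |
| > t | > t | > t | specialized |

The rules partition all outcomes (verified exhaustively over the 2³ sign
patterns). Comparisons use an absolute tolerance of 1e-9: with a
noise-free baseline the cutoff is exactly 0 and float residue from the
normalization round trip (~1e-16) must not read as divergence. The two
neofunctionalization directions are tracked internally and pooled for
headline proportions.

## Epigenetic divergence

Promoter windows are the 2 kb immediately upstream of each TSS
(strand-aware). Per-mark profiles are 10-bin covered-fraction vectors
across the window; fold enrichments (window coverage over genome-wide
coverage rate, log₂ with pseudocount 1e-3) are z-scored across genes with
the population (n-denominator) standard deviation, giving mean 0 and std
1 exactly. Pair divergence is the Pearson r of the two copies' profiles
and 1 − r; zero-variance profiles are flagged undefined. State-count
divergence correlates the two copies' 10-dimensional segment-count
vectors and reports per-state shared counts min(c₁, c₂). Category
comparisons use the two-sided Wilcoxon rank-sum test: exact enumeration
when the combined sample is ≤ 12 without ties, otherwise the normal
approximation with midranks and continuity correction.

## Synthetic data

The generator emulates the *shape* of a six-tissue study: 3 chromosomes
× 1 Mb with 300 non-overlapping genes by default (tissues named brain,
liver, spleen, muscle, intestine, kidney). Each sub-generator draws from
its own stream derived from the master seed, so stages regenerate
independently and full runs are byte-identical.

Planted structure and defaults:

- Expression: log-normal TPM; 20 % of genes planted tissue-specific
  (four-fifths by the fold-10 rule, one-fifth by the 1-vs-zero rule);
  background genes are adjusted away from both rule boundaries so planted
  labels are the unique correct answer.
- State tracks: complete per-chromosome tilings; expressed genes (TPM > 1)
  get TssA at the TSS, a TssAFlnk flank and one upstream active-enhancer
  segment; gaps are filled with geometric-dwell segments (mean dwell per
  state roughly matching promoter/enhancer ≈ 1 kb, poised/polycomb
  several kb, quiescent tens of kb).
- H3K27ac clusters: a shared layout of 100 stitchable clusters; per
  tissue 5 get high, well-separated signals (mostly common across tissues
  plus one tissue-unique) and 95 get low signal in a narrow band, so the
  ranked curve's slope-1 crossing is unique and zero-noise recovery is
  exact.
- Methylome: background level 0.75; a flat dip to 0.10 within ±250 bp of
  each TSS ramping back to background by ±2 kb; level 0.5 inside active
  states; Poisson(30) depths with planted sub-10-depth sites and a few
  sites far above the 99.9th percentile (capped below 0.1 % of sites,
  since more cannot all exceed that percentile).
- Triplets: ancestors from a Dirichlet(1.5) over tissues; fates planted
  by largest-remainder apportionment of the configured mix (default
  0.736/0.142/0.002/0.120, matching the headline retention proportions);
  divergent profiles are redrawn until ≥ 0.3 from the ancestor;
  subfunctionalization partitions the ancestral profile tissue-wise so
  the combined profile is exactly ancestral. Noise is i.i.d. Gaussian on
  the simplex (sd 0.02 by default), clipped at 0 and renormalized.
  1 000 singleton pairs (ancestor + the same noise, twice) define the
  baseline — a scale at which the median+SIQR cutoff is stable; note the
  baseline distance is √2 times the single-copy noise scale, which is
  what gives the classifier its margin.
- QTL/SNPs: 12 QTL of 150 kb with traits cycling growth/fillet-quality/
  BCWD; 30 % of 400 SNPs planted inside enhancer∩QTL∩motif triples with
  motif families apportioned exactly 70/30 C/EBP/GR; decoys are
  constructed to fail exactly one condition, and a 20-bp exclusion zone
  around every placement prevents decoys from entering planted motifs.
- Pair promoter profiles: gamma-distributed bin values with
  fate-dependent copy-to-copy noise planting the similarity ordering
  conserved > specialized > neofunctionalized.

What the generator does **not** emulate: read-level artifacts (mapping,
duplicates, bisulfite conversion errors), peak-calling noise, realistic
linkage between QTL and gene positions, chromatin-state autocorrelation
beyond geometric dwell, or biological coupling between the expression
fates and the promoter epigenetic profiles (the latter are planted
directly). Passing tests therefore demonstrate correctness of the
computations on inputs with known structure, not end-to-end robustness on
real sequencing data.

In the orchestrated pipeline the epigenetic-divergence stage consumes the
generator's per-pair promoter profiles directly, because synthetic
triplets are expression-only entities not placed on the simulated genome;
the track- and peak-based profile extractors are exercised separately on
constructed tracks.

## Problem sizes and determinism

Default sizes (300 genes, 20 000 CpGs, 500 triplets, 100 enhancer
clusters per tissue, 400 SNPs) keep a full run in seconds while leaving
every statistic comfortably estimable; the acceptance checks use larger
sizes where precision matters (1 000 genes for specificity, 100 000 CpGs
for the methylation dip, 1 000 triplets for fate accuracy, 1 000 shuffles
for the enrichment null). All randomness flows from a single seed;
`run_all` writes a manifest (seed, parameters, SHA-256 of every output,
record counts, no timestamps) and reruns are byte-identical.

## Known limitations

- The tangent-slope cutoff assumes a convex ranked-signal curve; signal
  distributions with multiple elbows yield the highest suffix only.
- The χ² contrast treats peaks as independent observations; spatially
  clustered peaks violate this, as they do in any peak-count χ² analysis.
- The length-proportional QTL null ignores chromosome-specific QTL
  density; use the QTL-base-weighted variant when that matters.
- One global SIQR cutoff is used for all triplets; tissue-matched
  baselines would require singleton sets per tissue composition.
- With a noise-free baseline the cutoff degenerates to 0 and
  classification of real (noisy) data is meaningless; the cutoff is only
  as good as the singleton set behind it.
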