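# Methods

## Coordinate and overlap conventions

All genomic coordinates are 0-based, half-open (BED convention),
including bedpe anchors. Overlap anywhere in the package means ≥ 1 bp,
matching default bedtools semantics. "Subtraction" is whole-interval
exclusion (bedtools `intersect -v`), not base clipping: peaks are
treated as atomic regulatory elements, so a peak touching a promoter
window is removed entirely rather than trimmed. Intersection is
likewise selection (`intersect -u`): the left-hand set's coordinates
are preserved. Every operation returns sets sorted by
(chrom, start, end).

Consensus across samples is reference-anchored: the intervals of a
designated reference sample (default: the first) that overlap at least
one interval in every other sample. This keeps the output coordinates
well-defined without inventing a merged coordinate system.

## Region derivation parameters

- ATAC/CTCF summit flank: 100 bp (200 bp peaks). Summit-less intervals
  are rejected by `extend_summits`; a reader flag
  (`summit_from_midpoint`) can substitute the midpoint where summit
  offsets are genuinely unavailable.
- Promoter window flank: 2500 bp per side of the TSS (5 kb total) — one
  2.5 kb loop bin on either side of the TSS. Distal means zero overlap
  with any such window.
- CTCF-high identification: k-means (k = 2, 10 restarts, seeded
  k-means++) on the per-region signal matrix; the "high" cluster is the
  one whose centroid has the largest mean across samples. Inputs with
  fewer distinct rows than k fail loudly rather than returning an
  arbitrary split. The features may be peak scores or read coverage;
  the matrix abstraction accepts either. The selection is invariant to
  row order and to common positive rescaling of all samples.

## Knee-point thresholding

Contact counts of enhancer–promoter pairs, sorted descending, are
fitted with `value = a·e^(−b·rank)` by ordinary least squares on
log-values — deterministic and robust, at the cost of weighting
relative rather than absolute errors. Fits with slope ≥ −1e−10 are
flagged non-decaying and refused a knee (the tolerance absorbs float
noise on exactly constant inputs).

For the knee, ranks are min-max normalized to [0, 1] and fitted values
are normalized to their maximum, so the chord always runs from (0, 1)
to (1, y_min). The knee is the rank whose *fitted* point maximizes the
perpendicular distance to the chord (a `distance="vertical"` variant
measures the vertical gap instead); ties break toward the smallest
rank, which retains more pairs above the threshold. The threshold
returned is the *observed* count at the knee rank, so downstream
filtering happens on the original count scale. For a noiseless
exponential `e^(−c·t)` this construction has the closed-form solution
`t* = −(1/c)·ln((1 − e^(−c))/c)`, which the tests verify to within one
grid step for c ∈ {1, 2, 5, 10}; the knee rank is invariant to scaling
all counts by any positive factor.

## Loop filtering and cross-sample intersection

Loop catalogs are all-to-all bedpe with a contact-count column
(default: column 7), 2.5 kb bins and a 10 kb minimum anchor-midpoint
cis distance; trans and shorter pairs are dropped and counted at parse
time. A loop becomes an EPI candidate when one anchor overlaps an
active TSS window (H3K4me3-marked) and the other a consensus enhancer,
in either orientation; an anchor overlapping several TSS windows yields
one record per gene (the procedure is gene-centric). Counts from
multiple bin pairs hitting the same (gene, enhancer) key are summed —
summation preserves total signal — and a loop matching the same key
through both orientations contributes once, which makes the operation
exactly symmetric under anchor swapping.

Depth normalization multiplies each sample's counts by
`depth_max / depth_sample`, so the deepest library is the unit
reference. The knee is computed per sample on its normalized EPI
counts, thresholding precedes the cross-sample intersection, and pair
identity across samples is (gene id, consensus enhancer id) — bins
differ between samples, so coordinate-level identity would be
unattainable. The intersected table reports the per-sample counts and
their minimum as the consolidated count.

## Gene classes and hub connectivity

DE thresholds are strict, exactly as stated: down means
log2FC < −0.25 *and* FDR < 0.05; nonregulated means |log2FC| < 0.15
*and* FDR > 0.25. Genes at a boundary or between the windows (e.g. FDR
0.1 with small fold change) are "other" and excluded from the
comparison; up-regulated genes are not modeled. Common dependent genes
are those down in every sample.

A gene's hub size counts *distinct* TF peaks that (i) lie outside all
promoter windows and (ii) overlap at least one enhancer looped to the
gene; a peak reachable through two enhancers of the same gene counts
once. The class comparison is a pooled-variance two-sided Student's t
(a Welch option exists); two zero-variance groups with equal means
return t = 0, p = 1 rather than NaN.

## Cell-state scores

The signature score of a unit is the mean of within-gene z-scored
(population SD) expression over the signature genes present in the
matrix — deterministic and dependency-free; genes absent from the
matrix are skipped with a warning and zero-variance genes contribute 0.
The basal score is flipped negative and added to the classical score
(tumor-type score, x-axis); the intermediate score is
`(classical + basal) − |tumor-type|`, algebraically
`2·min(classical, basal)` (y-axis), which places coexpressing units
above committed ones. The input is assumed library-normalized and
log-transformed; a guard warns on integer-count-like matrices. Bulk
panels with ≥ 3 samples are projected per gene through Pearson
correlation with the per-sample classical and basal score vectors, the
same two formulas then applied to (r_classical, r_basal); zero-variance
genes are emitted as missing.

Where the intermediate formula was genuinely ambiguous, this reading
was chosen because it is the one under which coexpressors score highest
on the y-axis — the geometry the diagram is designed to show.

## Phenotype scoring

The treatment effect is `E = 1 − treated/control` confluency at the
last shared timepoint by default (an AUC mode compares trapezoidal
areas instead); E = 0 means no effect, E = 1 complete suppression, and
a zero control is an error. The Bliss score of a combination is
`E_combo − [E_a + E_b − E_a·E_b]`: zero on the whole independence
surface, positive for synergy, negative for antagonism, bounded in
[−1, 1] for effects in [0, 1].

The positivity threshold fits a 2-component Gaussian mixture to log
intensities with seeded EM initialized at the 25th/75th quantiles
(deterministic and translation-equivariant, so scaling intensities by a
factor shifts the threshold by exactly its log). The threshold is the
equal-posterior crossing between the two component means, found by root
bracketing; when extreme weights leave no crossing strictly between the
means, the point of closest posterior balance on a 1001-point grid is
used. Fits with Ashman's D < 2 (component separation in pooled-SD
units) are flagged unimodal — the natural-seeming "means closer than
the pooled SD" rule never fires, because a 2-component fit of a single
Gaussian always lands its means ~1.6σ apart. Positivity is
log-intensity ≥ threshold; fixed user-supplied cutoffs are supported,
with ≤ semantics for marker-*loss* calls. Co-positivity fractions are
computed per cell class (class-defining marker requirements, e.g.
pan-CK⁺/HNF4A⁺/KRT5/6⁻), with empty classes reported as missing
rather than zero.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of `SimConfig` (seed included);
identical configs produce byte-identical files, and truth tables are
emitted next to each dataset. The default scale — 2 chromosomes × 5 Mb,
300 genes, 6 samples, 40 shared enhancers — runs the full pipeline in a
few seconds on one CPU; it was chosen as the smallest scale at which
every stage (consensus, CTCF subtraction, knee, intersection, hub
statistics) operates away from degenerate edge cases.

The genome is laid out one feature per 10 kb slot, which guarantees
non-overlapping promoter windows, distal enhancers, and loop anchors
that map to at most one feature. Planted gene–enhancer links give
dependent genes 6 enhancers and nonregulated genes 2 on average (±1
per-gene jitter, so hub sizes have realistic within-class variance);
their loop counts are drawn from a high regime (200–400, scaled by each
sample's depth so normalization equalizes them), while background
gene–enhancer pairs — resampled independently per sample — follow an
exponentially decaying rank profile topping out at ~50, and pure-noise
loops join unassigned slots. DE tables draw each class from bounded
uniform windows placed strictly inside its defining thresholds, so
classification recovers truth exactly at the default effect size
(|log2FC| = 1). Background CTCF rows carry an exactly constant baseline
(high rows are noisy); this idealization makes a zero high-fraction
config degenerate cleanly instead of producing an arbitrary split.

Passing recovery tests on these data shows the *procedures* are correct
and correctly composed; it does not show robustness to features real
data have and the generator does not: overlapping and nested peaks,
copy-number-driven count inflation, distance-dependent contact decay
within loops, batch effects between samples, doublets or ambient
expression in single-cell matrices, or segmentation artifacts in
imaging tables.

## Numerical and degenerate-input choices

- Knee ties break to the smallest rank; thresholding keeps counts
  exactly equal to the knee value.
- `RankedDistribution` requires ≥ 3 positive values; constant inputs
  are flagged non-decaying, not knee-located.
- Depth normalization requires positive depths; a single sample gets
  factor exactly 1.
- EPI intersection refuses tables with pairwise-disjoint enhancer
  namespaces (a symptom of ids not coming from a shared consensus set).
- The t comparison requires ≥ 2 observations per group.
- GMM fitting requires ≥ 20 observations and ≥ 2 distinct values.
- Empty imaging classes report missing fractions with their size 0.

## Known limitations

- The discovery cascade treats peak catalogs as given; peak calling,
  alignment, loop calling and differential-binding analysis are out of
  scope, as are motif analysis (candidate enhancers are exported as BED
  for external tools), survival statistics and image segmentation.
- The log-OLS exponential fit is biased when the count distribution has
  a heavy plateau of high values; the knee is robust to this in
  practice because only the fitted curve's bend, not its head, decides
  the threshold, but strongly non-exponential tails would call for the
  vertical-distance variant or a different model.
- Reference-anchored consensus depends (mildly) on the reference
  choice; the reference is a configuration knob.
- Single-sample runs degenerate gracefully (consensus and intersection
  become identities) but lose the subtype-independence claim the
  multi-sample design exists for.
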