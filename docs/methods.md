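# Methods

## Reference cleaning

The reference is a genes × cells integer count matrix with per-cell
`cell_type` and `sample_id` labels; labels are taken as given (no doublet
detection, clustering or annotation). Cleaning runs in a fixed order —
(1) combo filter, (2) ortholog mapping, (3) low-detection filter,
(4) symbol dedup, (5) category exclusion — chosen so that gene-level
statistics (detection counts, totals, means) are computed on the cell set
that downstream steps will actually see. Steps 3–5 only remove genes, so
the combo guarantee (≥ `min_cells` cells per surviving (type, sample)
pair, default 10) still holds at the end, and the gene-level filters
commute and are idempotent.

Parameter meanings and defaults:

* `min_cells = 10` cells per (cell type, sample) combination — the minimum
  for a usable per-sample mean expression estimate.
* `min_cells_detected = 20` cells with count > 0 per gene. "Detected"
  means any nonzero count, not a UMI threshold.
* Ortholog mapping uses only `one2one` and `many2one` relations by
  default; `one2many`/`many2many` rows are dropped because no principled
  single target exists (an `expand_one2many` flag duplicates the source
  row under every target instead). "Most highly expressed" is the highest
  **total raw count across all cells** — totals rather than means so the
  choice is independent of cell-set normalization — with ties broken
  toward the lexicographically smaller source symbol for determinism.
* Duplicate symbols keep the copy with the highest **mean** count (first
  occurrence on ties).
* Mitochondrial/ribosomal genes are recognized by case-sensitive symbol
  prefixes (`mt-`, `Rps`, `Rpl` for mouse; `MT-`, `RPS`, `RPL` for human),
  overridable by explicit lists; note the prefix semantics also remove
  e.g. `Rpsa`. The cell-cycle list must be supplied by the user (any
  G2M/S list, e.g. the one shipped with Seurat, works).

## Cell-type association score

Per-type mean expression is computed on `log1p` of per-cell CPM by default.
The basis is configurable (`raw`, `cpm`, `log1p-cpm`) and recorded in the
signature because the published description does not pin it down;
`log1p-cpm` is the default because it removes per-cell depth differences
and compresses the heavy right tail of expression, so no single gene
dominates the weighted sum. The per-gene centering subtracts the
**unweighted mean of per-type means** (not the grand mean over cells), so
abundant cell types do not drag the baseline; consequently every signature
row sums to zero to machine precision, and a bulk sample with constant CPM
over all signature genes scores exactly zero.

Per-type means pool all cells by default; a `per_sample_means` flag
averages per-(type, sample) means with equal weight instead, which is the
reason the ≥ 10-cell combo filter exists. Scores are sums over the shared
genes; a per-gene-normalized copy (`score_per_gene`) is emitted alongside
for cross-run comparability, since the sum scales with the overlap size.
The score is linear in the CPM vector, so a mixture of two samples scores
as the same mixture of their scores.

Group comparison is a per-cell-type two-tailed t test, Welch by default
(equal variances are not assumed; a Student option exists). No
multiple-testing correction is applied across cell types by default —
each type is reported marginally — with BH available via `adjust="bh"`.
Zero-variance degenerate inputs resolve to t = 0, p = 1 when the group
means agree (and p = 0 otherwise) rather than NaN.

## Marker gene sets

Reference counts are normalized per cell by a **median-library scaling**
(each cell rescaled so its library equals the median library size). This
is a deliberately simple, documented stand-in for pooled size-factor
normalization; it preserves within-cell relative expression, makes
per-cell totals equal, and changes fold-change values only slightly.
`none` and user-supplied factors are selectable, and the choice is
recorded.

The test per (gene, type) is a two-sided Wilcoxon rank-sum, one type vs
all others: exact enumeration when both groups have ≤ 8 cells and no ties,
a tie-corrected normal approximation (with continuity correction)
otherwise; the two agree within 0.02 absolute p at the crossover. Fold
change is a linear ratio of group means of normalized expression with a
symmetric pseudocount of 1e-8 (only there to guard zero denominators; it
is negligible against any real expression). BH-FDR is applied across genes
**within each cell type** — each type's marker hunt is its own family.

Sets keep genes with adjusted p < 0.05 and fold change ≥ 1.5, sorted by
decreasing fold change (ties by smaller adjusted p, then symbol),
truncated to 200; fewer passers are all kept; empty sets are allowed with
a warning. GMT serialization writes one set per line
(`name TAB description TAB gene…`); read∘write is the identity, and an
empty set is written with a trailing empty field so the line still parses.

## Overrepresentation

The DE filter is inclusive on the fold-change bound (FC = +1.5 passes
"≥ +1.5") and strict on the p bound (adjusted p = 0.05 fails "< 0.05");
fold changes are signed linear values with |FC| ≥ 1. The enrichment p for
a set is the upper hypergeometric tail P(X ≥ k) with universe N, set∩
universe K, query n, overlap k (k = 0 gives p = 1). Correction across
sets is Benjamini-Hochberg FDR at a 0.05 significance threshold
(Bonferroni selectable). The default universe is the DE-table genes
intersected with the union of all marker-set genes — the genes both sides
could in principle have reported — with `de`, `gmt`, or a user list as
alternatives; overlap counts are universe-independent but p values are
not, so the universe choice is always explicit in the output. Symbol
matching is case-sensitive; a `capitalize_mouse` helper maps UPPER-case
symbols to Title case for cross-species queries.

Overlap matrices keep only query genes present in ≥ 1 set, so column sums
equal the per-set overlap counts.

## Histomorphometry

Images are 8-bit grayscale; RGB input is collapsed by the unweighted
channel mean (rounded), matching the common default of histogram-based
ImageJ workflows, with Rec. 601 luminance weights optional. The Minimum
auto-threshold smooths the 256-bin histogram with a 3-point running mean
(reflected edges) until exactly two local maxima remain (cap 10 000
passes; plateaus count once via a direction scan) and returns the level of
the smoothed histogram's minimum between the peaks. It is deterministic
and invariant to scaling all counts by a positive constant; a histogram
that never becomes bimodal (e.g. a uniform image) raises a thresholding
error. The bimodality check runs **before** each smoothing pass; scikit-
image's `threshold_minimum` smooths once first, so the two can differ by a
couple of gray levels on already-bimodal histograms — the test suite pins
the loop against an independently coded reference and cross-checks
proximity to scikit-image.

Foreground is strictly **above** the threshold (droplets are the bright
side); exclusion masks (manually drawn vessel/artifact regions, supplied
as binary images) force pixels to background before the histogram and the
labeling. Components are 8-connected; hole filling is off. The size
cutoff is enforced in physical units with strict `<`, so a 30-px droplet
(exactly 18.0 µm² at the default 0.6 µm²/px calibration, which is itself
derived from the 30 px ↔ 18 µm² equivalence and always overridable) is
retained and a 29-px droplet is excluded. Bins are half-open
([18, 200), [200, 400), …) with an open last bin at a configurable cap
(default 2000 µm²) so frequencies remain comparable across animals;
per-animal summaries pool all fields of view before binning and the
median. Group comparisons are unpaired two-tailed t tests on per-animal
medians and on each bin's frequencies. Thresholding is per image, not per
batch. Colorization paints each surviving droplet its bin's palette color
and is a pure function of (labels, records).

Stained-area ratios threshold the signal channel with Yen and the nuclei
channel with Otsu (both from scikit-image), count pixels strictly above
threshold, and divide the percent areas; a constant channel has zero
foreground, and a zero nuclei area raises an error rather than returning
infinity.

## Synthetic data

The generators are pure functions of their parameters and seed. The
single-cell simulator draws lognormal baseline means and negative-binomial
counts (gamma-Poisson, dispersion α = 0.3 by default, Poisson selectable)
— NB being the standard overdispersed RNA-seq noise model — and multiplies
the planted markers' means by `effect_fold` (default 10) in their type
only; defaults are 5 types × 100 cells, 500 genes, 20 markers/type,
3 donors. Bulk simulation mixes the reference **mean profiles** (not
resampled cells) so the score's linearity is exact in expectation, and
draws multinomial counts at the requested depth. DE tables plant up/down
genes that pass the filter by construction while every null gene fails at
least one criterion. Section images place non-touching disks by rejection
sampling (bounded retries, then an error), at background 120 / foreground
240 with Gaussian pixel noise (σ = 10) — 6 σ below the ~180 valley, so
segmentation recovers the rasterized disks exactly; the truth records the
rasterized pixel count of every disk, which is the correct target for the
area-recovery checks (πr² differs from the raster by discretization).

What the synthetic data deliberately does **not** emulate: real library
size and cell-type frequency distributions, per-donor batch structure,
gene-gene correlation, ambient RNA, irregular droplet shapes, uneven
staining or illumination gradients. Passing recovery tests therefore
demonstrates the pipeline's correctness on data satisfying its own
modeling assumptions, not robustness to every artifact of real sections
or real dissociation protocols.

## Problem sizes in the standard checks

The packaged property checks run at desk scale, chosen to exercise every
code path with comfortable statistical margins: 100 random references for
signature centering; 100 replicates of the 0.2 → 0.4 fraction-shift design
(5 types, 300 genes, 40 cells/type, 8 bulk samples at depth 2×10⁵); 50–100
replicates of marker recovery at 100 cells/type; exhaustive hypergeometric
enumeration to N = 12; 20 noisy synthetic sections for the droplet
pipeline. Larger sizes change none of the conclusions, only the runtime.

## Known limitations

* The association score's absolute magnitude depends on the expression
  basis and on whether scores are summed or averaged over genes; only
  relative and group-level structure is interpretable across settings.
* The median-library normalization is not scran pooling; marker-set
  contents can differ at the margin for genes near the fold-change or FDR
  boundaries.
* Hypergeometric p values depend on the universe; report it with results.
* The Minimum threshold assumes a genuinely bimodal histogram; sections
  with almost no lipid or almost all lipid will fail to threshold, by
  design, rather than return an arbitrary cut.
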