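# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `spatialmargin`. Nothing here asserts an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic section generator

The generator (`spatialmargin.simulate`) emulates a spot-binned spatial
transcriptomics section with a planted tumor so that every downstream
stage has an analytic ground truth.

**Geometry.** Spots sit on a rectangular grid with pitch 50 µm (one
spot per 50-µm bin), centers at ((i+½)·pitch, (j+½)·pitch), origin at
the bottom-left corner, y up, all distances Euclidean in µm. The number
of spots is exactly ⌊width/pitch⌋·⌊height/pitch⌋. The tumor is a polygon
(usually a finely discretized disk) that must keep ≥ 1500 µm clearance
to every section edge so all six zonal bands fit inside tissue.

**Composition.** Each spot receives non-negative mixing weights per cell
type, normalized to sum to 1. Inside the tumor the malignant "AT2-like"
type has weight `tumor_purity` (default 0.7, in the range deconvolution
typically reports for tumor-dense multi-cell spots); outside, the normal
"AT2" type has weight `normal_dominance` (default 0.55); the remainder
is spread uniformly over the other types. Peri-tumoral gradients add
`peak_fraction · exp(−d/decay)` to one type's weight on one side of the
border, where d is the exact distance to the tumor boundary; the
exponential form is a modelling choice — real sections show empirical
enrichment profiles, not a known functional form. Ground-truth labels:
`truth_type` is the argmax of the noise-free weights, and `truth_band`
comes from the exact signed distance to the planted boundary with the
same half-open interval conventions the geometry module uses.

**Abundance noise.** The `abundance` field plays the role of an external
deconvolution's *estimate* of the composition: optionally the clean
weights plus i.i.d. Gaussian noise (`abundance_noise_sigma`), clipped at
zero. Counts are always drawn from the clean weights. Note a degenerate
property of noise-free scenes: the clean weights are piecewise constant,
so the dominant/second ratio is heavily tied and the strict
percentile-threshold assignment rule can unassign entire regions; scenes
meant to exercise assignment should carry a realistic noise level
(σ ≈ 0.05–0.1).

**Counts.** Expected count of gene g in spot s is
`L_s · Σ_t A_st · mū_gt`, with `mū` the per-type signature normalized to
sum to 1 over genes and `L_s` a log-normal library size (median 3000
transcripts, σ_log = 0.35 — inside the per-spot transcript range
spot-based platforms report; both configurable). Counts are negative
binomial via gamma–Poisson mixing with per-gene dispersion (log-normal
around 2), matching the overdispersion of spot data; dispersion `inf`
gives exact Poisson. A single scene seed drives everything; each stage
(library sizes, abundance noise, counts) uses a deterministically
derived substream, and counts are drawn per spot from per-spot
substreams. This makes CNV planting exactly local: `plant_cnv` re-draws
only tumor spots with block-multiplied means, all other spots stay
bit-identical, and a block factor of 1.0 reproduces the input section
exactly.

**Signature panels.** `make_signature_panel` gives every cell type a
disjoint block of 10 consecutive marker genes with 8-fold elevated mean,
spread across contiguous chromosomes of near-equal size; mitochondrial
flags are placed on non-marker genes. This guarantees distinguishable
signatures and genome-localized markers (useful for CNV sentinels).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: segmentation/registration artifacts, spatial
autocorrelation of library size, zero inflation beyond NB, platform
chemistry, irregular tissue boundaries, holes and folds, and real
deconvolution error structure (which is correlated across types and
spots, not i.i.d. Gaussian).

## QC and assignment

"Expressed"/"detected" means count > 0. Cell-level filters (200–2500
expressed genes, ≤ 5 % mitochondrial transcript fraction) run before the
gene-prevalence filter (≥ 3 cells); spot-level filtering removes spots
whose detected-gene count is *strictly below* the section's 5th
percentile (linear-interpolation percentile — stated because tie
behaviour depends on the method) and then genes detected in < 10
retained spots. Both filters are idempotent.

Assignment: abundances are scaled per spot by the row maximum (0–1
scale). The ratio dominant/second is scale-free, so pre-scaled and raw
inputs give identical calls. "Surpassed" is read as a strict inequality:
spots exactly at the threshold stay unassigned, so a fully tied section
assigns nobody (and warns). Spots whose second-highest abundance is zero
get ratio +∞; infinite ratios are excluded from the threshold
distribution but always assigned. All-zero spots are flagged and never
assigned. With continuous ratios and q = 10 the assigned fraction
converges to 90 %.

## Border detection

Pipeline order: threshold → binary image → Gaussian blur → Canny →
morphological closing → hole filling → contour extraction →
simplification. Defaults: Otsu threshold on the positive-pixel histogram
(fixed τ available); blur σ = 50 µm (one pixel at the default raster);
Canny hysteresis at 0.1/0.3 of the maximum gradient; closing kernel
3 × 3 pixels; Douglas–Peucker tolerance 25 µm (0 exposes the raw
contour). All are configurable; none is sharply determined by the
procedure itself, so they are deliberately plain image-processing
defaults.

One numerical choice matters: the filled Canny edge map decides *which*
closed regions exist, but its pixel mask is quantized to half-pixel
staircases (±25 µm at 50-µm pitch), which alone biases the area of a
1000-µm disk by several percent. The candidate boundary is therefore
traced as the sub-pixel 0.5-level contour of the blurred binary field
(for a blurred step edge the 0.5 level is the edge position, with a
curvature bias of order σ²/r ≈ 2.5 µm at r = 1000 µm). The largest-area
candidate becomes the region of interest; all closed candidates are kept
(multifocal sections), and with several band sets the nearest borderline
claims each spot. The borderline is the ROI boundary oriented
counter-clockwise.

## Zonal bands

TR_k = interior points with border distance in [off_{k−1}, off_k),
NR_k = exterior points in (off_{k−1}, off_k], off_0 = 0, defaults
(500, 1000, 1500) µm. A point exactly on the border is TR1. Band
*polygons* are buffer-ring differences clipped to the section extent
(for areas and GeoJSON export); band *membership* of a spot uses the
exact signed distance, so the half-open conventions are honoured
independently of polygon predicates. For a straight border every band is
exactly 500 µm wide; the construction commutes with rigid motions.

## Zonal statistics

* **Composition units.** Two proportions are supported: assigned-spot
  counts (the default for labelled data) and abundance-mass shares
  (the type's share of summed abundance in the band). The second exists
  because a real but never-dominant gradient — e.g. a fibroblast
  component that peaks at 0.25 of a spot while the malignant type holds
  0.5 — is invisible to dominant-type counts yet is exactly what
  per-zone "relative abundance" boxplots display. Enrichment tests can
  be run per-section (band proportions across replicate sections, the
  default test unit) or per-spot; both modes exist because published
  zonal comparisons rarely state which unit they used.
* **Rank-sum test.** Mann–Whitney U with midranks. For pooled n + m ≤ 12
  the two-sided p is computed by enumerating all C(n+m, n) group
  assignments (correct under ties); larger samples use the normal
  approximation with continuity and tie corrections. Fully tied input
  gives p = 1.
* **BH correction** is applied within one comparison family (genes of
  one contrast; cell types of one composition table; group pairs of one
  burden comparison).
* **Differential expression.** Expression is log1p of library-size
  normalized counts (target sum 10⁴) unless marked pre-normalized;
  Welch's t (the unequal-variance variant, since groups of spots rarely
  share variance); log2FC is the difference of group means of log1p
  expression rescaled by 1/ln 2 (pseudocount 1). A gene is flagged iff
  |log2FC| ≥ 1.5 *and* BH-adjusted p < 0.05. Zero-variance genes get
  p = 1 with the fold change still reported. Note that a uniform depth
  shift between groups normalizes away entirely.
* **Gene-set score.** Mean expression of the set minus the mean of an
  expression-matched control pool: genes are ranked by mean expression
  into 25 bins and 50 control genes per set gene are drawn from the
  matching bin (set genes excluded), deterministically under a seed.
  Matched control is the default because raw set means are
  depth-confounded; a plain-mean mode is available.

## CNV burden

Genes are ordered by (chromosome, ordinal) with natural chromosome order
and gene-id tie-breaks; unannotated genes are dropped with a log entry.
The per-spot profile is log1p-normalized expression minus the mean
profile of reference-labelled spots (default label "AT2", the normal
counterpart of the malignant population), smoothed with a centered
250-gene moving average. 250 is even: the window covers 125 genes left
and 124 right of the center gene. Windows truncate at chromosome
boundaries (shorter realized windows near ends, never spanning two
chromosomes); chromosomes with < 3 genes pass through unsmoothed.
Compared to full inferCNV-style tools this deliberately omits per-cell
clipping, denoising and HMM segmentation — the smoothed relative profile
is the object of interest here, not discrete CNV calls.

Two burden statistics summarize a profile: `signed_mean` (default;
positive = net gain, matching the reading that a higher score means a
higher probability of gain) and `mean_square` (total aberration). A
practical caveat the tests make explicit: under library-size
normalization a focal gain depresses the normalized expression of all
other genes, so the genome-wide *signed mean* of a gain-only profile
cancels toward zero; comparisons of CNV *prevalence* between groups
should therefore use `mean_square`, which separates planted-CNV from
reference groups decisively.

## Pipeline, formats, reproducibility

`run_pipeline` executes simulate/load → spot QC → assignment → margin →
zones → CNV in order, echoes every parameter into `run_report.json`,
records all warnings, and is byte-reproducible for a fixed config and
seed. Formats: TSV tables, MatrixMarket counts with barcode/feature
sidecars, GeoJSON band geometry in µm, plain-text gene lists, YAML
scenes/configs. CLI exit codes distinguish parameter errors (2),
malformed inputs (3) and geometry failures (4).

## Problem sizes used in tests and acceptance

Simulated sections are 5 × 5 mm (10 000 spots) with 100–2000 genes,
1000-µm disk tumors, 200 spots/group for CNV comparisons, 50
observations/group for differential expression, and 8 replicate sections
for the zonal enrichment comparison. These sizes were chosen so each
recovery check has clear statistical headroom while a full run of the
suite plus the acceptance script stays in the minutes range on a single
CPU.

## Known limitations

* The borderline is computed from one cell type's abundance raster;
  pathologist annotations or multi-marker segmentation are out of scope.
* Gradients, noise and counts are simplified models (see generator
  section); recovery rates measured here bound what the method can do
  under those models, not on real tissue.
* Band areas near the section edge are truncated; composition statistics
  use realized band contents, and a band can legitimately be empty
  (e.g. TR3 inside a 1000-µm tumor, whose interior depth never reaches
  1000 µm at spot centers).
* The per-spot "CNV score" of the underlying literature is not specified
  beyond its direction; both burden statistics here are labelled
  interpretations.
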