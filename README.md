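# spatialmargin

Zonation analysis of tumor invasive margins in spatial transcriptomics.

Spot-based spatial transcriptomics (e.g. Stereo-seq binned to 50-µm
"bin100" spots) measures gene expression on a regular grid where each
spot mixes several cells. After an external deconvolution step has
estimated per-spot cell-type abundances, a recurring analysis pattern in
tumor biology is to (i) call a cell type per spot, (ii) find the
borderline between tumor and adjacent normal tissue, (iii) partition the
margin into fixed-width zonal bands on both sides of that border, and
(iv) ask how cell-type composition, gene programs and copy-number burden
change across those bands. `spatialmargin` implements that workflow as a
tested, reusable library with scikit-learn-style estimators, a thin CLI,
and a synthetic-section generator that plants ground truth for every
stage.

## The methods at its core

* **QC** — single-cell filters (cells with < 200 or > 2500 expressed
  genes or > 5 % mitochondrial transcripts removed; genes expressed in
  < 3 cells removed) and spatial filters (spots with detected-gene count
  below the section's 5th percentile removed; genes detected in < 10
  spots removed).
* **Ratio-threshold assignment** — abundances are scaled to 0–1 per
  spot; each spot is assigned to its dominant cell type iff the ratio
  r = a₍₁₎/a₍₂₎ of the two largest abundances strictly exceeds the 10th
  percentile of the section's finite-ratio distribution, else it stays
  `UNASSIGNED` (`SpotTypeAssigner`).
* **Border detection** — the malignant-type abundance is rasterized
  (one pixel per spot), then threshold (Otsu) → Gaussian blur → Canny
  edges → morphological closing → hole filling; candidate contours are
  refined sub-pixel against the blurred field and simplified; the
  largest-area candidate is the tumor region of interest
  (`TumorMarginDetector`).
* **Zonal bands** — perpendicular offsets at 500/1000/1500 µm on either
  side of the borderline define six 500-µm bands, TR1–TR3 inward and
  NR1–NR3 outward; spots are labelled by exact signed distance d to the
  border (tumor side [0, 500) → TR1, …; normal side (0, 500] → NR1, …).
* **Zonal statistics** — per-band composition (assigned-spot counts or
  abundance mass), two-sided Wilcoxon rank-sum tests (exact enumeration
  for pooled n ≤ 12, tie-corrected normal approximation otherwise),
  Benjamini–Hochberg correction, Welch-t differential expression with
  the |log₂FC| ≥ 1.5 and adjusted p < 0.05 flagging rule, and gene-set
  scores with expression-matched control subtraction.
* **CNV burden** — genes ordered along the genome, log1p-normalized
  expression expressed relative to a normal reference population (AT2
  by default), smoothed by a 250-gene moving average truncated at
  chromosome boundaries; per-spot burden is the signed mean (net
  gain/loss) or mean square (total aberration) of the smoothed profile
  (`CNVScorer`).

## Worked example

```python
import spatialmargin as sm

scene = sm.Scene(
    width_um=5000, height_um=5000,
    tumor_region=sm.disk(2500, 2500, 1000),
    gradient_specs=(sm.GradientSpec("Fibroblast", "tumor", 400, 0.4),),
    seed=11,
)
panel = sm.make_signature_panel(n_genes=200, n_types=5, n_chroms=4, seed=11)
section = sm.simulate_section(scene, panel)

det = sm.TumorMarginDetector().fit(section)
print(f"ROI area {det.region_.area_um2:.3e} um^2 "
      f"(true {scene.tumor_region.area:.3e})")
bands = det.predict(section)
agree = (bands == section.truth_band).mean()
print(f"band agreement with planted truth: {agree:.3f}")

comp = sm.band_composition(bands, abundance=section.abundance_frame())
fib = comp.set_index(["band", "cell_type"])["proportion"]
print(f"fibroblast share TR1={fib[('TR1','Fibroblast')]:.3f} "
      f"NR3={fib[('NR3','Fibroblast')]:.3f}")
```

prints

```
ROI area 3.124e+06 um^2 (true 3.142e+06)
band agreement with planted truth: 0.991
fibroblast share TR1=0.252 NR3=0.113
```

i.e. the detected tumor region matches the planted 1000-µm disk to ~1 %
in area, 99.1 % of spots receive the band the exact signed distance
assigns, and the planted tumor-side fibroblast gradient appears as an
elevated fibroblast abundance share in the first tumor band (TR1)
relative to the far normal band (NR3).

The same workflow is available from the shell:

```bash
spatialmargin simulate --scene scene.yaml --out section/
spatialmargin margin --input section/ --celltype AT2-like --out out/
spatialmargin zones --bands out/bands.geojson --input section/ --out zones.tsv
spatialmargin run --scene scene.yaml --out full_run/   # full pipeline
```

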