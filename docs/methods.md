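# Methods

This note documents the models and numeric conventions behind
`organoidquant`: what each stage computes, the parameters that matter, what
the synthetic-data generators emulate (and deliberately do not), and the
design choices made where the underlying procedure left them open.

## Rosette ROI geometry

A neural rosette is delineated by two hand-drawn closed boundary polylines in
physical micrometres: an outer tissue boundary and an inner luminal boundary.
Two regions of interest are derived:

- **Body** — the annulus between the boundaries, eroded by `erosion_um`
  (default **1.8 µm**) so that neither the outer edge nor the apical ribbon
  contaminates the body signal.
- **Ribbon** — the apical band of pixels within `dilation_um` (default
  **1.8 µm**) of the inner luminal boundary line.

All geometry is computed in physical units from pixel centres
(`(i + 0.5)·pixel_size_um`, y down). Rasterization sets a pixel iff its
centre lies inside the polygon; the erosion/dilation margins are realized by
exact Euclidean distance from pixel centres to the *continuous* boundary
polylines, not by discrete structuring elements or raster distance
transforms. This choice has three consequences worth stating:

1. the masks have an exact brute-force oracle (point-in-polygon plus
   point-to-segment distance minimization), which the test suite checks
   pixel-for-pixel;
2. mask areas converge to the analytic region areas as the pixel size
   shrinks, with no disk-discretization anisotropy;
3. body (`distance > margin`, strict) and ribbon (`distance <= margin`) are
   disjoint *by construction* at the shared 1.8 µm front.

Optional Otsu refinement (off by default) intersects a mask with
`channel >= t`, where `t` is an Otsu threshold computed on a 256-bin
histogram of the intensities inside the un-eroded geometric region (annulus
for the body, band for the ribbon). The refinement channel is the channel
being quantified; it is configurable because the original procedure does not
name it.

**Morphometrics.** Rosette area is the pixel count of body ∪ ribbon times
the pixel area — the lumen interior is *not* counted. The aspect ratio is
major/minor axis length of the ellipse with the same normalized second
central moments as the hole-filled union (the lumen is filled only for the
axis measurement, so the axes describe the rosette outline). Which region
feeds the axis measurement was an open choice; the hole-filled outline
matches the intuitive notion of rosette shape.

## Marker quantification (pTau S396, Reelin)

Diffuse marker images are quantified in two fixed steps, in this order:

1. **White top-hat**: the image minus its grayscale opening with a disk of
   radius **54 µm** (rounded to the nearest whole pixel; an error is raised
   if that rounds below one pixel). The large radius removes smooth
   background and illumination gradients while preserving features smaller
   than the disk.
2. **Otsu foreground mean**: an Otsu threshold on a 256-bin histogram of the
   whole filtered image; the foreground is `>= threshold` (ties go to
   foreground) and the reported statistic is the mean filtered intensity over
   the foreground, together with the threshold and foreground fraction.

Otsu is applied per image, not per ROI, since whole fluorescence fields are
being quantified. A regression test pins the order (top-hat first): applying
Otsu to the raw image mixes background plane into the foreground.

**Known bias under pixel noise.** With iid Gaussian pixel noise of standard
deviation σ, the grayscale opening sits below the true background by an
extreme-value deficit of roughly 2.5–3.5 σ (the erosion is a hard minimum
over ~9·10³ pixels at 1 µm pixels, only partially recovered by the
dilation). Every foreground pixel therefore carries a positive offset of
that size, and the recovered foreground mean overshoots the true amplitude
by ~6–9 % at σ = 5 AU on a 200 AU amplitude. The bias is a property of the
top-hat method itself, is absent in the noiseless case (where recovery is
exact), and shrinks with the noise level — it is measured, not corrected,
because the quantification procedure is fixed.

## Thresholded colocalization volumes (TVC)

Stacks carry three roles — *target* (β-catenin), *nuclear* (DAPI), *neuronal*
(NeuN). Each channel is binarized (per-channel Otsu over the whole volume by
default; fixed thresholds supported, and all thresholds are recorded in the
output). For channels A, B:

```
TVC(A, B) = 100 · |A ∩ B| / |A|   (percent of A's volume inside B)
```

The measure is asymmetric; the identity `TVC(A,B)·|A| = TVC(B,A)·|B|` is a
tested invariant. Because the denominator convention for the neuronal
comparison is a modelling choice, both orientations are emitted. 2D images
are accepted as single-slice volumes. Cross-region comparison uses the
ANOVA/Tukey chain below; with fewer than two regions (or fewer than two
stacks per region) the TVC table is still emitted and statistics are skipped
with a warning.

## Expression screen

The screen applies fixed numeric rules to gene × cell integer count
matrices; clustering, integration, doublet removal and GSEA scoring are
upstream inputs (an upstream multiplet rate of 0.8 % is carried as
provenance metadata only).

| rule | default | semantics |
|---|---|---|
| QC removal | nFeature > 8000, nFeature < 200, nCount > 50000, pct_mito > 20 | all strict; boundary cells survive |
| downsample | 6,400 cells | uniform, seeded, without replacement |
| normalization | counts / cell total × 10,000 | per-cell library size |
| cluster ratio | log2((mean_A + ε)/(mean_B + ε)), ε = 0.01 | arithmetic means of normalized counts per (gene, cluster) |
| DE selection | \|log2 ratio\| > 1 | strict; per cluster (pseudobulk mode available) |
| enrichment filter | NES ≥ 7.5 | arg-max NES among kept rows; ties → lexicographically first set id, flagged |
| overrepresentation | binomial tail, Bonferroni | p0 = \|set ∩ background\|/\|background\|, p = P(X ≥ k), X ~ Bin(n, p0) |

The normalization behind the cluster aggregates and the pseudocount are not
dictated by the upstream procedure; both are configurable and recorded in
the output `parameters.json`. Clusters present in only one sample yield a
flagged row with a null ratio. The planted fold change in the synthetic
experiment is defined as the A-vs-B contrast, so the measured
`log2(mean_A/mean_B)` equals the planted value in expectation.

## Group statistics

The comparison chain is: Shapiro–Wilk normality per group (reported, never
used to switch the test), fixed-effects one-way ANOVA from explicit sums of
squares, and Tukey's multiple comparison with the Tukey–Kramer standard
error `sqrt(MS_within/2 · (1/n_i + 1/n_j))` for unbalanced groups, adjusted
p from the studentized-range distribution with k groups and N − k degrees of
freedom. Degenerate inputs are defined rather than undefined: identical
group means give F = 0, p = 1 (including the fully constant case); zero
within-group variance with unequal means gives F = ∞, p = 0; the Tukey table
is skipped when MS_within = 0. A Welch ANOVA is available behind a flag, off
by default.

Isogenic-control pooling merges each patient's control lines into one
comparator group before testing. Raw measurements are pooled by default;
a per-line-mean mode is available since "averaging together" is ambiguous
between the two.

## Synthetic data: what is emulated, what is not

Every generator is seeded, bit-reproducible, and returns a `SceneTruth`
carrying the planted values its downstream stage should recover.

- **Rosette scenes** (default 256² px at 0.5 µm): concentric-ellipse
  geometry, composited region intensities (background 20, body 100, ribbon
  300 AU by default; each pixel belongs to exactly one region, so noiseless
  region means are planted exactly), an optional linear illumination ramp,
  and additive Gaussian pixel noise clipped at zero. Ground-truth boundaries
  are 256-vertex polygons of the two ellipses.
- **Marker fields** (256² px at 1 µm): an affine background plane plus
  disk-shaped puncta of equal additive amplitude (default 200 AU, radius
  5 µm, 30 puncta), placed away from the border and from each other with a
  retry-then-fail policy.
- **Colocalization stacks** (64³ voxels): the target support is a union of
  random balls; each secondary channel receives exactly `round(f·|target|)`
  target voxels plus an equal number of disjoint voxels, so the planted
  overlap fraction is exact by construction (identical supports at f = 1,
  disjoint at f = 0). Supports render at 250 AU over a 5 AU background.
- **Count experiments**: negative-binomial counts (variance m + 0.1 m²) with
  lognormal per-gene base means clipped to [0.05, 50] counts, a mild
  per-cluster modulation, planted log2 fold changes (planted genes are
  floored at 0.5 base counts so the effect is detectable — the screen
  targets expressed genes), ~5 % mitochondrial genes, and named cells
  overwritten to violate exactly one QC rule each.

None of the generators model point-spread-function optics, shot noise,
spatially correlated noise, tissue autofluorescence, realistic organoid
histology, sequencing-read sampling, or ambient RNA. Passing tests therefore
demonstrate that the *numeric rules* are implemented correctly and recover
planted truth under idealized imaging and sampling noise — not that the
rules are robust to every artifact of real microscopy or scRNA-seq data.
The iid-Gaussian noise model is also what exposes the top-hat bias above;
real camera noise filtered by the optics is spatially correlated and would
reduce it.

## Statistical calibration

`organoidquant.calibration` runs the full chain — scene generation with a
planted ribbon intensity (between-rosette CV 10 %, per-pixel σ = 10 AU),
ribbon ROI reconstruction from the true luminal boundary, mean-intensity
measurement, one-way ANOVA across groups — on small scenes (64² px at
1.5 µm, 64-vertex boundaries, geometry jittered per rosette) so that
hundreds of runs finish in minutes. With three groups of 20 rosettes the
measured type-I error at α = 0.05 is ~5 % over 500 seeded runs, and power
for a 1.5× ribbon effect at p < 0.01 is ~100 % over 100 runs. The
acceptance script reports both rates at exactly these problem sizes.

## Numerical conventions

- Otsu thresholds always use a 256-bin histogram; foreground/supra-threshold
  sets use `>=` for Otsu (`>` for explicit fixed thresholds, so `fixed(0)`
  keeps all positive voxels).
- Physical parameters live in configuration in µm and are converted to
  pixels at the point of use; no pixel-unit parameters are exposed.
- All randomness flows through `numpy.random.default_rng` seeds; re-running
  any stage with the same configuration and seed reproduces CSV/JSON outputs
  byte-for-byte.
- ImageJ `.roi` support covers the stable polygon/freehand subset of the
  format (big-endian, 64-byte header, relative int16 vertices); CSV is the
  primary boundary interchange format.

## Known limitations

- The top-hat foreground mean is biased upward by a few percent under iid
  pixel noise (quantified above).
- Aspect-ratio accuracy degrades for rosettes only a few pixels across;
  morphometrics assume the rosette spans tens of pixels.
- The screen's DE selection is a fold-change cutoff on aggregate ratios; it
  is not a variance-modelled differential-expression test and inherits the
  pseudocount's attenuation of ratios for very lowly expressed genes.
- Welch ANOVA degrees of freedom are reported rounded to the nearest integer
  in the result record.
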