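# organoidquant

Quantification pipeline for cerebral-organoid immunofluorescence and a
single-cell expression screen, built for studies that measure Wnt/β-catenin
and tau-phosphorylation phenotypes in patient-derived organoids. It covers
five analysis stages, each driven by a seeded synthetic-data generator that
plants known ground truth:

1. **Rosette ROI quantification** — hand-drawn outer/inner boundary
   polylines (µm) become the **Body** (inter-boundary annulus eroded by
   1.8 µm) and **Ribbon** (luminal boundary dilated by 1.8 µm) masks;
   mean channel intensity per region, rosette area (pixel count of
   body ∪ ribbon) and aspect ratio (major/minor axis of the hole-filled
   outline) are reported.
2. **Marker quantification** — white top-hat background subtraction with a
   54 µm disk, then Otsu foreground and its mean intensity
   (`mean over {x : tophat(x) ≥ t_Otsu}`), for diffuse markers such as
   pTau S396 and Reelin.
3. **Colocalization** — thresholded colocalization volumes across channel
   pairs in 3D stacks: `TVC(A,B) = 100·|A∩B|/|A|` on per-channel Otsu (or
   fixed) supra-threshold supports.
4. **Expression screen** — per-cell QC (`nFeature`, `nCount`, `pct_mito`)
   with strict removal cutoffs (>8000, <200, >50000, >20 %), seeded 6,400-cell
   downsampling, cluster-aggregate `log2((mean_A+ε)/(mean_B+ε))` sample
   ratios, |log2 fc| > 1 DE selection, NES ≥ 7.5 cell-type assignment, and a
   binomial overrepresentation test with Bonferroni correction.
5. **Group statistics** — Shapiro–Wilk, one-way ANOVA
   (`F = MS_between/MS_within`), Tukey–Kramer post-hoc from the
   studentized-range distribution, with isogenic-control pooling per patient.

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.

## Worked example

Simulate a scene set and run every stage end to end:

```sh
organoidquant run-all --seed 7 --outdir demo
```

which writes, among other outputs, `demo/rosette-quant/rosette_measurements.csv`:

```
rosette_id,mean_body,mean_ribbon,area_um2,aspect_ratio
rosette_00,99.94468002858719,299.66241963704425,1845.0,1.2711103619527806
rosette_01,100.20265061244207,300.6405040553359,1845.0,1.2711103619527806
```

The generator planted body intensity 100 AU and ribbon intensity 300 AU with
pixel noise σ = 10; the measured means recover both to well under 1 %. The
area (1845 µm²) is the body-plus-ribbon pixel count for the default
30 × 24 µm outer / 9 × 7 µm lumen ellipse pair at 0.5 µm pixels, and the
aspect ratio reflects the 30/24 outer axis ratio (1.25; the measured 1.27
also sees the elliptical ribbon band).

The same stages are available programmatically:

```python
from organoidquant import (
    RosetteSceneParams, make_rosette_scene, BoundaryPolyline,
    build_rosette_roi, mean_roi_intensity, rosette_morphometrics,
)

channel, truth = make_rosette_scene(RosetteSceneParams(noise_sigma=10, seed=1))
roi = build_rosette_roi(
    BoundaryPolyline(truth.outer_polyline_um),
    BoundaryPolyline(truth.inner_polyline_um),
    channel.grid, channel,
)
print(mean_roi_intensity(channel, roi.ribbon_mask))   # ≈ 300
print(rosette_morphometrics(roi))                     # (area µm², aspect ratio)
```

Other subcommands: `simulate`, `rosette-quant`, `marker-quant`, `coloc`,
`screen`, `stats`; every stage writes a `parameters.json` snapshot and reruns
byte-identically for the same config and seed.

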