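# stromaquant

Quantification pipeline for 3D bioengineered airway-stroma tissues.

Tissue-engineered stroma models — fibroblast-seeded micro-tissues that fuse
into connective-tissue equivalents — are characterized by a recurring set of
measurements: how much collagen the cells deposited, how coarse and
disordered the fiber network is, how many cells are present and how much
matrix protein each produced, how large the micro-tissues grew, and how
stiff the resulting construct is.  When the same cells are also profiled by
RNA-seq in 2D and 3D, the transcriptomic readout ends in set logic: which
genes respond in either culture format, and whether their regulation is
concordant.  `stromaquant` implements this whole quantification stack as a
tested, reusable library with a thin CLI, together with synthetic-data
generators that emulate every input class with known ground truth, so that
each stage can be validated end to end without access to raw microscopy or
instrument data.

## What it computes

**Collagen fraction** (SHG images). Within a region of interest, after
thresholding (Otsu or fixed) and optional exclusion of scaffold pixels,

&nbsp;&nbsp;&nbsp;&nbsp;Collagen Fraction (%) = 100 · N_c / (N_c + N_b),

where N_c and N_b are bright (collagenous) and dark pixel counts.

**Texture correlation length** (GLCM). The gray-level co-occurrence
matrix correlation feature C(d) is computed for pixel offsets d = 1..100 in
the horizontal and vertical directions; C(d) for any offset is identically
the Pearson correlation of the quantized pixel pairs at that offset. The
directions are averaged and the decay is fit by C(d) = exp(−d/λ); the
correlation length λ grows with thicker, more disordered fiber bundles.

**Morphometry** (fluorescence and optical images). Nuclei are counted as
8-connected components of the thresholded DAPI channel above a minimum
area; protein-per-cell is the thresholded fluorescent area in µm² divided
by the nuclei count; micro-tissue diameter is the equivalent circular
diameter 2·√(A/π) of the largest object.

**Elastic modulus** (spherical nano-indentation). From a piezo
displacement / load record (z, P) with probe radius R and cantilever
stiffness k, the true depth is h = (z − z₀) − P/k after contact-point
detection. With contact radius a = √(R·h), the indentation stress and
strain are

&nbsp;&nbsp;&nbsp;&nbsp;σ_ind = P / (π a²), &nbsp;&nbsp; ε_ind = (4/3π) · (h/a) / (1 − ν²),

chosen so that σ_ind = E · ε_ind exactly reproduces the Hertz relation
P = (4/3)·E/(1−ν²)·√R·h^{3/2}.  E is the slope of a zero-intercept
least-squares fit of σ_ind on ε_ind.

**Transcriptome post-processing**. Genes are filtered out when they have
< 1 cpm in fewer than n_min samples *and* more than 20% multi-mapping
reads; differential expression calls use FDR < 0.05 with an optional
|logFC| cutoff; two contrasts are compared into a disjoint concordance
partition (dataset-specific up/down, common concordant up/down,
discordant).

**Group statistics**. One-way ANOVA with Tukey HSD post-hoc pairs
(Tukey–Kramer for unequal n), flagged at p < 0.05 and p < 0.01.

## Worked example

```python
from stromaquant.synthetic import FiberImageSpec, make_fiber_image, \
    IndentationSpec, make_indentation_curve
from stromaquant.morphometry import collagen_fraction
from stromaquant.texture import estimate_correlation_length
from stromaquant.indentation import elastic_modulus

# a thick, disordered fiber network imaged at 0.62 µm/px
img = make_fiber_image(FiberImageSpec(
    image_size=512, n_fibers=60, fiber_width=4.0,
    orientation_concentration=0.5, pixel_size=0.62, seed=0))
frac, roi = collagen_fraction(img, threshold=0.5)
fit = estimate_correlation_length(img, d_max=100, levels=64)
print(f"collagen fraction: {frac:.2f} %  (threshold {roi.threshold_used})")
print(f"correlation length: {fit.corr_length_px:.2f} px = {fit.corr_length_um:.2f} um")

# a 1.2 kPa sample indented with a 53.5 µm probe on a 4.53 N/m cantilever
curve = make_indentation_curve(IndentationSpec(
    true_modulus=1200.0, load_noise_sd=0.02, seed=3))
mfit = elastic_modulus(curve)
print(f"E = {mfit.E_pa:.1f} Pa  (pointwise {mfit.pointwise_mean_pa:.1f} "
      f"+/- {mfit.pointwise_sd_pa:.1f} Pa)")
```

prints

```
collagen fraction: 69.85 %  (threshold 0.5)
correlation length: 16.66 px = 10.33 um
E = 1200.0 Pa  (pointwise 1200.9 +/- 157.9 Pa)
```

69.85% of the region is collagenous at the half-peak threshold; the texture
decorrelates over ~17 px (≈10 µm at this calibration); and the modulus fit
recovers the generating 1.2 kPa to within a tenth of a percent despite 2%
load noise (the pointwise σ/ε ratio scatters, the fit does not).

The same operations are available from the shell, e.g.

```sh
stromaquant texture image.tif --dmax 100 --levels 64
stromaquant indent curve.csv --radius 53.5 --stiffness 4.53 --poisson 0.5
stromaquant deg-compare contrast2D.tsv contrast3D.tsv --fdr 0.05
stromaquant run config.yaml --out results/
```

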