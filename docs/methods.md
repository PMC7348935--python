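# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the measurement conventions
of the field leave room.

## Calibrated images

Images are 2D float64 intensity grids with a physical pixel size in µm/px.
Coordinates are 0-based (row, col); masks are pixel sets; areas are kept in
px² internally and converted by pixel_size² only at the reporting boundary.
On disk, images are single-channel unsigned 16-bit TIFF with an affine
intensity mapping and the pixel size recorded in a JSON sidecar.

## Thresholding

Bright/dark segmentation defaults to Otsu's method, with a fixed intensity
value as an override; the threshold actually applied is always returned and
logged, so any run can be reproduced exactly.  Otsu on a constant image is
degenerate and raises rather than guessing.  Pixels strictly above the cut
count as bright.  This convention makes the checkerboard case exact: a
two-level image thresholded between the levels yields exactly 50%.

## Collagen fraction

100·Nc/(Nc+Nb) over a region of interest, with an optional exclusion mask
(e.g. scaffold autofluorescence) subtracted from the ROI before counting.
The fraction is monotone non-increasing in a fixed threshold, and bright
and dark percentages always sum to 100 — both properties are tested.

## Nuclei counting and protein per cell

Nuclei are 8-connected components of the thresholded channel with area ≥
`min_area` (default 20 px², configurable) to suppress noise specks.
Touching nuclei merge into one component: no watershed separation is
attempted, because no separation rule survives thresholded binary masks
without shape priors, and the synthetic validation images are generated
non-overlapping.  Protein-per-cell is (bright pixels × pixel_size²) /
nuclei count; a zero cell count is an error, not an infinity.

## Micro-tissue diameter

The equivalent circular diameter 2·√(A/π) of the largest connected
component, appropriate for near-spherical micro-tissues; the maximum Feret
(caliper) diameter is available behind a flag for elongated objects.  The
measure scales exactly linearly with pixel size.

## GLCM correlation and correlation length

Intensities are linearly quantized to G = 64 levels by default (a
convention for 8-bit-class microscopy; G is configurable and recorded).
For an offset (dx, dy) the co-occurrence matrix counts all in-bounds
ordered pixel pairs; the symmetric variant (default) adds the reversed
pairs, which makes the correlation feature independent of the offset sign.
The correlation feature Σ(i−µᵢ)(j−µⱼ)p(i,j)/(σᵢσⱼ) is identically the
Pearson correlation of the quantized pair sample — the test suite verifies
this against brute-force pair enumeration to 1e−10, and the matrix
construction against an independent co-occurrence implementation.

Curves run d = 1..100 px in the horizontal and vertical directions (the
image must exceed the maximum offset; the error message reports the
largest usable d).  The two directions are averaged before fitting — a
single length per sample is wanted and averaging is the symmetric pooling
choice.  The decay is fit by nonlinear least squares with the model
C(d) = exp(−d/λ), amplitude fixed at 1, on the linear scale: large-d
correlations scatter around zero (and go slightly negative), which a log
transform cannot tolerate.  A fit pushed to the bound λ ≥ 10·d_max is
reported as non-decaying with no λ.

The default fitting path uses the raw (unnormalized) curve.  For a
decaying texture the d → 0 limit of the correlation is ≈ 1, so the
amplitude-1 model applies directly; dividing by the d = 1 value first
(the common plotting normalization, which is provided as an option) would
rescale the curve to exp(−(d−1)/λ) and bias λ upward when λ is only a few
pixels.  With the raw-curve convention, parameter recovery on synthetic
exponential-covariance fields is unbiased to within sampling error across
λ₀ = 5–50 px.

## Spherical nano-indentation

Defaults mirror a displacement-controlled fiber-optic nano-indenter with a
53.5 µm radius spherical tip on a 4.53 N/m cantilever, indenting ~10 µm
into kPa-scale soft tissue; the sample Poisson ratio defaults to 0.5
(incompressible soft tissue) and is configurable.  All computation is in
SI; the containers carry instrument units (µm, N, N/m), so expressing a
record in (µm, µN) vs (m, N) cannot change the fitted modulus.

*Contact detection.*  The baseline load statistics come from the first 5%
of samples; the rise is where the smoothed load first exceeds
mean + 5·SD (multiplier configurable).  That crossing is systematically
late — the load is already above the noise band there — so it is
back-extrapolated to zero load using the contact geometry: with
u = z − P/k the deflection-corrected travel, P^{2/3} is exactly linear in
u past contact for a Hertzian material, and the root of a least-squares
line through (u, P^{2/3}) over the clearly-loaded samples is the contact
offset.  This recovers the offset to machine precision on noiseless
records and keeps the median modulus error under 2% at 2% load noise.  A
record with no pre-contact baseline falls back to the first sample with a
warning; a record whose load never rises above the baseline band raises.

*Stress–strain and modulus.*  σ_ind = P/(πa²) and
ε_ind = (4/3π)(h/a)/(1−ν²) with a = √(R·h) make σ/ε constant and equal to
E for an ideal Hertz response — the unique stress/strain reading whose
ratio reproduces P = (4/3)·E/(1−ν²)·√R·h^{3/2}.  E is reported as the
slope of a zero-intercept least-squares fit of σ on ε, which uses the
whole depth record and is robust to load noise; the pointwise ratio
mean ± SD is reported alongside.  The shallowest 10% of the depth record
is excluded by default, where the relative error of the contact point
dominates h.  Both E and the reduced modulus E* = E/(1−ν²) are labelled in
the output.  Only the loading segment is analyzed; creep, adhesion and
substrate corrections are out of scope.  Replicate indentations (e.g. 5
points per sample) aggregate as mean ± SD over successful fits with the
failure count reported.

## Expression filter and concordance partition

cpm is count·10⁶/library-size.  A gene is removed when it is expressed
(cpm ≥ 1) in fewer than n_min samples AND its multi-mapping-read
percentage exceeds 20% — the conjunction reading of "simultaneously"; the
OR reading is available behind `require_both=False`.  n_min has no
universal default (it depends on the design) and must be supplied; the
smallest group size is the sensible choice.  The filter is idempotent.

DEG thresholding takes FDR < 0.05 with an optional |logFC| cutoff;
significant genes with logFC exactly 0 are flagged and assigned to
neither direction.  Comparing two contrasts yields seven disjoint sets —
specific up/down per dataset, common concordant up/down, and discordant
(significant in both with opposite signs) — whose union is exactly the
union of the two DEG sets.  All derived totals (dataset-specific, common)
are computed from the partition, never taken on faith from any external
tally: the common total is by construction the sum of concordant-up,
concordant-down and discordant counts.  Gene ids match after whitespace
and case normalization only; no alias resolution.

## Group statistics

One-way fixed-effects ANOVA from between/within sums of squares; pairwise
Tukey HSD p-values from the studentized-range distribution with the
Tukey–Kramer standard error for unequal n.  Two-group ANOVA reduces
exactly to the pooled t-test (F = t²), and every Tukey-adjusted p is at
least the corresponding pooled-variance unadjusted p — both identities are
tested.  All values identical across groups gives F = 0, p = 1; zero
within-group variance with differing means gives F = ∞, p = 0.

## Synthetic-data generators

Every generator is a pure function of its spec including the seed —
bit-identical reruns — and attaches its ground truth to the artifact so
validation never goes through the code under test.

- **Fiber images**: straight lines with Gaussian cross-section (σ =
  `fiber_width`), centers uniform, orientations von Mises (κ = 0
  isotropic/"chaotic", large κ aligned), additive Gaussian background
  noise.  The ground-truth mask marks pixels whose noiseless intensity
  exceeds half the single-fiber peak.  Real collagen is curvilinear,
  branched and imaged through nonlinear optics; straight fibers are
  deliberately simpler but suffice to control thickness and orientation
  disorder, which is what the texture ordering tests need.
- **Correlated fields**: Gaussian random fields with isotropic exponential
  covariance exp(−r/λ₀), synthesized spectrally (white noise filtered by
  √S with S(k) ∝ λ²(1+(kλ)²)^{−3/2}, the 2D Matérn-ν=½ density).  Spectral
  synthesis gives exact covariance control on a periodic grid; λ₀
  approaching half the grid is flagged unresolvable.  Defaults: 1024²
  grid, which resolves λ₀ up to ~50 px comfortably.
- **Nuclei images**: non-overlapping disks by rejection sampling with a
  1 px guard band; an unplaceable request is an explicit error, never
  silently fewer disks.
- **Indentation curves**: exact Hertz loads on a true-depth grid with
  piezo axis z = offset + h + P/k, pre-contact zero-load travel, and
  additive Gaussian load noise scaled to the maximum load.  Defaults:
  E = 1 kPa, ν = 0.5, R = 53.5 µm, k = 4.53 N/m, 10 µm depth, 600 samples.
- **DEG fixtures**: paired tables over a shared synthetic gene universe
  with prescribed category sizes; significant FDRs are drawn strictly
  below 0.05 and null FDRs at or above it (ranges crossing the threshold
  are rejected as ambiguous), logFC signs follow the category.  The
  partition of the emitted pair reproduces the prescribed sizes exactly.
- **Count matrices**: negative-binomial counts with log-uniform means, a
  silent-gene fraction, and uniform per-gene multi-mapping percentages.

What passing tests on these generators shows — and does not.  Recovery and
ordering results demonstrate that the estimators are unbiased and
correctly ordered *under the generating models*: stationary textures,
ideal Hertzian elasticity, disjoint nuclei, unambiguous DEG calls.  They
do not certify performance on real data with curved fibers, optical
blur, viscoelastic drift, clumped nuclei or borderline FDRs; those
effects are exactly what the configurable thresholds and fit ranges exist
for.

## Problem sizes and runtime

The validation sweeps use 1024² fields (10 seeds per λ₀), 512² fiber
images (10 matched pairs), 600-sample indentation records (20 noise seeds
per modulus), and 1000 random concordance fixtures — sizes at which every
estimate is stable while a full run of the suite plus the acceptance
script stays within a few minutes on one CPU.

## Known limitations

- GLCM curves are computed per direction on the raw grid; no rotational
  averaging beyond horizontal/vertical, matching common practice.
- The exponential decay model is the only fit offered; stretched
  exponentials or two-scale textures are out of scope.
- No watershed nuclei separation, no 3D stack support, no stain
  deconvolution.
- Unloading-segment (viscoelastic) analysis is not implemented.
- The DE model itself (dispersion estimation, GLM testing) is consumed,
  not re-fit; upstream read processing is out of scope.
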