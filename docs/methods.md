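# Methods

This note records the models, algorithms and design choices behind
`steatoquant`, including the points where the underlying analysis is a
convention rather than a measurement, and what validation on phantoms does
and does not establish about real slides.

## Imaging model and conventions

A slide is a registered pair of non-negative intensity rasters: SHG
(specific to fibrillar collagen) and TPEF (tissue autofluorescence from
NAD(P)H and flavins). Acquisition tiles are 512 × 512 px covering
200 × 200 µm², so the default pixel pitch is 200/512 ≈ 0.3906 µm; tiles
abut without overlap and are assembled row-major. On disk, 2-channel TIFFs
carry channels in the order (SHG, TPEF); pixel size is read from an
explicit argument, TIFF resolution tags (inch or centimeter units), or the
tile-geometry default, in that order. Pixel coordinates are 0-based
(row, col) and physical coordinates refer to pixel centers — this fixes
all centroid and diameter arithmetic. 8- and 16-bit integer input is
promoted to float32 so no threshold ever depends on detector bit depth.

Tissue foreground: pixels above a global Otsu threshold of the TPEF
histogram, then morphological closing (disk radius 2 px), hole filling
(so enclosed vacuoles count as tissue — they are tissue that lost its
fluorophores) and removal of components below 50 µm². The tissue area in
mm² is the denominator of every "% area" and "per mm²" readout.

## Detection

All thresholds are computed per image on a 256-bin histogram of the
min–max-scaled channel. The Otsu threshold is the level maximizing
between-class variance, ties resolved to the lowest level; this makes
detection invariant under any positive rescaling of the intensities.

Candidates are 8-connected components of below-threshold TPEF pixels
inside the tissue mask, hole-filled, with equivalent diameter in
[3, 200] µm (defaults; both configurable). Components touching the image
border are excluded: their truncated features would corrupt
classification. One guard exists beyond plain Otsu: real vacuoles are
fluorophore-free, so the dark class must be far darker than the
parenchyma. If the mean of below-threshold pixels exceeds 0.5× the
bright-class mean, the split is only carving texture out of a hole-free
background and detection returns nothing. Without this, any unimodal
background would be split in half and its darker patches reported as
candidates.

Per-candidate features (the classifier inputs, frozen in this order):
mean interior TPEF intensity; area (µm²); circularity 4πA/P², clamped to
≤ 1 because discrete perimeters can push it above 1 (perimeter is the
contour-weighted estimate of `skimage.measure.regionprops`); solidity
(area over convex-hull area), which serves as the compactness/"density"
feature separating smooth droplets from ragged lumens; length-to-width
ratio of the second-moment ellipse (minor axis floored at half a pixel for
degenerate thin shapes); and the SHG-positive fraction of a 5 µm-wide
annulus outside the candidate boundary, where SHG-positive means above a
global Otsu threshold of the SHG channel (a constant SHG channel yields
fraction 0). Mean interior intensity is used rather than a contrast
measure because the vacuole interior is the physically meaningful
signal-free region.

## Classification

The classifier is a CART binary tree: greedy recursive partitioning on
Gini impurity (1 − Σpᵢ²), thresholds at midpoints between consecutive
distinct sorted values, deterministic tie-breaks (lowest threshold, then
lowest feature index). Stopping: `max_depth` 5, `min_samples_leaf` 5, or
node purity; no pruning. Axis-aligned splits are invariant to monotone
per-feature rescaling, which is why no feature normalization is needed or
performed. Leaves predict their majority class with ties going to
`non_fat`, because a false fat call inflates all 45 downstream parameters
while a miss only loses one droplet. Models serialize to JSON with a
schema version and the feature name order embedded, so a model cannot be
silently applied to a mismatched feature layout.

Training labels come from phantom ground truth: a candidate is `fat` iff
its best-overlapping truth object is a fat vacuole with IoU ≥ 0.5. On real
data the same interface accepts expert-labeled ROI candidates.

## Region partition

The four histological regions are anatomically defined but no
per-pixel algorithm follows from the definition, so the partition here is
an explicit geometric interpretation, flagged as such:

* vessel calling: non-fat candidates with equivalent diameter ≥ 40 µm are
  vessel lumens; collagen-annulus fraction ≥ 0.3 → portal tract (collagen-
  walled), else central vein;
* pixels within 50 µm of a portal lumen → portal tract; within 50 µm of a
  central vein → central vein; remaining tissue within 10 µm of
  SHG-positive strands → perisinusoidal; the rest → lobular;
* priority portal > central > perisinusoidal > lobular resolves overlaps,
  which makes the labels a true partition of the tissue.

All radii and cutoffs are configurable. Each fat vacuole is assigned to
the region containing its centroid — unambiguous for droplets straddling
boundaries. Distances are Euclidean (exact distance transform).

## Quantification

The 45-parameter profile factorizes as 9 metrics × 5 contexts (overall +
four regions): % area, count, count/mm², mean and median equivalent
diameter, macrovesicular and microvesicular counts and % areas. The
factorization is a design choice that reproduces the canonical total of 45
and covers size/number/percentage per region; the names are frozen in the
output headers. Conventions:

* regional % area uses the region's own area as denominator (overall uses
  whole tissue), so regional values are local severities and do not sum to
  the overall value;
* a zero-area region reports NaN for all nine metrics — undefined, never a
  fake 0; diameters are NaN when the count is 0;
* macro/micro cut: equivalent diameter ≥ 15 µm is macrovesicular. The
  literature distinguishes the two classes without a standard numeric cut,
  so this is a configurable convention, not a measurement;
* grade: 0 below 5 %, 1 in [5, 33), 2 in [33, 66], 3 above 66 % steatotic
  area (the outer bounds are the standard grade definitions; 33/66 are the
  standard interior cuts);
* diameter distribution: 2 µm bins over [0, 100] µm by default, counts
  divided by tissue area; diameters beyond the last edge are counted in
  the last bin so the histogram always conserves the total count.

## Statistics

Group comparison uses the classical machinery (via scipy): one-way ANOVA
(F = MSB/MSW; degenerate zero-variance inputs return NaN when means are
equal, +inf otherwise, never a silent number), the two-sample
Kolmogorov–Smirnov test with asymptotic two-sided p-values for diameter
distributions, and correlation defaulting to Spearman rank (grades and
burden readouts are ordinal; Pearson by flag). `compare_cohort` emits a
tidy table (parameter × comparison × statistic × p × significance at
α = 0.05). No multiple-testing correction is applied by default; a Holm
step-down option exists.

## Phantom generator

The phantom renders what the pipeline assumes real slides look like:

* TPEF background: mean 150 (arbitrary units) modulated by a
  low-frequency multiplicative field (Gaussian-filtered noise, σ = 32 px,
  relative amplitude 6/150) plus additive Gaussian noise (σ = 10) —
  enough texture to make Otsu's histogram realistic;
* fat vacuoles: ellipses with axis ratio bounded so analytic circularity
  stays ≥ 0.97, interiors set to zero signal; diameters lognormal
  (median 12 µm, σ_log 0.4 by default) — a right-skewed law matching how
  droplet-size distributions present;
* vessels: larger radially-perturbed lumens (radius 20–40 µm), zero
  interior; a configurable fraction (default 0.5) are portal-type and
  receive a bright 6 µm SHG collagen ring, central-vein-type receive none
  — precisely the contrast that makes the collagen feature discriminative;
* nuclei: 4–8 µm disks keeping 25 % of the local background signal
  (chromatin is dim, not signal-free) — the feature that lets the tree
  separate nuclei from genuinely empty microvesicular droplets;
* SHG background: faint noise plus thin bright strands (~60 per mm²,
  1 µm thick, 30–100 µm long) kept clear of object annuli;
* defaults describe a 1024 × 1024 px (400 × 400 µm², a 2 × 2 tile mosaic)
  field with 50 droplets, 5 vessels and 200 nuclei — nuclei an order of
  magnitude more numerous than droplets, as in tissue.

Objects are placed by rejection sampling without overlap (small safety
margins; droplets placed largest-first so dense severe-steatosis specs
remain feasible); an infeasible spec raises an error rather than silently
truncating counts. Truth region labels are produced by the same distance
rules as the pipeline's partition, so region recovery is testable.
Identical (spec, seed) gives bit-identical phantoms; cohort generation
spawns per-sample seeds deterministically and supports per-group fat-count
scaling and median-diameter shifts.

What the phantom does **not** emulate: optics (PSF, depth sectioning,
shading), partial-volume boundary blur, droplet clumping/merging,
degenerated hepatocytes with intermediate signal, and staining appearance.
Consequently, passing phantom tests establishes the correctness of the
algorithmic chain (segmentation arithmetic, feature computation, tree
induction, bookkeeping, statistics) under the stated image model — it does
not establish classifier accuracy on real slides, where boundary blur and
confounder diversity will lower the near-perfect phantom figures.

## Validation sizes and numerical choices

Desk-scale validation uses: default phantoms for detection/classification
(train 10, test 3 in the test suite); a 20-phantom burden sweep from under
1 % to above 30 % steatotic area for % area recovery; a 2048² phantom with
500 droplets for diameter-distribution consistency (KS); a 3 × 5 cohort of
512² phantoms with fat burden doubling per timepoint for the trend ANOVA;
and 200 two-group null cohorts of 384² phantoms for type-I-error
calibration (the null check feeds truth burden values to the ANOVA,
isolating the statistic from detection cost). These sizes were chosen as
the smallest that make the respective statistics informative.

Numerical details worth knowing: Otsu ties go to the lowest level; CART
split ties go to the lowest threshold within 1e-12 of the best decrease
(guarding float-rounding in cumulative sums); circularity is clamped at 1;
single-pixel-thin shapes floor the minor axis at 0.5 px; NaN (not 0) marks
undefined readouts throughout.

## Known limitations

* The region partition is a geometric stand-in for true lobular anatomy;
  it does not tessellate lobules (no Voronoi of veins) and inherits any
  vessel-calling errors.
* Merged droplets are not split (no watershed); touching droplets count
  as one larger vacuole.
* Vessel-lumen candidates larger than the 200 µm diameter cap are ignored
  entirely.
* The macro/micro cut, the region radii and the portal collagen fraction
  are conventions; cross-study comparisons must hold them fixed.
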