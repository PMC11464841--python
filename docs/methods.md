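# Methods

This note documents the models and conventions behind `imccn`: what each
stage computes, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the choices made where the design
was genuinely open.

## Coordinate and data conventions

Pixels are pixel-centered, origin top-left, x rightwards (array columns),
y downwards (array rows), 0-based; arrays are indexed `[y, x]`. Images are
`(C, H, W)` stacks of nonnegative intensities in arbitrary ion-count
units. The cell table is a pandas DataFrame with a stable column order
(`cell_id, image_id, patient_id, group, x, y, area, raw_*, norm_*,
phenotype, cn`) that round-trips losslessly through CSV.

## Synthetic tissue and image model

The generator plants a tissue (`generate_tissue`) and renders it into an
observed image (`render_image`) with known ground truth, so every
downstream stage can be scored against planted labels.

**Geometry.** Cells are a filled nuclear disk (integer radius, default
3–5 px) plus a 1-px membrane annulus at radius `r + 3`. Arbitrary shapes
are a non-goal: disks and annuli exercise every downstream operator
(thresholding, connectivity, the membrane-distance rule, per-cell means)
while keeping the truth mask exact. Placement is rejection sampling under
a minimum center spacing (default `2·(r_max + halo) + 2`, which keeps
whole cells disjoint); exhausting the per-cell attempt cap raises an
error naming the constraint rather than silently truncating.

**Niches.** Each niche holds a proportion of the cells, a type palette,
and a spatial layout: `uniform` (scattered field-wide), `aggregate`
(Gaussian spread around one or more foci — a TLS- or vessel-like focus),
or `block` (a private vertical strip of the field — contiguous
compartments such as tumor vs. stroma). Niche counts follow
largest-remainder apportionment, so stated proportions are met exactly up
to rounding.

**Panel and noise.** A panel gives per-type mean expression for one
nuclear channel (disk only), membrane channels (annulus only) and lineage
channels (whole cell). The default panel is gating-grade: each type's
lineage marker is high (25 units) on its own type and low (0.5)
elsewhere, with DNA (40) and membrane (30) shared by all types. Three
degradations are applied in order:

1. *cell-to-cell heterogeneity* — each cell scales every channel mean by
   an independent log-normal factor (default CV 0.25, unit mean). Real
   marker intensities vary log-normally across cells in every channel;
   without this, within-type variation collapses onto the single
   dominant channel and clustering sees an unrealistic one-dimensional
   cloud;
2. *spillover* — observed = true · S per pixel, S the mixing matrix;
3. *counting noise* — Poisson counts on (signal + uniform background),
   IMC being a counting modality. `poisson_scale = 0` disables noise and
   background entirely, giving bit-exact planes for oracle tests.

What the generator does **not** emulate: irregular cell shapes, touching
or overlapping cells (unless spacing is relaxed), 3-D structure,
autofluorescence-like structured background, marker biology beyond the
near-binary palette, and isotope-specific spillover structure (the test
matrices are random diagonally dominant mixtures). Passing tests
therefore demonstrate that the algorithms are implemented correctly and
recover planted structure under the stated noise model — not that the
pipeline is robust to every artifact of real tissue.

## Preprocessing

Order is fixed: compensate → median filter → rescale.

- **Compensation** solves `t·S = o` per pixel as one vectorized linear
  solve (true-signal-in-rows convention) and clips negative solutions to
  zero; nonnegative least squares is available as a config switch.
  Channels are matched to the matrix by name; singular or
  near-singular matrices (condition number > 1e12) raise an unmixing
  error.
- **Median filter**: odd window, default 3×3, borders by edge
  replication; window 1 is the identity.
- **Rescale**: linear map of each plane's min→0 and max→255. A constant
  plane maps to all zeros by convention. Rescaling is per-channel
  (config-switchable); whether the original procedure rescaled globally
  is not stated, and per-channel matches how channels are inspected
  independently.

Quantification reads intensities from the **compensated, unfiltered**
image: the median filter and rescaling exist to stabilize thresholding
and are applied on the segmentation path only. Filtering before
averaging would bias per-cell means by cell size (the filter erodes thin
structures such as the membrane ring differently for small and large
cells).

## Segmentation

Nuclei: threshold (Otsu by default; the nuclear channel and any fixed
threshold are explicit configuration, never guessed), remove objects
below a minimum area, label connected components (8-connectivity by
default, 4 as option). Membrane fragments are assigned to the nucleus
with the nearest center (fragment centroid → nucleus centroid,
Euclidean); fragments farther than `max_dist = 15` px from every center
are discarded as artifacts; equidistant ties go to the lower label.
Touching nuclei are *not* split by default — incomplete separation of
adjacent cells is a known limitation of the modality at ~1 µm
resolution — but a distance-transform watershed is available
(`split_touching=True`).

## Quantification and normalization

Per-cell features are means over the cell's mask pixels. Normalization
divides each channel by its 99th percentile (linear interpolation between
order statistics — results depend on this definition), computed per image
by default (ROIs are scanned separately; per-patient pooling is a config
option), with values above 1 clipped by default. A channel whose
percentile is zero is left at zero with a warning. The percentile is
computed on cell-level means, not pixels.

## Phenotype clustering

A kNN graph (k = 100, Euclidean, on all normalized channels) is
symmetrized by union and weighted by the Jaccard overlap of neighbor
sets; zero-overlap edges are dropped. For n ≤ 8192 cells the neighbor
search is exact with ties broken by cell index (deterministic for
duplicate points); larger tables use a tree-based search. Leiden
modularity (RB configuration null) partitions the graph; the resolution
defaults to 1.0 and is exposed, and the community seed makes runs
reproducible. Rows are sorted by (image, cell) before clustering, so
labels are invariant to table row order. The cluster count is emergent —
it is never forced to any particular number. Note that on *spatially*
coherent low-dimensional blobs, modularity at resolution 1 legitimately
subdivides large communities; planted-partition recovery tests therefore
run at a coarse resolution, where separated blobs (disconnected graph
components) can never merge.

Batch alignment is a deliberately simple, off-by-default location
adjustment (per batch and channel: subtract batch mean, add global mean),
not a mutual-nearest-neighbor or mixture-model correction.

## Cellular neighborhoods

"The 20 closest cells" is resolved as center + 20 neighbors = a 21-cell
window (switchable); windows are computed within each image only, since
ROIs are disjoint tissue scans, and distance ties break by cell index.
Window composition vectors (fractions over the T cell types) are
K-means-clustered with k-means++ initialization and a fixed seed;
centroids are recomputed as empirical member means, so they are exact
probability vectors, and empty clusters (possible under degenerate
identical compositions) are compacted to a contiguous label range rather
than re-seeded. The default k = 15 follows the analysis convention;
planted-niche recovery experiments use k equal to the planted niche
count, which is the parameter-recovery question. CN assignment depends
only on pairwise distances, hence is invariant under rigid motions of
the coordinates.

The Voronoi map mirrors each point across the four field edges before
tessellating, which makes every region finite, then clips to the field
box; fewer than three cells or collinear cells raise an error suggesting
a scatter plot instead.

## Interaction testing

The statistic for an ordered type pair (A, B) is the mean number of
type-B neighbors per type-A cell under an explicit neighbor rule (fixed
radius or the CN windows). The null shuffles type labels within each
image, keeping positions and hence the neighbor graph fixed — never
across images or patients, because tissue composition differs per ROI.
Enrichment and avoidance p-values are the two tails of the same null
sample with the +1 correction, `p = (1 + #{null ⋛ obs}) / (1 + n_perm)`,
so p is never exactly 0 and the smallest attainable p at n_perm = 199 is
1/200. Types absent from an image are reported as missing (NaN) for that
image, not as zero. Benjamini-Hochberg-adjusted matrices are offered
alongside raw p-values. Group-level summaries stop at per-patient
CN × type count tensors, their marginals and per-group mean compositions.

## Trial endpoints

Clopper-Pearson bounds come from Beta quantiles
(`lower = B(α/2; s, n−s+1)`, `upper = B(1−α/2; s+1, n−s)`), with the
boundary conventions lower = 0 at s = 0 and upper = 1 at s = n; the
test-suite oracle inverts the binomial tail probabilities by bisection
instead, and the two agree to 1e−6. The exact method is conservative:
its coverage, computed exactly by summing the binomial pmf over covering
counts, is ≥ nominal at every (p, n) checked. ORR counts CR+PR, DCR
counts CR+PR+SD; percentages are reported to one decimal. The
Kaplan-Meier estimator is fit via lifelines; the median is read as the
earliest time with S(t) ≤ 0.5 and "not reached" when the curve never
crosses 0.5. Sample size defaults to the unpooled normal-approximation
formula (which reproduces the published design of 35 + 10% dropout → 39);
an exact-binomial power search is provided as a cross-check mode and is
typically slightly larger.

## Validation experiment sizes

The reproduction script and acceptance tests use: 50 noise-free cells
for exact segmentation recovery; 30 cells for the compensation
round-trip; a 2,000-cell, 1250² px image with two block compartments of
partially overlapping palettes for phenotype (k = 100) and CN (w = 20,
k = 2) recovery; and 2,400 replicates of 300 uniformly scattered cells
(radius-20 rule, n_perm = 199) for type-I calibration. The replicate
count is sized to the quantity being estimated: the test's true level
under this null is ~0.040 (the +1 correction caps it at 0.045 and ties
on the lattice-valued statistic take it slightly lower), so the binomial
standard error must be a few thousandths for the measured rate to
reflect the level rather than replicate noise. These sizes keep each
experiment between seconds and about half a minute on one CPU while
leaving the measured properties stable across seeds. CN recovery is scored with
planted type labels (stage isolation); phenotype recovery is scored
against the planted types through the ground-truth mask.

## Known limitations

- No watershed by default means merged labels for genuinely touching
  cells; the synthetic spacing avoids this, real tissue will not.
- Per-pixel linear unmixing can clip to zero under heavy noise; NNLS is
  slower and only pairwise-tested against the linear path.
- The permutation test's p-values are discrete; at small n_perm the
  attainable significance levels are coarse (at n_perm = 199, nothing
  below 0.005, and a test at α = 0.05 effectively operates at 0.045).
- The batch-centering hook aligns locations only; scale or nonlinear
  batch effects pass through.
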