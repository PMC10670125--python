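# Methods

This note documents the models and procedures implemented in `histovasc`,
the parameters that matter, the design decisions taken where the problem was
genuinely open, and what validation on the synthetic phantom does and does
not demonstrate.

## Input model and coordinate conventions

The pipeline operates on an ordered stack of RGB rasters of serial
histological sections. Physical scale enters through two numbers: the
in-plane pixel size (default 0.5 µm) and the slice thickness (default
2.5 µm), giving a 5:1 axial anisotropy. All coordinates are (x, y) with
pixel centers at integer positions, origin at the top-left pixel, x
rightward, y downward, 0-based; volumes are indexed (z, y, x). A single
convention end to end avoids half-pixel drift between registration,
segmentation and reconstruction.

## Preprocessing

Background whitening classifies a pixel as non-tissue when its minimum RGB
channel is at least `background_threshold` (default 0.88) of full intensity
*and* it is 8-connected to the image border. The border-connectivity clause
is essential: vessel lumina are also near-white but lie inside tissue, and
they are the primary segmentation signal, so a global threshold would
destroy them. Tissue fragments in the background smaller than
`min_tissue_component_px` (default 64) are whitened as debris. The operation
is idempotent.

The white margin is read as 12.5% of each dimension added on *each* side
(total growth 25% per axis), so a rotation of the tissue block cannot push
content out of frame. The margin choice is symmetric because rotation loss
is symmetric.

## Pairwise similarity estimation

The transform between consecutive slices is modeled as a similarity
(rotation, isotropic scale, translation, optional reflection — slices can be
flipped during mounting), optionally composed with a free-form deformation.

The similarity is estimated by multi-resolution optimization with three
specific choices that the data forced:

* **Metric: mean squared difference of gradient magnitudes**, not of
  intensities. The images are dominated by large uniform regions (white
  margin and background, homogeneous tissue); a plain intensity MSE is
  mostly insensitive to pose within those regions and, empirically on
  phantoms, can prefer a visibly wrong pose at reduced resolution. The
  alignment information lives in edges (vessel walls, tissue boundary), and
  the gradient metric ranks poses by how well those edges coincide.
* **Translation initialization by tissue centroids.** For each candidate
  rotation on a coarse grid (±20° in 2° steps, with and without reflection),
  the translation is initialized from the shift between the tissue
  centroids of the fixed and the rotated moving image. Phase correlation is
  the fallback when either image has no detectable tissue; on mostly-white
  frames it otherwise locks onto the static margin instead of the tissue.
* **Deferred basin commitment.** The gradient metric still has local minima
  where distinct vessels overlap under a wrong pose, and the wrong basin can
  score *better* at coarse resolution. The top `multi_start` (default 3)
  coarse candidates with distinct rotations are therefore each refined by a
  Powell search at the coarsest pyramid level (default scale 0.25), the two
  best survivors are re-refined at the finest level (default 0.5), and the
  winner is chosen by the finest-level score. Optimizer parameters are
  scaled to comparable magnitudes (degrees, 100·log scale, pixels).

If the final pose does not beat the identity map, the identity is returned
flagged `low_confidence` rather than a worse-than-nothing estimate.

On phantom pairs with known similarity misalignment (≤10°, ≤20 px, ±2%
scale) this recovers the pose to ≈0.1–0.3 px mean landmark error at 512 px
slice size, a few seconds per pair on one CPU.

## Elastic refinement

Sectioning also deforms tissue locally. The elastic stage estimates a
residual displacement field on a coarse control-point lattice (default
spacing 64 px at the working resolution of 0.25): per node, a local phase
correlation between the similarity-warped moving patch and the fixed patch;
the field is Gaussian-smoothed across the lattice, displacements above half
the lattice spacing are rejected as mismatches, and the whole deformation is
kept only when it improves the intensity metric by at least `elastic_margin`
(default 5%, relative). This is deliberately a lightweight stand-in with the
same contract as a full B-spline registration energy: coarse lattice, smooth
field, rejection when it does not help. Deformations are applied as forward
displacements in the target frame and inverted by fixed-point iteration
(displacements are small and smooth by construction; 8 iterations reach
well below 0.01 px).

## Two-step stack registration

Step 1 estimates all consecutive-pair transforms; each is an independent
task and its result is serialized to JSON. Step 2 composes, for every slice
i, the chain i → i−1 → … → 0; compositions are again independent. Slice 0 is
the untransformed reference frame. Similarity parts compose exactly (matrix
products); deformations compose by resampling the chained point map on a
lattice and storing the residual against the composed similarity. A failed
pairwise estimate degrades to an identity stand-in with a warning so the
chain beyond it remains usable. Results are bitwise independent of the
worker count because every task is a pure function and results are reduced
in slice order.

Chained composition accumulates a slow random-walk drift (≈0.1–0.3 px per
pair), which is the dominant registration error over long stacks; on a
50-slice phantom the slice-49 landmark error stays below ≈4 px.

## Segmentation

Preparation: grayscale, CLAHE (clip 0.01, tile 64 px), median filter
(5 px). CLAHE homogenizes staining intensity across the slide; the median
filter suppresses cell-nucleus speckle that would otherwise litter the
contour threshold.

(i) *Interiors*: fixed cutoff at 82.35% intensity on the prepared image,
one value for the whole stack (the preprocessing makes slices comparable).
`otsu_cutoff` recomputes the value from a reference slice for new datasets;
on a bimodal image it attains the exhaustive-scan maximum of the
between-class variance.

(ii) *Contours*: per tile (256 px), pixels at or below μ − x·σ of the
tile's *tissue* pixels, with x = 2.0. Two deliberate choices: the sign is
negative because vessel walls are darker than surrounding tissue (the
threshold form μ + x·σ is kept in `local_cutoff` with signed x); and white
background pixels (≥0.95) are excluded from the statistics and can never be
contours — in border tiles dominated by white, σ collapses and a relative
threshold would otherwise mark faint interpolation ramps along the tissue
boundary as vessels, which then persist across slices and survive every
consistency filter. x, the tile size and the despeckle window are the
method's empirical constants; they were calibrated once on the default
phantom and are exposed in the configuration.

(iii) *Cleanup*: the despeckle rule deletes every 8-connected component
whose bounding box fits in n×n (n = 9; with vessels down to 5 px radius a
larger window provably deletes real vessels, and small lumina lost here are
recovered through their contours at fusion). The contour-support rule
dilates contours by 5 px (Euclidean disk via distance transform) and keeps
an interior only if at least 45% of its Moore–Neighbor-traced boundary
pixels (Jacob's stopping criterion; 8-connected trace, deduplicated) lie in
the dilated contour. Temporal consistency matches components across the
three co-registered neighboring slices by centroid distance (≤10 px) plus
nonzero overlap after the centroid shift: center components with no match in
either neighbor are removed; structures matched between both neighbors but
missing in the center are inserted as the intersection of the neighbor
components after aligning their centroids to the mean position, which makes
the rule symmetric under reversing the window. The window generalizes to
any odd span s (keep needs ≥1 match; insertion needs presence in
⌈(s−1)/2⌉+1 neighbors); the first and last slices use one-sided keep-only
windows.

(iv) *Fusion*: pixelwise union of surviving interiors and contours, with
provenance retained for overlay rendering (interiors blue, contours black,
discarded red).

(v) *Gap closing and filling*: iterative rounds of morphological closing
(Euclidean-disk dilation/erosion implemented by distance-transform
thresholding, O(n) regardless of radius) followed by hole filling. Each
round, every newly enclosed region larger than the area of the biggest
vessel interior in the slice is rejected and reverted; closing residue
("necks") is accepted only where it touches an accepted fill, because a neck
that encloses nothing closes no contour — it only welds separate structures
together, which was the main cause of spuriously merged vessels. The disk
radius starts at 5 px and doubles per round until the first rejection, then
grows by 5 px per round (the chosen reading of an ambiguous escalation
rule), capped at 6 rounds. A final density-adaptive pass closes residual
gaps per tile with a radius that shrinks to zero as the tile's vessel
density approaches 0.5, preventing clustering in vessel-dense regions.

## 3D reconstruction

The registered masks are stacked into a voxel grid. Gap interpolation sets
every unset voxel with ≥15 set voxels in its 3×3×10 (x, y, z) neighborhood —
a single pass over the input volume, so decisions never cascade. The even
z-extent is centered as offsets −5..+4; neighbor counts exclude the examined
voxel; neighborhoods are clipped at the volume boundary with unchanged
thresholds (for counting set voxels, zero padding and clipping are
identical). Consistency pruning discards voxels of the *original* stack with
fewer than 10 set voxels in their 3×3×3 original-stack neighborhood.
Pruning deliberately re-checks the original voxels rather than the
interpolated volume: interpolated voxels already required 15 supporting
voxels, and pruning them against the original would undo every bridged
z-gap of more than one slice (a gap voxel has at most 9 original
neighbors). Both rules are verified against exhaustive brute-force
neighbor-count oracles, including the exact 14/15 and 9/10 boundary cases.
Finally an anisotropic Gaussian (σ = 0.8 voxels axially, 1.5 in-plane)
plus a 0.5 threshold smooths the surface; the defaults keep a flat
interface within half a voxel and change a ball's volume by under 10%.

Network statistics: vessels are 26-connected components with at least
`min_component_vox` voxels (default 300 — the smallest phantom vessel, 5 px
radius over a handful of slices, exceeds 1000 voxels, while surviving debris
stays far below); per-vessel diameters are inscribed-circle diameters,
2 × max(EDT) per 2D cross-section and slice × in-plane spacing, reported as
per-vessel minimum and median (exact for tubes, unlike raw medial-axis
sampling whose discretization spokes bias the median low); the axial extent
is n_slices × slice thickness (169 slices × 2.5 µm = 422.5 µm).

## The phantom

The generator emulates what the pipeline actually consumes: smooth vessel
tubes spanning the z-range (lateral random-walk centerlines, Gaussian
smoothed; radii uniform in 5–30 px; optional branches), rendered per slice
as a bright near-white lumen inside a dark wall ring (3 px) over pinkish
tissue with Gaussian noise and dark nucleus speckles, the tissue block
sitting inside a white slide border (12.5% of the in-plane size). The border
matters: a real slide shows the whole tissue piece surrounded by background,
so no tissue edge is pinned to the image frame; rendering without it creates
a stationary clipping edge shared by all slices that anchors any area metric
toward the identity pose. Each slice then receives a random similarity
misalignment (slice 0 stays the identity anchor so the registered frame
coincides with the ground-truth frame), and damage artifacts are injected at
a Poisson rate per slice: dark fissure polylines 1–3 px wide (slicing tears)
and white dropout patches (lost tissue) — the two failure classes the
cleanup heuristics target. Ground truth records per-slice vessel and lumen
masks in both the reference and the misaligned frames, the 3D truth volume
(whose z-slices equal the reference-frame masks by construction), the true
transforms, a landmark grid with exact correspondences, and artifact masks.
Everything is a deterministic function of (seed, config).

Default test scale: 50 slices of 512×512 px, 8 vessels (criteria use 10),
misalignment up to 5° / 10 px / ±2% scale, no artifacts unless enabled.
These sizes exercise every rule — including the 10-voxel z-reach — in
minutes on one CPU.

What phantom validation shows: that the implemented rules recover known
geometry through realistic misalignment, noise, speckle and damage, with
exact end-to-end ground truth. What it does not show: performance under real
staining variability (the phantom has one staining palette), real elastic
tissue deformation (test warps are low-frequency sinusoids ≤5 px), collapsed
vessels without lumina, or out-of-plane vessel geometry effects (tube
cross-sections are rendered as discs).

## Numerical and degenerate-input choices

Component connectivity is 8-connected in 2D and 26-connected in 3D
throughout. Medians use the midpoint-of-two rule for even counts.
Robustness counts strictly improved landmarks (ties are not improvements),
so an identity registration scores 0. An empty landmark set, empty slice
stack, zero image diagonal or non-contiguous transform chain raise errors
rather than returning defaults. All masks are strictly boolean end to end;
warping uses bilinear interpolation with white fill for intensity images and
nearest-neighbor with zero fill for masks. A slice pair whose registration
fails contributes an identity transform flagged `low_confidence` plus a
warning, and the chain continues.

## Known limitations

* Chain composition accumulates drift with stack length; there is no global
  (groupwise) correction pass, by design of the two-step scheme.
* The elastic stage is block matching with smoothing, not an energy-minimal
  B-spline registration; strong local deformation beyond the lattice scale
  is out of reach.
* The gap-closing neck rule cannot distinguish a true anastomosis from two
  abutting vessels; vessels closer than the closing radius with a shared
  enclosed region may still merge.
* Diameter statistics assume approximately tubular cross-sections; highly
  eccentric or collapsed vessels are summarized by their inscribed circle.
* Reflection handling assumes a whole-slice flip; locally folded tissue is
  not modeled.
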