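# Methods

## The measurement

`rootvoi` quantifies periodontal bone as the bone volume fraction (BV/TV)
inside a standardized shell volume of interest (VOI) around the roots of a
first molar in micro-CT scans. The procedure is:

1. **Segmentation.** The scan is smoothed with an iterated 3×3×3 median
   filter (default 3 passes, edge replication), turned into a
   gradient-magnitude landscape with the 3D Sobel operator, and partitioned
   by a marker-controlled watershed: operator-placed seed voxels for *air*,
   *bone* and *tooth* grow over the gradient landscape until the fronts
   meet on the gradient ridges at tissue interfaces. Every voxel receives
   exactly one label; there are no watershed-line voxels.
2. **Alignment.** A plane is fitted to ≥3 manually picked points on the
   cementoenamel junction (CEJ) by principal component analysis (the normal
   is the direction of smallest variance; with exactly three points this is
   the cross-product plane). The minimal rotation taking the normal onto
   the z axis is applied to the label map about the CEJ centroid, so the
   CEJ plane becomes z = 0 with the apical direction +z. Labels are
   resampled with nearest-neighbor interpolation onto an enlarged grid.
3. **Shell VOI.** The tooth is cut 30 voxels apical of the CEJ plane
   (half-open: the crop slice itself is excluded), root canals are filled
   in 3D after capping the cut face with a one-slice plate (canals opening
   onto the cut would otherwise count as border-connected background), the
   filled roots are grown by 100 µm using the exact Euclidean distance
   transform, and the original roots are subtracted. The result is a
   100 µm-thick shell following the root surface.
4. **Morphometry.** BV/TV = bone-labeled voxels / non-tooth voxels inside
   the shell. Voxels of an adjacent tooth that fall inside the shell are
   excluded from the reference volume (and reported separately) rather
   than counted as missing bone.
5. **Statistics.** Repeatability of repeated analyses is summarized by
   ICC(2,1) (two-way random effects, absolute agreement, single
   measurement — appropriate because each repeat is a full re-execution of
   the procedure); paired side comparisons use Bland–Altman limits of
   agreement (mean ± 1.96 SD of differences; the "critical difference" is
   the repeatability coefficient 1.96 SD) and the exact Wilcoxon
   signed-rank test.

## Deterministic watershed

The watershed is a priority flood: a *claim* is a (voxel, label) pair;
claims pop in ascending order of (gradient value at the claimed voxel,
claim insertion order), the voxel goes to the first claim popped, and
claims for unlabeled 6-neighbors are inserted in the fixed order
(−i, +i, −j, +j, −k, +k). Seed voxels keep their label; their claims are
emitted first, sorted by (label, raster position). The rule is fully
deterministic, which makes the whole analysis path bit-reproducible —
repeating a run on identical inputs gives the identical BV/TV, so the
triplicate ICC isolates operator input variation (seed and CEJ placement)
rather than code variation.

Insertion order, not label id, breaks gradient-value ties. A label-first
rule hands every symmetric ridge plateau to the smallest label id; since
air sorts first, that erodes bone and tooth by up to a voxel along every
blurred interface and biases BV/TV low by several points. With
insertion-order ties, two fronts approaching a symmetric two-voxel ridge
plateau each take their own side.

The flood is implemented as a numba kernel with an explicit binary heap
(the heap holds up to 6 claims per voxel). A plain-Python `heapq`
implementation of the same contract serves as the independent oracle in
the tests; on random grids, including integer-valued plateau-rich ones,
the two agree voxel for voxel.

## Alignment numerics

`apply_transform` resamples labels with `scipy.ndimage.affine_transform`
(order 0). Two guards keep exact cases exact: the output bounding box is
snapped against floating-point contamination (an identity rotation plus
integer-voxel translation resamples bit-exactly), and non-integer
resampling offsets are nudged by 10⁻⁴ voxel so that exact half-voxel
coordinates — which arise whenever a centered structure on an even grid is
aligned — round uniformly instead of by the interpolator's half-way
convention. The in-plane (about-z) orientation after alignment is left
arbitrary: the shell VOI and BV/TV are invariant to it.

The CEJ normal's sign is chosen so the tooth's larger extent from the
plane lies at +z. The root side extends much farther from the CEJ than
the crown, so this is robust even when the crown carries more volume than
the tapered roots (a center-of-mass rule fails exactly there).

## The phantom

Because no scans ship with the package, a synthetic quadrant generator
provides ground-truthed inputs for every stage:

* **Tooth**: crown cylinder with an enclosed pulp chamber, a short root
  trunk, and three tapered roots (mesial at +x, two more at ±120°), each
  carrying an open canal that joins the chamber coronally and ends short
  of the apex.
* **Periodontal ligament**: a 40 µm air-intensity gap around the tooth
  apical of the CEJ.
* **Bone**: a correlated Gaussian random field (default correlation length
  120 µm, murine trabecular scale) thresholded to an exact foreground
  fraction. The threshold is calibrated inside the peri-root measurement
  sleeve (40–100 µm from the root, below the crop plane) and extended
  outward, so the bone fraction where BV/TV is measured tracks the
  requested target instead of drifting with the texture realization —
  essential for simulation studies whose per-animal fractions are drawn
  from stated distributions. Pores and bone islets smaller than 150 voxels
  are absorbed: a real reconstruction cannot carry structures below the
  scanner's resolving power.
* **Intensities**: per-tissue means (air 20, bone 100, dentin 140,
  arbitrary units) with small voxel noise (σ≈3–5), plus a smooth
  within-tissue heterogeneity field (amplitude 18, correlation 150 µm) on
  the calcified tissues emulating mineralization gradients. The
  heterogeneity makes the bone and dentin histograms overlap — a global
  threshold misclassifies >5% of calcified voxels — while local edges stay
  crisp, which is precisely the regime where seeded watershed outperforms
  thresholding. A Gaussian blur of σ = 4 µm stands in for the scanner PSF
  of a sharp high-resolution reconstruction, followed by additive noise.
* **Seeds and CEJ points**: seeds emulate liberal manual marking — a
  stride-4 lattice of interior voxels (≥2 voxels deep) per tissue plus the
  deepest voxel of every connected component (so enclosed marrow pockets
  are always marked). Twelve CEJ points sit on the crown/root junction
  ring with sub-voxel scatter (≤1 voxel) to exercise the least-squares
  plane fit. Sparse seeding (one point per tissue) provably fails here:
  zero-gradient pockets beyond narrow throats, e.g. across the ~4-voxel
  PDL, are then captured by the surrounding label.

Ground truth (label map, filled root mask, shell, BV/TV) is computed by
running the package's own VOI contract on the true labels, so truth and
measurement share definitions by construction.

What the phantom does **not** model: scanner physics (beam hardening,
rings, cone-beam artifacts), cortical/trabecular compartments, anatomical
root curvature, lamina dura densification, and anisotropic trabecular
orientation. Passing tests therefore demonstrate the correctness and
stability of the *procedure*, not segmentation performance on arbitrary
real scans.

## Accuracy of the full pipeline

On noise-free, blur-free phantoms the segmentation reproduces the truth
everywhere outside a one-voxel interface band, and the deterministic
geometry tail (alignment → crop → fill → dilate → count) reproduces the
true BV/TV bit-exactly. Under the default imaging model at 10.4 µm voxels
(128³ grid), tooth and bone Dice exceed 0.95 and the measured BV/TV lies
within 0.02 of truth. The residual deficit (≈ −0.015) is a real property
of the protocol, dominated by the median filter's curvature-flow erosion
of convex structures (roots, trabeculae) at this resolution; it shrinks as
structures grow relative to the voxel and is common-mode in paired
designs.

## Simulation studies and problem sizes

The split-mouth emulation draws per-animal control fractions from
N(0.4133, 0.0491) and test fractions from N(0.3323, 0.0574), renders both
quadrants (left = mirrored geometry), runs the full pipeline per side and
applies the exact Wilcoxon test to the paired BV/TV values. Power
experiments repeat this over seeds and report the detection rate at
α = 0.05.

Simulation studies run on a reduced grid chosen as the package's standard
simulation size: 56³ voxels at 17.8 µm — the same ~1 mm physical quadrant
at half resolution — with the crop offset at 18 voxels (320 µm, matching
the full-resolution 30 × 10.4 µm = 312 µm) and CEJ scatter kept at
~10 µm. At this size one full study (14 animals × 2 sides) takes ~15 s,
and the per-site measurement error (σ ≈ 0.013 after the common-mode bias)
is small against the between-animal spread, so the detection rate is
governed by the stated biological distributions. Accuracy-oriented checks
use the full 128³ resolution instead.

## Numerical conventions and edge cases

* Voxel indices are 0-based; physical coordinate = origin + index × voxel
  size (µm) at voxel centers; axis 2 is z. Only isotropic volumes are
  accepted — anisotropic headers are a hard error, never a silent
  resample.
* Dilation uses the exact Euclidean distance transform, not an iterated
  structuring element, so a 100 µm radius needs no rounding to a whole
  voxel count; a 9.615-voxel ball at 10.4 µm means exactly the lattice
  points within 100 µm.
* The crop is half-open (root starts at CEJ index + offset; the crop
  slice is excluded).
* Wilcoxon: zero differences are discarded (classical convention), tied
  absolute differences get mid-ranks, and the exact null distribution of
  W⁺ is built by convolution over doubled ranks for n ≤ 25; above that a
  normal approximation with tie correction (no continuity correction) is
  used. The reported statistic is W⁺.
* ICC(2,1) comes from the two-way ANOVA mean squares with tiny-residual
  clamping so identical repeats give exactly 1.0; ICC(3,1) (consistency)
  is available for comparison and the form id is recorded in every report.
* All randomness lives in the phantom generator and the simulation
  drivers, each seeded explicitly; the analysis path is deterministic.

## Known limitations

* The BV/TV deficit from median-filter erosion (above) is inherent to the
  protocol at ~10 µm voxels; absolute BV/TV values carry it, paired
  comparisons largely cancel it.
* Watershed assignment of the single ambiguous partial-volume voxel at
  each interface cannot be made exact by any deterministic tie rule; on
  curved interfaces this contributes a small air-ward bias.
* The contralateral "left = mirror of right" identity is exact for truth
  masks; the measured BV/TV of a mirrored scan can differ in the last few
  digits because floating-point convolution is not bit-mirror-symmetric.
* Per-root (mesial/distal/palatal) sub-VOIs and additional morphometric
  indices (trabecular thickness/separation, BMD) are out of scope.
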