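# Methods

`mfnorm` implements a two-stage *functional* normalization for multi-subject
fMRI: a single functional template (FT) is fused from several intrinsic
network (IN) spatial maps, each subject's fused network image is registered
to that template, and the estimated warp is applied to the subject's task
data. The package also carries the statistics used to judge whether such a
normalization helps: activation t-maps with FDR and region tables, spatial
correlation to a group mean, functional network connectivity (FNC) group
tests, and two classifiers run under a repeated random-split protocol.

## Morphological wavelet (analysis / synthesis)

Each 2-D slice (even dimensions; odd axes are replicate-padded by one
row/column and cropped on synthesis) is divided into disjoint 2×2 blocks.
Analysis stores, per block,

```
M  = max{X(r,c), X(r,c+1), X(r+1,c), X(r+1,c+1)}         (approximation)
yv = |M − X(r,c+1)|,  yh = |M − X(r+1,c)|,  yd = |M − X(r+1,c+1)|
```

The band names ("vertical" for the horizontal neighbour, etc.) are kept as
conventionally printed rather than reinterpreted. Because the approximation
is the block maximum, the sign branch of the detail definition is
unreachable; the code asserts rather than assumes this. Synthesis places `M`
at all four positions and subtracts the detail gaps:

```
X'(r,c)     = M + min(yv, yh, yd, 0)
X'(r,c+1)   = M − yv ;  X'(r+1,c) = M − yh ;  X'(r+1,c+1) = M − yd
```

Consequences, verified against a brute-force per-block oracle:

* reconstruction is exact at every non-top-left position (to IEEE
  round-off) and at the top-left whenever it attains the block maximum;
  otherwise the top-left is replaced by the block maximum — the scheme's
  only, and localized, approximation;
* gray-shift invariance: `analyze(X+c)` shifts the approximation by exactly
  `c` and leaves the details unchanged up to round-off;
* if `X ∈ [0,R]` then the approximation stays in `[0,R]` and the details in
  `[0,R]`.

Only one decomposition level is supported (a dual-resolution scheme suited
to the low spatial resolution of fMRI); the `level` argument exists but
rejects values ≠ 1. Volumes are processed as independent 2-D slices along a
configurable axis (default axial); a 2×2×2 3-D extension is deliberately
not invented.

## Entropy-filtered maximum-selection fusion

To fuse `n` network decompositions, each sub-band is optionally replaced by
a *priority* map: the Shannon entropy (bits) of a 3×3 neighbourhood
histogram, quantized into 256 bins over the band's **global** range (local
ranges would make entropies incomparable across positions). Borders are
replicate-padded; a constant band has zero entropy everywhere. The
maximum-selection (MS) rule then picks, per band and position, the input
with the largest priority magnitude (raw band magnitude when the entropy
filter is off); ties go to the lowest input index.

Two readings of the fused value are possible and both are implemented:

* **default** — the winner's original signed coefficient. This preserves
  activation magnitudes through fusion, which is the point of using a
  gray-value-preserving transform in the first place;
* `output="priority"` — the winning entropy value itself (the literal
  "replace each voxel by its entropy" reading; it destroys magnitudes and
  exists for comparison only).

`epsilon_threshold` zeroes priorities below a minimum local entropy,
implementing the removal of low-entropy voxels; the default 0 is pure MS.
Which bands are filtered is configurable (`filter_bands`); default is all
four, since the method description does not restrict it.

With the filter off and nonnegative inputs the fused approximation equals
the positionwise maximum of the inputs — the property the tests check
against an independent oracle.

## Functional normalization

Registration of a subject's fused network image to the group template is a
simplified SPM-style scheme, not an SPM re-implementation:

* **affine stage** — 12 parameters (translation, rotation, scale, shear) in
  voxel coordinates about the grid centre, fit by Gauss–Newton on the sum
  of squared differences (SSD) with a finite-difference Jacobian and step
  halving; deterministic from the identity initialization.
* **non-linear stage** — per-axis displacement fields expanded in a
  separable orthonormal 3-D DCT-II basis, default 7×8×7 = 392 coefficients
  per direction; fixed 12 Gauss–Newton sweeps minimizing
  `SSD + λ · penalty(c)` with λ = 0.01. Step halving guarantees the
  objective is non-increasing over accepted iterations.

The default penalty is a **membrane energy** (squared first derivatives of
the displacement field), which is diagonal in the DCT basis with weight
`(πm/nx)² + (πn/ny)² + (πo/nz)²` for mode `(m,n,o)`. This was a genuinely
open design point: a plain ridge on coefficient magnitude
(`penalty="ridge"`, still available) turned out to shrink smooth multi-voxel
displacements toward zero strongly enough that a truth-initialized
optimizer walked away from the true field — a magnitude penalty taxes
exactly the smooth, large-scale deformations the basis is there to express.
The membrane form leaves those nearly free while damping high-frequency
modes. Both images are globally scaled to unit-RMS target inside the
estimator so that λ has a stable meaning across inputs. With the membrane
default, in-span deformations of ≤ 3 voxels peak amplitude on 32×32×16 blob
images are recovered to < 0.5 voxel RMS over the image support with ≥ 90%
SSD reduction versus affine-only.

Recovery error is reported over the image *support* (voxels above 5% of the
maximum intensity): outside the support the SSD objective carries no
information about the displacement, so a whole-volume RMS would measure the
regularizer rather than registration accuracy.

Applying a warp composes affine and displacement into a single coordinate
map and interpolates the data exactly once (trilinear by default, nearest
for label volumes); each timepoint of a 4-D series is resampled
independently; out-of-field voxels become 0. Warping is therefore linear in
image intensities up to the out-of-field zeros.

`normalize_subject` fuses the subject's network maps with the *same* fusion
settings as the group template, estimates the subject warp fused-subject →
template, and applies it to the subject's task series.

## Evaluation statistics

* **t-maps** — voxelwise one-sample t with `df = n − 1`; zero-variance
  voxels are masked (NaN), not reported as 0.
* **FDR** — Benjamini–Hochberg step-up; the implementation also returns the
  critical p (largest `p(k) ≤ kq/m`). Defaults: q = 0.01 for activation
  maps, q = 0.05 for FNC families. Applied jointly over in-mask voxels, not
  per region.
* **Region tables** — per labeled region at the corrected threshold:
  suprathreshold voxel count, mean t *over suprathreshold voxels only*, and
  the world-mm peak of |t| (ties to first in scan order; no sub-voxel
  interpolation). Regions left empty after thresholding are absent, not
  zero. Pairing two schemes yields percent extent gain and the Euclidean
  peak shift in mm.
* **FNC** — per-subject Pearson correlations between component
  timecourses; constant rows give undefined (NaN) pairs. Group comparison
  is a two-sample t per pair on Fisher-z-transformed correlations (the
  transform is toggleable; z is the default because correlations are
  bounded), BH-corrected over the pair family.
* **Classifiers** — binary Fisher LDA with pooled covariance (singular
  pooled covariance is an error unless an explicit ridge ε is supplied) and
  an exhaustive shapelet search: candidates are all training subsequences
  (stride 1) in a length range (default 10–50% of T), distance is the
  minimum sliding-window Euclidean distance (optionally z-normalized per
  window), and the winner maximizes information gain with ties broken by
  larger split margin, then shorter length, then earliest candidate. A test
  distance exactly at the threshold goes to the low (motif) side. The
  repeated random-split protocol defaults to the study design: 14/14
  training and 14/13 test subjects per class, 100 runs; split lists are
  generated once per seed and can be shared across methods for paired
  comparison.

## Synthetic cohorts

The generator emulates what the pipeline consumes downstream of group ICA;
its defaults are the modeled study conditions: 28 HC and 27 SP subjects,
498-sample timecourses, four task-relevant networks (bilateral superior and
middle temporal blobs, left/right sensorimotor blobs). Group maps are sums
of Gaussian blobs; subject maps push the group map through a smooth random
displacement expanded in a low-order (3×3×3) DCT basis — i.e. in-span of
the estimation basis, enabling exact-recovery tests — scaled to a 1.5-voxel
peak by default, plus N(0, 0.05) voxel noise. Timecourses are multivariate
normal with a 0.20 background correlation and a group-dependent superior-
temporal–middle-temporal pair at 0.55 (HC) vs 0.15 (SP); an optional
Hann-windowed motif of configurable length/amplitude is inserted into one
component of one class at a random offset per subject. The default grid is
32×32×16 for test speed; `PAPER_GRID` (53×63×46) reproduces the acquisition
geometry. Everything is bit-reproducible from the spec seed.

What the generator does **not** emulate: BOLD hemodynamics and temporal
autocorrelation, scanner noise structure, anatomical variability beyond
smooth in-span warps, or the ICA decomposition itself. Passing tests
therefore demonstrate the correctness and internal consistency of the
operators and the direction of the normalization effect under the modeled
conditions — not clinical-data effect sizes.

## Problem sizes and numerical choices

Tests and the acceptance script run warp estimation with a reduced 4×4×3
basis on the 32×32×16 grid (the 392-parameter default stays the library
default and is shape-checked); the cohort-level experiment uses the full
55-subject design on the small grid. Computation is float64 with float32
Jacobians and on-disk storage (NIfTI convention); a 1e-8 identity term
conditions the Gauss–Newton normal matrix; degenerate inputs (constant
images, empty masks, zero-variance voxels, non-positive-definite target
correlations) raise informative errors rather than propagating NaNs.

## Known limitations

* Slice-wise (2-D) wavelet processing; through-plane detail is only carried
  by the slice stacking.
* SSD is the only registration objective; intensity differences between
  subject and template beyond a global scale are not modeled.
* The shapelet search is exhaustive (O(n²T²) distances per length); it is
  intended for component timecourses at modest lengths, not long signals.
* `compare_regions` pairs regions by name and drops regions absent from
  either table; a region that is suprathreshold under only one scheme does
  not appear in the paired table.
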