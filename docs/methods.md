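# Methods

`voxatlas` builds a population-level, voxelised statistical model of
prostate-cancer biology from per-patient, histology-derived data: graded
tumour annotations and cell-density maps defined on sparse axial slices
of co-registered ex-vivo imaging.  This note records the models, the
numerical choices, and what the synthetic phantom does and does not
emulate.

## Data model and conventions

Every volume is a `VoxelGrid`: a 3D array (axis order x, y, z) with
per-axis spacing (mm), the physical position of the first voxel centre,
and an orthonormal direction matrix with determinant +1.  Axial slices
run along the third axis; voxel indexing is 0-based; masks are {0, 1}
grids and "inside" means value 1 at the voxel centre.  Aggregation
operations require exact grid alignment (spacing, origin, orientation,
shape) and raise otherwise.  NIfTI and MetaImage round-trip losslessly
through SimpleITK.

Interpolator policy: binary masks are always resampled nearest-neighbour
(they stay binary); probabilistic and density maps linearly (convexity
keeps them inside their value range).  These are package conventions —
reasonable defaults rather than uniquely correct choices.

## Slice interpolation

Histology sections exist every 5 mm on a 2.5 mm-slice grid, so every
second slice is unannotated.  Gaps wider than one slice are rejected.

* **Contours** — morphological interpolation, implemented as the signed
  distance-function-average variant: the two neighbouring regions are
  shifted to their mean centroid, their signed Euclidean distance
  functions averaged, and the zero-superlevel set taken.  When one
  neighbour is empty, the filled slice is the non-empty region eroded to
  half its maximal interior depth (the shape "shrinks to extinction"
  over the two half-steps).  The behavioural contract — intermediate
  area, nesting, idempotence on constant stacks — is what the tests pin
  down, not the internal algorithm.
* **Cell density** — the filled voxel is the arithmetic mean of the two
  flanking slices at the same in-plane position, hence always within
  their range.  When a tissue mask is supplied (as the pipeline does
  with the prostate mask), the mean is support-weighted: where only one
  flanking slice lies inside tissue, its value is used alone rather than
  averaged with the zero recorded outside the gland — otherwise the
  filled density near the tapering apex/base is systematically halved.
  Cross-sectional density (cells/mm²) is converted to volumetric
  (cells/mm³) by an elementwise power law with exponent 3/2; the
  exponent is configurable (1.0 gives the linear-scaling alternative).
* **Graded lesions** — one volume per Gleason grade.  Annotated lesion
  voxels carry 1; each flanking annotated slice contributes 0.5 on the
  adjacent filled slice at covered positions; contributions add, capped
  at 1.  A voxel flanked by the same grade on both sides therefore
  carries 1, and one flanked by two different grades carries 0.5 in each
  grade's volume.  The cap (rather than a sum that could exceed 1) is
  the reading consistent with assigning exactly 1 between same-grade
  slices.  Two grades may not overlap at a single annotated voxel.

Slices beyond the first/last annotated slice receive no values and are
excluded from the validity mask, as is any filled in-gland voxel with no
tissue on either flanking annotated slice.  Interpolated slices count as
sampled data in the atlas: only voxels outside a patient's annotated
span are unsampled, which reproduces near-complete mid-gland sampling
with a taper towards apex and base.

## Reference geometry

Each patient's prostate mask is rigidly aligned — centroid to the
origin, then a rotation taking the principal second-moment axes onto the
coordinate axes.  Eigenvectors are assigned to the axes they are most
parallel to (linear-sum assignment on |cosine|), signed so the diagonal
is positive, with determinant +1 enforced by flipping the least-aligned
axis; near-axis-aligned glands therefore receive near-identity rotations
and no axis is ever flipped.  For degenerate (near-spherical) moments
the rotation is defined only up to symmetry, and tested as such.

The consensus reference prostate keeps voxels covered by at least a
configurable fraction (default 0.5, "half or more", with the threshold
attained counting as inside) of the aligned masks.  The reference PZ is
the analogous consensus of PZ masks *after* the whole-gland registration
stage, intersected with the reference prostate.  The reference urethra
is a tube of fixed radius (default 1.5 mm) around a cubic interpolating
spline through per-slice centroids of the aggregated warped urethra
masks.

## Registration

Each patient is mapped to the reference by a chain: anisotropic
similarity, whole-gland deformable stage, PZ deformable stage.

**Anisotropic similarity** is fitted by moment matching: centroids give
the translation, principal frames the rotation, and square roots of
matched second-moment eigenvalue ratios the three scales, applied along
the moving shape's principal axes (scale about the centroid, rotate,
translate).  This is exact for ellipsoids related by a similarity and
recovers synthetic transforms to within 2% scale / 2° rotation / 0.5 mm
translation on well-conditioned shapes.

**Deformable stages** use a log-domain, symmetric-forces demons
algorithm driven by the *normalised distance maps* (NDMs) of the two
shapes: signed Euclidean distance to the boundary, positive inside,
divided by the maximal interior depth so the deepest point reads 1 and
the boundary 0, with the exterior divided by the same factor and clipped
at −1 (the clip concentrates the matching signal in a band around the
boundary while interior shells carry the distance semantics; the
structure-guided registration literature leaves the exterior
normalisation open, so this is a package choice).  Because the "image" value at a point is its relative depth, a
converged registration maps every interior shell of the moving gland
onto the equal-depth shell of the fixed gland — boundary match *and*
interior correspondence.  Binary-mask-driven guidance is available as a
control and demonstrably fails the interior-correspondence property.

Numerics: symmetric demons forces from the mean gradient of fixed and
warped-moving images, update magnitude capped at 1 voxel, update field
smoothed with σ = 1.5 voxels, accumulated stationary velocity smoothed
with σ = 0.5 voxels, 3-level multiresolution pyramid (shrinks 4/2/1,
50/30/20 iterations by default; cohort-scale runs use 2 levels and fewer
iterations).  The displacement is the scaling-and-squaring exponential
of the velocity, which keeps the map diffeomorphic (positive Jacobian on
≥99.9% of in-gland voxels in the tests).  A residual plateau terminates
a level; a clearly rebounding residual emits a warning and keeps the
best-so-far field.

The PZ stage pins the prostate border: the velocity field is multiplied
each iteration by a smooth weight that is 0 within one voxel of the
gland boundary and ramps to 1 over 3 voxels, so refining PZ
correspondence cannot disturb the whole-gland match.  The mechanism
(weighting the velocity) is an implementation choice; the constraint
(zero deformation at the border) is the requirement.

Transform chains map reference points back to patient space for
resampling (displacement fields live on the reference grid, in mm).
Density is warped with mask-weighted linear interpolation — the density
times its validity support and the support itself are warped and
divided — so voxels at the edge of the sampled region are not diluted by
the zeros outside it; validity itself is warped nearest-neighbour and
gates all downstream statistics.

## Voxel statistics

With n(x) patients contributing valid data at reference voxel x
(sampling frequency = the count of warped validity masks):

* **Tumour probability.**  Per patient, the any-grade weight is
  min(1, Σ grades) of the warped probabilistic labels; p(x) is the
  weight sum over n(x).  The occurrence frequency is binomial,
  approximated by N(μ = n·p, σ² = n·p·(1−p)); the rate-scale variance
  p(1−p)/n is also exposed.  Relative uncertainty is
  CV = √((1−p)/(n·p)), undefined (NaN) where p = 0 or n = 0.
* **Cell density.**  Normal and log-normal fits use the 1/n
  (maximum-likelihood) variance form — deliberately, matching the model
  definitions, not 1/(n−1).  Zero-density samples are excluded from the
  log fit at that voxel with the count adjusted.  Voxels with fewer than
  3 usable samples (configurable) are flagged unfitted.  The log-normal
  CV is the closed form √(exp(σ²)−1).
* **Model evaluation.**  Per voxel with ≥5 usable samples, a Gaussian
  KDE of the empirical density distribution (1D Scott's rule,
  h = σ̂·n^(−1/5), σ̂ the ddof-1 sample standard deviation) is compared
  with each fitted model by the Kullback–Leibler divergence in bits:
  ∫ f log₂(f/g) on a grid spanning [max(0, min−4h), max+4h] with 512
  points, trapezoid quadrature, both densities renormalised on the grid
  (the truncation plus renormalisation controls the 0→∞ tail error).
  The model density is floored at 10⁻³⁰ inside the integrand; floored
  contributions trigger a warning.  Above a configurable cap the
  evaluation runs on a seeded random subsample of eligible voxels.

## The phantom

The generator emulates the *structure* of an ex-vivo histology study:
ellipsoid-like glands (per-axis scale ±20%, rotation ±15°, small
translation), a posterior-crescent PZ (radial thickness fraction 0.35),
a splined urethra, lesions preferring the posterolateral PZ, log-normal
cell density multiplied inside lesions, and annotation on every second
2.5 mm slice with a 5 mm apex/base margin.

Lesion counts are Poisson (rate 1.2/patient); each lesion independently
seeds in the posterolateral PZ with probability 0.45 (else uniformly in
the gland) and is a sphere of radius 4, 6 or 8 mm clipped to the gland,
with seeds drawn from canonical-grid voxel centres.  Under this marked
Poisson construction the per-voxel coverage probability has the exact
closed form p(x) = 1 − exp(−λ·Σ_R w_R (f ⋆ 1_{B_R})(x)), which
`cohort_truth` returns — parameter-recovery tests compare the atlas
against the *exact* latent field, not a simulation of it.  Spherical
lesions (rather than irregular blobs) buy this exactness; the atlas
statistics do not depend on lesion-shape realism.  The defaults give
≈42% of patients at least one posterolateral focus.

Cell density is a stationary Gaussian random field in log space
(filtered white noise, circular boundary, exact kernel-norm
normalisation): mean 7.0 log(cells/mm²), sd 0.17, correlation ~3 mm
in-plane and ~9 mm axially.  The long axial correlation makes adjacent
slices nearly identical, so linear slice interpolation and registration
resampling approximately preserve per-voxel marginals.  The sd is chosen
to sit in the regime implied by study-scale KL divergences (a few
hundredths of a bit at n≈60); with much larger spreads the linear-space
Scott-rule KDE is too broad to resolve the log-normal's skewness and the
comparison flips towards the normal model — a genuine property of this
metric at moderate n, and a known limitation.  The truth record carries
the log-density mean, variance and central fourth moment fields of the
lesion-multiplier mixture in closed form.  A truncated-normal density
family is available as a control; pipelines for it should use the
linear (exponent 1.0) volumetric conversion so normality survives.

What the phantom does **not** emulate: MRI physics and intensities,
staining and stain normalisation, histology-to-MRI co-registration
error, anatomically realistic gland or lesion shapes, and inter-patient
correlation of anatomy with disease.  Passing tests therefore establish
the pipeline's statistical and geometric correctness under the stated
generative model — not clinical validity on real cohorts.

## Problem sizes and determinism

Cohort-scale runs (reference construction, registration, statistics)
use 2 mm in-plane phantom grids and a 2 mm isotropic working resolution;
single-registration distance-preservation checks run at 0.8 mm on 64³
grids.  The 0.8 mm default working resolution matches in-vivo T2w
imaging and is what production use should keep.  All stochastic steps
consume an explicit seed; identical config + seed reproduces identical
cohorts and atlases (nearest-mode outputs byte-stable, float paths to
tolerance).

## Known limitations

* Inter-patient registration has no ground truth on real data; the
  acceptance of the registration is property-based on phantoms.
* The KDE/KL model comparison depends on the KDE's linear-space
  bandwidth; at small n or very large spreads it favours the normal
  model regardless of the generating family.
* Near-spherical glands make the principal-axis rotation ill-defined;
  behaviour is defined only up to the shape's symmetry.
* The σ² estimates inherit a small (≲10%) downward bias from
  interpolation and resampling averaging of correlated fields.
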