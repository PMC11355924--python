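# Methods

This note records the models, conventions, numerical choices and known
limitations behind `osteocurv`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic microstructures

Real trabecular specimens are binary micro-CT volumes; none ship with this
package. The generator emulates their controllable statistics: a
standard-normal white-noise field is smoothed with an anisotropic Gaussian
kernel (sigma = `correlation_length` x per-axis `anisotropy_scales`,
voxels) and thresholded at the quantile that puts the requested fraction
of voxels in the foreground. Only the largest 26-connected component is
kept; the threshold fraction is nudged (at most four deterministic steps)
so the *post-pruning* bone volume fraction lands within 0.005 of the
target. The generator promises the statistical knobs the analysis needs —
BV/TV, feature size, degree of anisotropy — and nothing else: it does not
reproduce plate/rod mixture statistics, cortical shells, or micro-CT noise
and partial-volume effects, so passing tests demonstrate method
correctness on trabecular-*like* geometry, not performance on scans.

Study-cohort defaults (`ExperimentConfig`): 300 cubes of 64^3 voxels at
35 um (2.24 mm side), BV/TV ~ U(0.08, 0.40), correlation length
~ U(1.5, 3.0) voxels, and a uniaxial kernel stretch ~ U(1.0, 2.5)
applied to a random axis. The correlation-length range was calibrated by
direct measurement — generated cubes show Tb.Th ~ 100 um per voxel of
correlation length — so the cohort spans roughly 170-360 um trabecular
thickness, the physiological range, with many trabeculae per cube. The full 6 mm / 172^3 scan geometry is supported everywhere but
only exercised where cheap (layer counting, projection resolution); the
64^3 cohort keeps a full experiment on one desktop CPU.

Analytic fixtures (sphere, cylinder, plate, torus, lattices) are
voxelized by center-of-voxel inclusion, exactly reproducible by brute
force, and carry the closed-form values the tests assert.

## Surface extraction and curvature

The bone/marrow interface is a marching-cubes isosurface of the (padded)
binary volume at level 0.5, in physical millimetres, with near-coincident
vertices merged. Marching cubes on binary data imprints lattice-scale
staircase noise on any curvature estimate, so two optional smoothers are
exposed and OFF by default: a Gaussian pre-smooth of the voxel field
(sigma in voxels) and shrink-resistant Taubin mesh smoothing. The
validated preset used throughout the pipeline and the fixture tests is
`smooth_sigma=1.0`, `taubin_iterations=20`, plus 6 rounds of 1-ring
vertex-normal averaging inside the curvature estimator. On a 1 mm sphere
voxelized at 25 um this preset gives median H = 1.003 mm^-1, area within
0.2% of 4*pi*r^2 and a Gauss-Bonnet sum within 0.1% of 4*pi; the raw
(unsmoothed) route remains available for users who want the uncooked
surface.

Principal curvatures use a finite-difference tensor fit: on each triangle
the 2x2 second fundamental form in the face frame is the least-squares
solution of II.e = dn over the three edges e and vertex-normal
differences dn (Tikhonov-regularized at 1e-9 of the squared edge length
so sliver faces cannot inject spurious curvature); face tensors are
parallel-transported into each vertex frame and averaged with
corner-angle weights; the eigenvalues give k1 >= k2, and K = k1*k2,
H = (k1+k2)/2 exactly. Sign convention: normals point out of the bone, so
a convex bone sphere has k1, k2 > 0. Vertices within one voxel of the
volume's bounding box are flagged as cut-plane artifacts; they are
excluded from curvature statistics, BS and SMI by default but *included*
in projection images (the projection sums everything).

## Projection images

The projection collapses vertex curvature onto the in-plane voxel grid:
bin value = (sum of the curvature of all vertices whose in-plane position
falls in the bin) / n, with n the number of one-voxel layers along the
projection axis (172 for the 6 mm / 35 um geometry; the axis defaults to
z and is configurable). Bins are half-open [edge, next-edge) intervals,
so boundary vertices land in the higher-index bin; bins with no vertices
are exactly zero. The four curvature kinds stack into one 4-channel
image. `projection_stack` can min-max rescale each channel per image
(recording the (min, max) pair); the experiment pipeline instead stores
raw projections and normalizes each channel with min-max statistics of
the *training split* — the same treatment the targets receive — because
absolute curvature magnitudes carry most of the morphometric signal and
per-image rescaling discards them.

Before projecting, the pipeline clips per-vertex principal curvatures at
the voxel Nyquist, |k| <= `curvature_clip`/spacing (default 1, i.e.
28.6 mm^-1 at 35 um): a marching-cubes mesh cannot resolve radii below
one voxel, and the rare pinched-neck vertices that report curvatures two
orders of magnitude above the bound would otherwise dominate the bin
sums and bury the morphometric signal (summary-feature regressions on
unclipped projections recover essentially nothing; on clipped ones they
recover BV/TV and BS with R^2 ~0.9). The general curvature API is left
unclipped.

## Histomorphometry

* BV/TV: integer voxel count ratio, exact.
* BS: mesh triangle area (cut faces excluded by default).
* Tb.Th: volume-weighted mean of a local-thickness map: per bone voxel,
  the diameter of the largest inscribed sphere containing it. Sphere
  radii come from the Euclidean distance transform, ceil-quantized to
  whole voxels with half-a-voxel coverage slack — the slack compensates
  the offset between lattice-bound sphere centers and the true medial
  locus, which otherwise biases round sections a full voxel low. A
  10-voxel slab reads exactly 0.35 mm at 35 um; a 20-voxel cylinder reads
  0.690 mm vs 0.700 mm true. An isolated voxel reads up to two voxel
  diameters (lattice-center convention).
* SMI = 6*BV*S'/S^2 with S' from a half-voxel outward vertex-normal
  offset of the mesh. Canonical values (0 plate / 3 rod / 4 sphere) are
  met on *spanning* plate and rod fixtures with cut faces masked; a free
  finite plate scores well above 0 because its rim genuinely contributes
  convex surface.
* DA: mean intercept length along quasi-uniform (Fibonacci-hemisphere)
  directions, random line origins, half-voxel sampling steps; the
  symmetric tensor fit of 1/MIL^2 gives the fabric ellipsoid, and
  DA = 1 - shortest/longest semi-axis (in [0, 1); the long/short ratio
  convention is one reciprocal away). Defaults 512 directions x 128
  origins; the pipeline uses 96 x 24, which widens the sampling noise of
  DA but leaves the other five parameters untouched. For extremely
  elongated structures the fitted quadratic form can turn indefinite
  (the 1/MIL^2 surface is genuinely non-ellipsoidal there); the public
  API raises, while the pipeline clamps eigenvalues at 1e-4 of the
  largest — DA saturates near 1 — and flags the sample.
* Conn.D = (1 - chi)/V with chi the 26-connectivity Euler characteristic
  by cubical-complex counting.

## Plate/rod decomposition

A deliberate simplification of individual-trabecula segmentation, built
for parameter recovery on fixtures rather than bit-compatibility with any
reference tool:

1. topology-preserving curve thinning (simple-point deletion in six
   directional subiterations; voxels with <= 2 neighbors are protected,
   which both preserves curve endpoints and stops a sequential pass from
   consuming a two-voxel ribbon end to end);
2. each skeleton voxel classified plate (surface-like) or rod
   (curve-like) from the principal-component shape of the *bone* cloud
   within an adaptive radius (1.5 x local thickness, clipped to 3-9
   voxels; planarity threshold l2/l1 >= 0.4);
3. rod-class junction voxels (skeleton degree >= 3) removed so branches
   separate; connected same-class segments become trabeculae, segments
   under 5 voxels are absorbed into their nearest neighbor, and every
   bone voxel takes the label of its nearest skeleton voxel.

Plate thickness = mean local thickness over the trabecula; plate area =
voxel volume / thickness; rod diameter = mean local thickness; rod length
= skeleton principal-axis extent *plus one diameter* (the medial axis
stops one inscribed radius short of each rod end); NND = mean same-class
nearest-centroid distance. Known limitations: junction voxels are
assigned by proximity (any junction convention is defensible; this one is
simplest), curved rods are measured by chord-like extent (a lower bound),
and rod length reproduces under 90-degree rotation only to two voxels
because thinning order shifts skeleton endpoints by up to a voxel per
end.

## Micro-FE homogenization

Each bone voxel becomes six congruent first-order tetrahedra sharing the
voxel's main diagonal (an optional trilinear hexahedron mode serves as a
discretization cross-check; the two agree within 3.4% on a 32^3
BV/TV-0.4 fixture, with the gap growing on thinner struts as expected for
C3D4 elements). "Uniform boundary conditions" are implemented as
kinematic-uniform: all RVE-boundary nodes receive u = eps0.x for the six
canonical unit strains (three uniaxial, three engineering shears with
gamma = 1); interior displacements come from Jacobi-preconditioned
conjugate gradients at relative residual 1e-8 (1e-6 in the cohort
pipeline). Voxels not face-connected to the main component are removed
and counted — corner- and edge-connected fragments form mechanisms under
KUBC. Column j of C is the volume-average stress (bone stress x bone
fraction) under case j; C is symmetrized with the asymmetry norm logged.
Tissue material: isotropic 15 GPa / 0.3. Sanity identity: a fully solid
cube returns exactly that material (1/S11 = 15.000 GPa, -S12/S11 =
0.300); this is what `scripts/acceptance.py` recomputes.

The stiffness can be rotated (full fourth-rank rotation) into the fabric
frame given by the MIL ellipsoid axes and projected onto the orthotropic
pattern — the nine constants of the familiar three-moduli/three-
couplings/three-shears form — with the Frobenius norm of the discarded
couplings reported rather than silently dropped.

## CNN regression

No deep-learning framework is part of the dependency set; the network is
implemented in numpy (im2col convolutions, max pooling, dense layers with
inverted dropout, Adam, MSE), which keeps training fully seeded: two runs
with one config give identical loss histories, and the backward pass is
verified against finite differences. Three tuned variants are provided —
histomorphometric (kernel 3x3, filters 8/16/32, dense 128/64, dropout
0.3, 200 epochs), geometric (5x5, 16/16/64, dropout 0.4, 300 epochs, 8
outputs) and stiffness (3x3, 16/32/64, dropout 0.5, 250 epochs, 9
outputs) — all with 2x2 pooling, learning rate 1e-4, and choices the
underlying description leaves open filled conventionally: Adam, ReLU
hidden activations with a linear output head, batch size 16, dropout on
dense layers only, a signed-square-root compression of the input bins
before min-max scaling, and random per-sample dihedral augmentation
(flips/90-degree rotations) of the training images — an exact symmetry
of a projection image with respect to scalar targets, and the main
regularizer at a few hundred training samples. Targets are min-max normalized per Eq.-style rescaling
using training-split statistics only; predictions are reported in native
units with per-target squared Pearson correlation and its two-sided
p-value.

On the 300-cube synthetic cohort the histomorphometric model recovers
BV/TV and BS with test R^2 >= 0.8 and Tb.Th >= 0.5, with DA ranking last
— the qualitative ordering expected of curvature-projection inputs, and
the package's own acceptance property. Absolute R^2 values on real
cadaveric data are outside what synthetic cubes can certify.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed (generator, MIL origins,
dataset split, weight init, batch shuffling, dropout); reruns of any
stage with an identical config produce bit-identical CSV outputs. Default
problem sizes — 300 x 64^3 cohort, 16^3/32^3 FE fixtures, 96^3 curvature
fixtures — were chosen so the full test suite and a complete
histomorphometric experiment run on a single desktop CPU; the full-scan-scale
172^3 FE problem (0.5-2.5 M elements) is reachable through the same API
as a long-running opt-in job.
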