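# Methods

`elasticshapes` compares two families of outline-shape analysis — the linear
geometric-morphometric route (Procrustes-aligned semi-landmarks + PCA,
"eigenshapes") and the elastic route (square-root velocity functions on the
shape sphere) — and everything a small comparative study needs around them:
a synthetic outline generator, distance-based k-NN classification with
stratified replicates, intrinsic and linear mean shapes, geodesic shape
transformations, and neighbour-joining trees over class-average distances.

## Shape representations and metrics

**Outlines.** The basic record is an ordered planar vertex sequence with a
closed/open flag. Closed outlines are stored without the duplicated closure
vertex, counter-clockwise, starting at the top-most vertex (ties broken by
smaller x) so that file round-trips are reproducible. Images enter through
Otsu (or fixed) thresholding and marching squares; when several closed
iso-contours exist the one with the greatest enclosed area is kept, since
inputs are single objects.

**Resampling.** "Equally spaced points" means equal arc length along an
interpolating spline (cubic by default; periodic for closed curves, natural
with pinned endpoints for open ones). Arc length is inverted on a dense
grid (50x oversampling), so successive chord lengths vary by well under 1%
at the working resolutions of 100–200 points; at much coarser sampling of
strongly curved outlines the residual variation is the genuine chord-vs-arc
gap, not resampler error.

**Eigenshapes.** Generalized Procrustes alignment removes translation,
scale and rotation (reflections excluded by default; a flag allows them)
by iterating member rotations against the consensus mean until the mean
moves by less than 1e-12 (max 200 rounds). The consensus frame is fixed by
a final global rotation that best matches the input configurations, which
makes alignment exactly idempotent. PCA of the flattened 2N-vectors (full
SVD, covariance scale) gives the eigenbasis; distances are Euclidean
between score vectors truncated at the smallest dimension explaining a
chosen variance fraction (tunable over {0.75, 0.9, 0.95, 0.99, 0.999}).

**Elastic metric.** A curve c becomes q = c' / sqrt(||c'||); after unit-norm
scaling, shapes are points on the L2 unit sphere and

    d(q1, q2) = arccos <q1, (O q2) o gamma . sqrt(gamma')>

minimized over rotation O, reparametrization gamma and, for closed curves,
the cyclic start point. Because the transform resamples to constant speed
first, the stored q is exactly the unit tangent field evaluated
analytically on the fitted spline — no finite-difference error.

The reparametrization search is dynamic programming on an M x M lattice.
Two move sets are used: a coarse one (slopes {1/3..3}) for the cyclic
seed scan, and a fine one (all coprime steps up to 6, slopes in [1/3, 3])
for the final match — the slopes near 1 are what let the DP represent
small smooth warps without paying a spurious sqrt(gamma') penalty. Segment
scores are trapezoid-rule integrals with q linearly interpolated between
nodes; interpolated vectors are rescaled to the interpolated magnitude,
because plain linear interpolation of a turning unit-vector field shrinks
it by cos(delta_phi/2) and that bias (about 1e-3 in inner product) would
otherwise dominate near-zero distances. With this quadrature the identity
warp reproduces the plain trapezoid inner product exactly, so
d(a, a) = 0 to machine precision.

Closed-curve alignment scans every seed_stride-th start vertex (default:
every vertex), solving the optimal rotation in closed form per candidate,
then refines the start point to sub-vertex precision by golden-section
search (the true shift of a resampled curve is rarely a whole vertex) and
runs warp-composition refinement passes; refinement only ever increases
the inner product, and `refine=0` reproduces the plain integer scan that a
brute-force oracle enumerates. Open curves follow the landmark convention:
endpoints pinned, no rotation search, unless explicitly requested; a
free-boundary mode lets the match slide past mismatched curve ends.

Known limitation: the DP optimum is direction-dependent. |d(a,b) - d(b,a)|
is about 1e-2 at M = 50–100 and shrinks with the grid; the
`symmetrize=True` option averages both directions when exact symmetry
matters. Pairwise matrices evaluate one direction per pair and are
symmetrized by construction.

**Geodesics, energy, means.** After alignment the geodesic is the great
circle between q1 and the aligned q2, sampled at kappa+1 points (default
kappa = 2 for distances, 5 for transformation series); closed-curve
intermediates are projected back to the closed constraint set by
reconstructing the curve, removing the linear closure drift, and
re-transforming. The path energy is the sum of consecutive great-circle
angles along the series, so an open-mode geodesic's energy equals its
endpoint distance by construction; `path_energy` on stored step outlines
compares consecutive steps at their stored sampling (a series shares a
sampling scheme), re-optimizing alignment per pair. The Karcher mean
iterates align -> average log-maps -> exponential-map update (step 0.5,
tolerance 1e-4 on the mean update, max 50 rounds) from the renormalized
extrinsic average; for identical inputs it stops after one round with zero
gradient. Mirror-symmetric transformation series split both outlines at
their extreme-y points, run the open geodesic between right halves, and
reflect/reattach each intermediate, re-oriented counter-clockwise.

## The synthetic generator

Real image datasets are replaced by star-shaped Fourier templates

    r(theta) = 1 + sum_j a_j cos(j theta) + b_j sin(j theta),

with 4 harmonics and amplitude scale `separation`/j (1/j decay keeps
templates smooth; draws with radius below 0.2 are rejected). Star shapes
are always simple closed curves with analytic area and perimeter, which
every geometric check exploits. Class members perturb the template radius
with i.i.d. vertex noise and are then dressed with the nuisance transforms
the metrics must ignore: smooth monotone parameter warps (sum of sines
with derivative bounded away from zero by construction), integer cyclic
start shifts, rotation, scale and translation. One seeded generator is
split into independent child streams per object, so any single outline is
reproducible.

The reference study condition is 5 classes at separation 0.25, 30 members
each, with vertex noise sd 0.01, warp strength 0.3, random start vertex,
full rotation, scale in [0.8, 1.25] and translation within ±0.5. The noise
level was chosen so the within-class elastic spread (≈ 0.11 rad) sits at
about half the smallest between-class template distance (≈ 0.15 rad at
this separation) — a moderately overlapping regime; i.i.d. radius noise is
harsh on a derivative-based metric, so small sd values already produce
substantial shape scatter. For tree experiments, `make_nested_families`
derives child classes from parent templates with amplitude offsets at 0.1
of the parent scale; because elastic distance compresses amplitude
differences, this keeps within-parent distances at roughly a third of
between-parent ones, a clean two-level hierarchy.

What the generator does not emulate: jagged or concave (non-star) outlines,
handles and other appendages, digitization artefacts beyond rasterization,
and correlated within-class deformation modes. Passing tests therefore
demonstrate metric invariances, optimizer correctness and the relative
behaviour of the methods under parametrization nuisance — not absolute
accuracy figures for any real dataset.

## Classification and trees

The k-NN takes a precomputed distance matrix; a test object receives the
majority label of its k nearest training objects, with class ties broken
by the nearest single neighbour among the tied classes and equal distances
resolved by stable training order. Evaluation uses stratified holdout
replicates (largest-remainder per-class allocation for fractional training
sizes), weighted F1 per replicate (scikit-learn's weighted average), and a
normal-approximation 95% CI over replicates; k is tuned on the replicate
mean over a grid (3–12 by default; ties go to the smaller k). Unlabeled
partitions — an expert sorting objects into anonymous groups — are scored
by the one-to-one group-to-class assignment maximizing weighted F1, found
by linear assignment over per-pair F1 contributions.

Class-average matrices hold mean cross-class object distances off the
diagonal and mean within-class distances on it; the diagonal is reported
but excluded from metric correlations (Pearson r over the upper triangle)
and from neighbour joining. NJ uses the standard Q-matrix agglomeration
with negative branch estimates clamped to zero; class ids are passed in
sorted order so ties resolve deterministically, and NJ is exact on
additive matrices. Monophyly of a family means some edge of the tree
separates exactly that family's leaves from the rest.

## Problem sizes and numerical choices

Default grids: 100 points per outline and a 100-point SRVF grid for
single-pair work; distance matrices for the 150-object reference study use
a 60-point grid (about 40 ms per pair including the full seed scan), and
tree experiments a 50-point grid. The arccos argument is clamped to
[-1, 1]; zero-length segments and degenerate configurations raise
value errors rather than propagating NaNs. All randomness flows from
explicit seeds; repeated runs are bit-identical.
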