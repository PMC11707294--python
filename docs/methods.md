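# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic validation shows. It states no number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate systems and conventions

Three Cartesian systems are used: raw tomogram axes X–Y–Z, a per-membrane
local frame x–y–z in which the membrane is a single-valued height field
z = f(x, y), and flattened axes u–v–w. Volumes are indexed `data[x, y, z]`
with 0-based voxel indices; the center of voxel (0,0,0) is position
(0.0, 0.0, 0.0), and the STAR export documents this so 1-based consumers can
shift. Voxel sizes are isotropic; anisotropic MRC headers are rejected
because all geometry is done in pixel units. The slab index is 0-based:
the central slice is `w_c = w_t` and the slab spans w ∈ [0, 2w_t]
(human-facing text uses the 1-based w_t + 1).

The local frame's z sign is chosen to have non-negative dot product with
raw +Z (tie: +X), and the frame translation is the centroid of the starting
points **rounded to the nearest integer voxel**. The rounding is an
arbitrary origin choice that buys one exactness property: when the membrane
is an axis-aligned plane on an integer Z level, the flattened grid is
lattice-aligned with the raw grid and trilinear resampling is value-exact
(the plane-identity test asserts this bitwise to float tolerance).

## Starting-point extraction

The mask boundary is `mask & ~erosion(mask)` with a 6-connected structuring
element, which yields single-voxel boundaries on axis-aligned slabs; a
per-slice 2D Canny alternative is provided (sigma 1.0, auto thresholds).
Seeded extension walks the boundary with the membrane-perpendicular axis as
the lateral coordinate: the primary chain steps Z by ±1 within the seed's
x–z plane, secondary chains step Y by ±1 within each x–y plane (axis
permutations handle membranes perpendicular to Y or Z). At each step the
candidates are boundary voxels in the next line within ±2 voxels laterally;
the nearest wins, ties broken by smaller offset then smaller coordinate.
Monotonicity of the stepped coordinate holds by construction; the walk
terminates when no candidate exists (e.g. at a fold, where the surface
doubles back) or at the extension limit. The lateral ±2 window and the
tie-break are this package's choices; folds separated laterally by more than
the window are never jumped. Outliers are removed by the mean-kNN-distance
rule (k = 50, threshold mean + 2 SD, k clipped to n−1 for small sets).

## Surface models

*Polynomial*: least squares on centered/scaled monomials for conditioning;
the reported coefficients are converted back to raw monomials, so a
degree-2 truth like 1 + 2x + 3y + 0.5xy is recovered to 1e-8 (asserted).
Rank deficiency raises with a suggestion to lower the degree.

*Thin-plate spline*: kernel r² log r with an affine tail, solved directly;
smoothing λ enters as diagonal regularization of the kernel block, so λ = 0
interpolates and the control-point residual sum is non-decreasing in λ
(property-tested). The solver is cross-checked against
`scipy.interpolate.RBFInterpolator` at λ = 0, but kept in-package because
flattening needs the analytic kernel gradient, which the scipy object does
not expose. Control points are grid-cell centroids at `downsample_spacing`
(default 12 px); after the first fit, control points whose absolute residual
exceeds 3 SD are dropped once and the fit repeated. With λ = 0 the residuals
vanish by construction, so the outlier refit is only active with λ > 0 —
use smoothing when the starting points may contain gross errors.

Unit normals are `normalize(−f_x, −f_y, 1)` rotated into raw coordinates.
On the flatmap grid, normals are instead computed from central differences
of the sampled surface positions (one-sided at edges); the two routes agree
to better than 1° on the sphere fixture (tested).

## Cylindrical unrolling

The open cylinder z = h(y) is fitted by nonlinear least squares jointly
over a rotation perturbation of the initial plane-fit frame and the
polynomial coefficients (`scipy.optimize.least_squares`); before the solve,
the frame is rotated in-plane so the direction of largest curvature of a
quadratic pre-fit becomes the bend axis y (a flag can force the axis).
Arc length v(y) is tabulated on a 4001-point trapezoid grid with monotone
PCHIP interpolants for v(y) and y(v); composition errors are below 1e-6 on
the tested profiles. Equal steps in v are equal arc-length steps on the
cylinder, which is what makes the intermediate flattening distortion-free:
on the circular-cylinder phantom the central-slice area and shape
distortion stay within 1% of unity (acceptance-tested, interior region).

The elliptic variant selects the cylinder axis as the principal direction
whose projection yields the best direct ellipse fit (skimage
`EllipseModel`), then builds (u = axis coordinate, v = ellipse arc length,
height = radial offset along the ellipse normal). A heuristic warns when
the projected cross-section looks single-valued (an open arc), recommending
the open-cylinder mode: a hugging ellipse can fit an arc well, so angular
coverage alone is not a reliable signal.

## Rendering, inversion, distortion

Rendering is trilinear (`scipy.ndimage.map_coordinates`, order 1) at
S + (w − w_c)·N; out-of-bounds samples receive the raw-volume mean and are
flagged in a validity mask. Between grid nodes, S and N are interpolated
bilinearly and N re-normalized (unit length is kept in preference to exact
linearity between nodes). The inverse map seeds from the nearest grid node
(KD-tree) and refines (u, v) by Gauss–Newton on the distance to the
interpolated surface; success requires a tangential residual below 0.5 px
and |w − w_c| ≤ w_t + 0.5. Round trips over the slab come back well under
0.5 px (tested at 1000 points).

Distortion is computed for any slice w by differencing the offset positions
S + (w − w_c)N with `np.gradient` (central interior, one-sided edges,
flagged). Because one-sided differences at the two-pixel edge band are
first-order only, quantitative statements in tests and the acceptance
script are made on the interior (a 4-px trim); the maps themselves cover
every pixel. On a cylinder of radius r, a slice at offset d has area
distortion (r+d)/r outside and r/(r−d) recorded as contraction inside
(both asserted within 2%). For a sphere unrolled over its tangent cylinder,
the shape distortion equals 1/cos φ at angular distance φ from the tangent
circle **along the perpendicular great circle**; off that line the law
acquires second-order corrections in the transverse coordinate (the
fundamental form develops an F term), so the acceptance measurement is made
along that row, where agreement is within 3% for φ ≤ 45°.

## Particle layer

Duplicate removal sorts by score (ties: (w, u, v) ascending) and greedily
keeps picks at least `min_spacing` apart in 3D flattened voxels (a 2D
(u,v)-only option exists); the result is input-order invariant and equals a
brute-force greedy oracle (tested). Orientation matrices are [vx vy n]
with vx first projected perpendicular to the normal and vy = n × vx; Euler
angles use the ZYZ intrinsic convention matching STAR rot/tilt/psi, with
tilt ≈ 0/180 canonicalized by psi = 0. The projection basis
(e1 = normalize(d × ẑ), e2 = d × e1, with e1 = x̂ when d ∥ ẑ) is shared
between projection images and 2DCTF extraction so in-plane angles mean the
same thing in both.

The 3DCTF is a deliberately simple model: per tilt, a planar slab through
the Fourier origin perpendicular to the beam with a linear falloff of
half-width 1 Fourier voxel; the voxel weight is the maximum over tilts
(keeping weights ≤ 1), optionally multiplied by a standard 1D CTF assigned
from the strongest tilt. It reproduces the geometry that matters for
weighting — no dose weighting or defocus gradients. The 2DCTF is the
central slice along the projection direction (trilinear; matches a
volume-rotation oracle to 1e-3).

## The phantom and what passing tests show

The generator renders the membrane as two parallel Gaussian-dark sheets
(leaflet separation 5 px, width 1.2 px, the negative-contrast convention of
cryoET) on an analytic surface — plane, polynomial sheet, sinusoid,
circular or elliptic cylinder, sphere — plus anisotropic dark particle
blobs at ground-truth positions. Each blob is an elongated Gaussian
(σ = 4×2×2 px) plus a smaller satellite displaced 5 px along the in-plane
direction; the satellite breaks the 180° symmetry of a plain ellipse so the
in-plane angle is identifiable over the full circle. ψ* is defined in the
projection basis of the local normal, the same convention the analysis
uses. Optional corruption: additive white noise and a Fourier-space
missing-wedge mask (angular criterion, tilt axis Y). Determinism is
seed-exact (bit-identical volumes, tested).

The end-to-end study plants 50 particles on a cylindrical patch
(radius 58 px, 220×200×140 volume, noise σ = 0.05 against a membrane
amplitude of 1) on a jittered grid guaranteeing ≥ 16 px separation — at
tighter spacing, neighboring particles enter each other's projection boxes
and in-plane matching degrades, which is a real crowding effect, not an
implementation artifact. The pipeline (mask → boundary → seeded extension →
TPS surface → cylinder → flatten → per-slice blob picking → dedup →
geometry attachment → joint rotation+shift template matching, two
recentering iterations) recovers positions with sub-voxel median error and
in-plane angles within a few degrees median; both numbers are recomputed by
`scripts/acceptance.py`.

What this does **not** show: performance on real tomograms with structured
noise, membrane-embedded crowding, segmentation errors, or proteins whose
projections are nearly rotationally symmetric; the blob detector and
template matcher are reference stand-ins for external neural picking and 2D
classification, not replacements. Problem sizes (≈200³ volumes, 50
particles, 33³ CTF cubes) were chosen so the full validation runs in tens
of seconds on one CPU while leaving every geometric property measurable at
sub-voxel precision.

## Known limitations

- One membrane per flatmap; self-intersecting or multi-sheet surfaces are
  out of scope (closed surfaces go through the elliptic or mesh pathway).
- The normal fibration can fold for |w − w_c| approaching the local radius
  of curvature; the inverse map reports such points as unmappable rather
  than guessing.
- TPS surfaces wobble within roughly one control-spacing of the data
  boundary (visible as edge bands in distortion maps); the polynomial
  surface is preferable for globally smooth membranes.
- The elliptic pathway assumes a roughly constant cross-section along the
  cylinder axis.
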