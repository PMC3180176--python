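# Methods

## Curves and curvature

A contour is an open, ordered polyline in pixel coordinates ((x, y),
0-based, pixel-center convention).  Before curvature evaluation every
curve is resampled to uniform arc-length spacing `min(1 px, l/100)`;
hand-drawn contours have uneven vertex spacing, which would otherwise
bias the derivative estimates.  First and second derivatives of the
coordinate functions with respect to arc length come from a centered
local quadratic fit (a Savitzky–Golay filter of polynomial order 2) over
a window of resampled vertices, clamped at the curve ends; curvature is
then κ = |ẋÿ − ẏẍ| / (ẋ² + ẏ²)^{3/2}, in 1/pixels.  Degenerate local
geometry returns 0 rather than NaN.

The window default is 9 vertices.  A 7-point window is marginally more
local, but when the input polyline's vertex spacing is coarser than the
1-px resampling grid the two samplings alias and the 7-point estimate
wobbles (up to ~2.2% on a radius-50 circle sampled at 200 points); 9
points keep the estimator within ~1.2% across radii 10–50 at that
sampling while still resolving pixel-scale features.  Larger windows
attenuate genuine curvature on small structures (≥15 points exceeds 2%
error on a radius-10 circle).

Maximum curvature over an interval is taken over the dense resampling
and floored at ε_κ = 10⁻⁶/px, so that the curvature-normalization in
the landmark cost never divides by zero on straight homologous segments.

## Landmark generation and relaxation

Landmarks live as arc-length fractions on a homologous curve pair.  The
two endpoint landmarks are fixed; the i-th landmark is inserted at the
arc-length midpoint of the longest source segment, its homologue at the
same fractional position (the midpoint) of the corresponding target
segment — proportional placement is the unique parameter-free choice.
Ties in segment length break toward lower arc length, for determinism.
Insertion records the landmark's initial position and its enclosing
segment, both frozen, so that the displacement term of the cost is
always measured against placement time.

The cost of an interior landmark pair is the normalized
curvature difference plus λ times the sum of the two normalized
arc-length displacements.  Two normalization choices were open:

* the curvature maximum is taken over the current sliding span (between
  the neighboring landmarks) on each curve, not over the whole curve —
  this lets a shared local feature dominate the comparison regardless of
  stronger features elsewhere on the curve; on synthetic phantoms the
  whole-curve alternative performed indistinguishably;
* the displacement is the landmark's own displacement only, normalized
  by the frozen insertion-segment length.

Relaxation minimizes the cost over the 2-D variable (source position,
target position), in arc-length pixels.  The minimizer is Nelder–Mead
with the stopping rules: simplex displacement below `tol_px` (default
10⁻⁴ px) or 500 iterations; out-of-bounds proposals cost 10⁶, which
confines each landmark to the open interval between its neighbors and
preserves landmark order.  Two numerical details matter:

* **Basin location.**  The curvature-difference term vanishes along
  narrow valleys in the (s, t) plane — wherever the two normalized
  curvature profiles cross — and these valleys can be only a pixel or
  two wide.  A simplex started from the initial position alone reliably
  finds only the nearest valley.  Relaxation therefore first scans the
  sliding rectangle at ~1 px spacing (a vectorized outer sum over the
  cached curvature tables, costing ~1 ms) and polishes the best
  candidates, plus the start point, with Nelder–Mead, keeping the best
  result.  The returned cost never exceeds the starting cost.
* **Minimum separation.**  The sliding interval is shrunk by
  `min(1 px, 10% of the span)` at each end.  Without this margin
  landmarks can converge sub-pixel-close to their neighbors; two
  near-coincident control points with different homologues make the
  thin-plate-spline system nearly singular and produce wild warps.

λ defaults to 0.25 (a 0.2–0.3 range works well for rodent-brain-scale
contours; larger λ restricts sliding, and mean displacement is
monotonically non-increasing in λ on the test suite's fixed curve
pairs).  By default only the newly inserted pair is relaxed after each
insertion; `reoptimize_all=True` additionally sweeps all interior
landmarks after every insertion until none moves more than `tol_px`
(at most 5 sweeps).

## Thin-plate spline

The classical 2-D thin-plate spline: kernel U(r) = r² log r² with
U(0) = 0 plus an affine part, solved as one dense linear system with the
side conditions (kernel weights sum to zero and are orthogonal to the
control-point coordinates).  With zero regularization — the default,
since the landmarks are assumed exact once optimized — the spline
interpolates every landmark pair; a positive regularization yields a
smoothing spline.  Collinear control points and duplicates within
10⁻⁶ px are rejected with diagnostics.

Image warping is backward: the inverse-direction spline (fitted to the
swapped landmark pairs, which the forward transform reproduces exactly)
maps each target pixel to a source location, sampled with nearest,
linear (default) or cubic interpolation; out-of-bounds samples are 0.
Fitting the inverse spline instead of numerically inverting the forward
map is standard practice; the two splines are not exact inverses away
from the landmarks, an asymmetry inherent to the approach.

## Metrics

NMI uses a bins×bins joint histogram (default 32) with equal-width bins
spanning each image's own min–max range, Shannon entropies in bits;
NMI = (H(A)+H(B))/H(A,B) ∈ [1, 2].  Comparisons are only meaningful at
fixed binning.  A mask restricts the histogram to a region of interest.
Constant images (zero entropy) are rejected.

TRE is the set of residual vectors T(P_S) − P_T over evaluation point
pairs, reported as the mean Euclidean magnitude.  Evaluation points must
be disjoint from the landmarks used in fitting (the pipeline warns
otherwise): under exact interpolation the residual at a fit landmark is
identically ~0 and carries no information.

## Synthetic phantoms

A phantom emulates a 2-D brain-slice registration problem:

* **Target image**: a lobed outer boundary (radius modulated by three
  low-order cosine harmonics, amplitudes 2–8%) with 1–3 internal
  structures of distinct intensities, rasterized on a 0–255 scale;
  boundary contours are taken analytically from the generating shapes,
  not by segmentation, so contour error does not contaminate
  landmark/warp error.  Each closed boundary is split at shared vertex
  indices into 4 homologous open curves.
* **Ground-truth deformation**: 3–6 Gaussian radial bumps, σ ∈ [10, 30]
  px, rescaled so the maximum displacement magnitude equals the
  requested amplitude (default 8 px).  Bump centers sit on the tissue
  boundaries with tangentially oriented vectors: boundary-parallel shear
  is the component of slice distortion that redistributes arc length
  along contours and thereby misplaces interval-based landmark
  placements — an interior-centered or uniform-direction field leaves
  proportional placement essentially exact and the optimization with
  nothing to correct.  The family is deliberately outside the
  thin-plate-spline class, so recovery is a fair test.
* **Source image**: backward-resampled through the numerically inverted
  field (fixed-point iteration, convergent at these amplitudes), with
  independent Gaussian intensity noise (default σ = 2, i.e. <1% of the
  dynamic range) added to both images.
* **Correspondences**: source contour vertices are exactly the deformed
  target vertices; 18 held-out evaluation pairs (12 just inside the
  structure boundaries — anatomical-feature points — and 6 interior).
  Self-intersecting deformed contours trigger regeneration (up to 10
  draws).  All randomness flows from one seeded generator; phantoms are
  bit-reproducible per seed.
* **Discrete-landmark emulation**: true correspondences perturbed on
  both sides by i.i.d. Gaussian jitter (magnitudes Rayleigh-distributed,
  mean σ√(π/2)) stand in for manual point picking.

What the phantom does *not* emulate: independently hand-drawn contours
(source contours are exact images of target contours), MR physics or
stain rendering, intensity differences between modalities, tissue
tearing (topology changes), or 3-D effects.  Passing phantom tests
demonstrates the pipeline's correctness and its behaviour under known
smooth deformations, not performance on real multimodal data.

## Pipeline defaults

λ = 0.25, tol = 10⁻⁴ px, 500 iterations, 10 landmarks per curve,
32 histogram bins, linear intensity interpolation, zero spline
regularization.  All are overridable via `OptimizerParams`, the CLI
flags, or a TOML config file.  Every run is deterministic given its
inputs; repeated runs produce byte-identical artifacts.

## Known limitations

* **Optimization vs. proportional placement on exact-contour
  phantoms.**  On the synthetic phantoms the nonoptimized (proportional)
  placements are already accurate to a few tenths of a pixel, because
  the source contours are exact images of the target contours under a
  smooth, bounded deformation.  The curvature-similarity term's own
  minimum sits 1–6 px from the true correspondence — the deformation
  rescales curvature (tangential stretch of order amplitude/σ), so a
  perfect curvature match is not a perfect anatomical match — and
  sliding toward it can therefore *increase* held-out TRE relative to
  leaving landmarks at their initial positions (measured at amplitude
  8 px: mean TRE 1.0 px optimized vs 0.55 px nonoptimized, both far
  below the 3.6 px pre-registration error and the 5.6 px obtained with
  2-px-jitter discrete landmarks).  This mirrors the regime where
  initial placements are already good; the optimization's value lies
  where initial correspondence is poor — independently drawn contours,
  inconsistent endpoint choices, strong arc-length redistribution — a
  regime an exact-correspondence phantom cannot represent.  NMI, by
  contrast, improves on every phantom seed after warping.
* Curvature matching assumes features survive the deformation; severe
  or high-frequency distortions (σ comparable to the feature width)
  degrade the correspondence signal.
* The warp is 2-D only; through-plane distortion must be handled
  upstream (e.g. a 3-D affine pre-alignment and reslicing).
* Closed contours are handled as split open curves; the split points
  act as fixed landmarks and should be placed at reliably identifiable
  positions.
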