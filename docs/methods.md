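# Methods

## The tract model

A white-matter tract delineated by tractography is represented by a discrete
medial surface: a triangulated mid-surface with, at every vertex v, a unit
normal n(v) pointing across the sheet's thickness and a radius R(v) equal to
the radius of the maximal inscribed sphere centred at v.  The two offset
sheets v ± R(v)·n(v) trace the tract boundary, so the triple (skeleton,
normals, R) simultaneously encodes the tract's core geometry and its local
thickness.  The model presumes sheet-like geometry; tubular tracts (fornix,
cingulum) have a degenerate (curve-like) medial locus and are rejected
explicitly rather than modelled badly.

The skeleton is built once, from the template-space tract mask; subjects
never receive individual skeletons.  Subject data reach the skeleton through
the projection step below.

## Medial surface extraction

Input: a binary tract mask on a voxel grid (voxel centres at integer
indices; the affine maps indices to world mm).  Pipeline:

1. **Distance transform** D = Euclidean distance transform of the mask, in mm.
2. **Thin-direction field**: the per-voxel principal eigenvector of the
   locally averaged structure tensor of ∇D (Gaussian smoothing of D with
   σ = 1 voxel; structure-tensor averaging with σ = 1.5 voxels).  On either
   side of the mid-surface ∇D points toward it along ∓ the sheet normal, so
   the structure tensor's dominant eigenvector is the thin direction with
   the sign ambiguity averaged out.  The field is oriented coherently
   against its own dominant axis.
3. **Level set**: the mid-surface is the zero level of the directional
   derivative ∇D·n, extracted by marching cubes restricted to mask voxels
   whose thin direction is coherent with the global axis (|cos| > 0.5); this
   suppresses spurious sheets at lateral rims where the medial locus belongs
   to side walls.  Tiny disconnected fragments (< 4 triangles) are dropped.
4. **Smoothing**: Laplacian smoothing with λ = 0.5; the iteration count is
   `round(2 · smoothing_mm / voxel)` (default `smoothing_mm = 1`).
5. **Normals and radius**: area-weighted mesh vertex normals, sign-aligned
   with the thin-direction field (the field itself substitutes where the
   mesh normal is degenerate); R is the trilinearly interpolated distance
   transform at the vertex.  R therefore agrees with the distance transform
   by construction, and on the shipped phantoms ≥ 95 % of vertices fall
   within 1 voxel of the analytic mid-surface while the union of balls
   B(v, R(v)) covers ≥ 95 % of the mask.

**Tubularity rejection.** The medial voxel set (local maxima of D along its
quantized gradient direction) is analysed by PCA; if its second principal
extent is ≤ 3 voxels the mask is tubular or blob-like and a geometry error
is raised.

## Tractography

FACT deterministic tracking: one bidirectional seed per voxel with
FA ≥ 0.1 (launched along ±e1 from the voxel centre), following each voxel's
principal eigenvector to the voxel face by exact ray–box intersection with a
10⁻⁶-voxel nudge across faces, eigenvector sign chosen to minimize turning.
Propagation stops on entering a voxel with FA below threshold, on a turn
exceeding the angle threshold (default 45°), on leaving the grid, or at
`max_steps` (default 2000, far above any phantom's needs).  Terminal points
are clipped to the stopping face.  Tract selection keeps a streamline iff it
intersects every waypoint ROI and no exclusion ROI; anatomical ROI placement
is supplied as mask files (manual protocols cannot be meaningfully
automated).  Point-to-voxel assignment uses half-up rounding so a face point
at i + 0.5 belongs to voxel i + 1 — every voxel a streamline traverses is
hit by its entry face.

## Projection

For each vertex, tensors are sampled at v + s·n(v) for s ∈ [−R(v), +R(v)]
at `sample_step_mm` spacing (default half the smallest voxel edge),
nearest-voxel lookup (half-up), deduplicated by voxel and ordered by |s|.
The **max** strategy keeps the sampled tensor of highest FA — ties resolve
to the sample closest to the skeleton — and derives every requested metric
(FA, MD, AD, RD) from that single tensor, even when the metric projected is
not FA.  The **mean** strategy averages the sampled tensors and derives
metrics from the average; averaging is log-Euclidean by default (keeps the
mean positive-definite and avoids eigenvalue swelling; arithmetic averaging
is available for sensitivity checks, and trilinear tensor interpolation is
available behind `interpolate=True`).  Vertices whose entire search segment
is background are flagged missing and propagate as missing into statistics
(zero-filling would bias the regression).  If more than 10 % of vertices
sample entirely outside the volume, a misalignment error is raised.

Because the search stops at the tract boundary, a high-FA voxel just beyond
the boundary is never selected.  The TBSS-style comparator reproduces the
alternative semantics: a voxel skeleton at the mean-FA ridge, a per-voxel
search direction of maximum FA change in the 3×3×3 neighbourhood (the
FA-weighted centre-of-gravity offset when appreciable, i.e. |offset| > 0.1
voxel, otherwise the largest-second-difference axis, which is the
across-ridge direction at ridge voxels), skeleton membership requiring a
strict local maximum along that direction, and a ±1-voxel max-FA search
stopped by the nearest-skeleton-voxel basin (a skeleton-distance-map
watershed) or `max_search_mm`.  This comparator is an emulation of those
semantics, not a port of the FSL implementation; inference-side features of
TBSS (threshold-free cluster enhancement) are out of scope.  On distractor
phantoms the boundary-limited projection excludes, and the comparator
includes, the planted voxel — the mechanism by which skeleton searches can
cross into neighbouring tracts.

## Statistics

`SkeletonGLM` fits, at each vertex, OLS of the projected metric on
[1, predictor, nuisances]; the test statistic is t = β̂/SE(β̂) with
df = n − p.  Perfect fits (zero residual variance) produce a capped sentinel
t (10⁶) rather than infinity.  Vertices observed in fewer than 90 % of
subjects are excluded; remaining missing values are handled complete-case
per vertex (and restricted to fully observed vertices within the permutation
machinery, which requires a rectangular matrix).

Cluster inference: observed clusters are connected components (mesh
adjacency) of vertices with t above a primary threshold — by default the
t-value of uncorrected one-sided p = 0.01 at the design's df, always
recorded in the result and overridable, since no convention is universal.
The null distribution is the maximum cluster size over the skeleton for each
of `n_perm` permutations under the Freedman–Lane scheme: residuals of the
nuisance-only model are permuted and the nuisance fit added back, giving
correct exchangeability in the presence of nuisance signal.  Corrected
p = (1 + #{null max ≥ observed size}) / (1 + n_perm); the +1 terms are the
always-included identity permutation, so p ≥ 1/(1 + n_perm).  The cluster
statistic is vertex count; positive, negative and two-sided contrasts are
supported so increases and decreases are reported separately.  Calibration
is verified by simulation: over 200 null cohorts (n = 20, 500 permutations,
≈ 500 vertices) the empirical family-wise error rate at α = 0.05 falls
within the exact binomial 95 % CI.

## Evaluation metrics

Dice overlap 2|A∩B|/(|A|+|B|) with per-subject medians over all pairwise
comparisons; normalized equal-width FA histograms (default 100 bins on
[0, 1], recorded with every distance) compared by the Bhattacharyya distance
D_B = −ln Σ√(pᵢqᵢ); and the Wilcoxon signed-rank test with Pratt-style zero
dropping (count reported), exact null enumeration up to n = 25 via dynamic
programming over doubled midranks (ties exact), and a tie- and
continuity-corrected normal approximation above.  Native-space reference
values are the FA at voxels visited by the selected streamlines.
`compare_projection_methods` assembles per-subject mean-FA triples and
Bhattacharyya distances plus paired cohort-level Wilcoxon tests for each
contrast.

## Synthetic data

`make_sheet_phantom` builds a tensor volume around the mid-surface
z = z₀ + a·sin(kx), optionally rotated about x, of half-thickness t
(default 3 mm at 1 mm isotropic voxels; a voxel centre is inside iff its
perpendicular distance is strictly below t, so the digitized boundary
coincides with the analytic one).  Tensors are axially symmetric with the
principal direction tangent to the sheet, MD = 1.2×10⁻³ mm²/s (a plausible
neonatal white-matter value; a generator convenience, config-exposed), and
FA following peak·(1 − falloff·(d/t)²) inside (defaults peak 0.7,
falloff 0.5) against 0.05 outside — outside FA sits below the 0.1 tracking
threshold.  Optional additive Gaussian component noise and an optional
high-FA distractor band planted at a configurable offset beyond the
boundary.  The truth object answers signed distance, inside/outside,
expected FA, and tangent/normal fields analytically.

`make_cohort` simulates skeleton FA maps for a cohort with GA at birth
drawn uniformly on [24, 32.86] weeks and PMA at scan on [38.57, 47.14]
weeks — the ranges of a preterm-at-term-equivalent-age population; only the
ranges are emulated, not the empirical age distribution.  Per-vertex FA is
baseline 0.4 plus β·(PMA − mean PMA) on a contiguous 50-vertex patch (grown
breadth-first from the most central vertex), plus an optional GA nuisance
slope, a subject-level offset (SD 0.02) and per-vertex noise (SD 0.02).
All generators are deterministic given their seed.

What the phantoms do **not** emulate: realistic whole-brain anatomy,
crossing fibres, registration error, raw-DWI noise physics (Rician bias,
motion, eddy currents), or spatially correlated vertex noise beyond the
shared subject offset.  Passing tests therefore demonstrate the
correctness of the geometry, projection and inference machinery under known
truth — not robustness to acquisition artifacts.

## Numerical choices and limitations

- Problem sizes in the test and acceptance runs (grids ≈ 22–36 voxels per
  side, skeletons of ≈ 500–2000 vertices, cohorts of 10–30 subjects,
  200-repetition calibration at 500 permutations) were chosen as the
  smallest at which the geometric criteria and the statistical calibration
  are stable.
- Tensor component order is fixed to lower-triangle row order everywhere in
  memory; eigenvector signs are canonicalized for reproducibility.
- Eigenvalues are clamped at 10⁻¹² only inside matrix logarithms; metrics
  elsewhere use raw values (negative eigenvalues from noise trigger a
  warning, not an error).
- The level-set medial extraction assumes a locally orientable sheet; sheets
  that fold back on themselves (normal rotating > 60° from the dominant
  axis) would be truncated by the coherence filter.
- The permutation test permutes subjects as exchangeable units; family
  structure or repeated scans would violate this.
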