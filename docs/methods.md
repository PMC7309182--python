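# Methods

## Overview

`phytoskel` extracts and refines curve skeletons of leafless plant point
clouds. The pipeline has four stages:

1. **Coarse skeleton** — cluster the cloud by quantized geodesic distance
   from a root at the bottom of the plant; cluster centroids become
   skeleton nodes, connected along shortest-path predecessors and reduced
   to a rooted tree.
2. **Axial decomposition** — give every vertex at most one *successor*
   (the child continuing its botanical axis); maximal successor paths are
   the axes. Collapsing axes gives the quotient tree; the *bearing vertex*
   of an axis is the parent of its first vertex.
3. **Curve tree** — fit a β-spline to each axis's vertices and resample it
   to uniform point density; attach each child curve to its parent curve
   so that the child starts on the parent (C_child(0) = C_parent(u₀)) and
   siblings are ordered along the parent axis.
4. **GMM/EM refinement** — treat the curve-tree points S = {s₁…s_m} as
   centroids of isotropic Gaussians and the cloud ℙ = {p₁…p_n} as
   observations of the mixture (plus a uniform outlier component of weight
   ε); displace the centroids by a kernel-smoothed field s′ = s + G·W to
   minimize the negative log-likelihood. For tube-like organs the
   stationary centroids sit on the centerline.

All coordinates are millimetres; nothing converts units.

## Coarse skeletonization

A symmetric k-nearest-neighbour graph (k = 5 by default) approximates the
surface's Riemannian structure; disconnected components are bridged by the
shortest inter-component edge. The root is the lowest-z point (overridable).
Geodesic distances from the root are binned (default width: 2% of the
bounding-box diagonal); each bin splits into connected clusters whose
centroids are skeleton nodes. Cycles are removed by keeping the Dijkstra
shortest-path tree (ties → smaller node id). This centroid construction is
deliberately simple and reproduces the classic artefacts — zigzag near
junctions, off-centre nodes — that the refinement stage corrects. A
user-supplied skeleton can replace this stage entirely.

## β-spline resampling

The blending function β(v) has tension t and skew s with normalizer
δ = t + 2s³ + 4s² + 4s + 2; defaults t = 10, s = 1 (t in [5, 15] works
well). At s = 1 the four active blending values form a partition of unity
for any t, so spline points are affine (indeed convex) combinations of at
most four control points; at t = 10 the weights at integer offsets are
(2/22, 18/22, 2/22, 0). The curve is evaluated with the index window
⌊nu−2⌋…⌈nu+2⌉, out-of-range indices clamped to the endpoints, and each
axis is resampled at N = max(2, ⌈d/d₀⌉) uniform parameters, where d is the
endpoint chord length (bending ignored on purpose) and d₀ = 1.0 mm; the
two terminal samples are truncated to the exact axis endpoints. The clamp
breaks C¹/C² continuity at the ends only; β(v) itself is continuous on its
support.

The approximating character of the spline matters: it low-passes the
zigzag of a degraded control polygon (±0.5 mm alternating offsets shrink
to roughly a third at control parameters and nearly vanish mid-span)
before the EM stage ever runs.

Note the spline is an *approximant*, not an interpolant: on coarse
samples of a curved arc its mid-span sag can slightly exceed the chord
sagitta of the control polyline (≈1.18× at t = 10). Raising t tightens
the fit.

## Curve-tree attachments

Child axes include their bearing vertex as leading control point, so every
child curve starts at the branch point. The attachment parameter is
*parametric*: u₀ = (control index of the bearing vertex)/(parent control
count − 1), realized as the interpolated point of the parent's resampled
polyline at that parameter (stored as segment index + fraction). After any
displacement of the points (perturbation, refinement) the child's first
point is re-synchronised onto the displaced parent polyline, so the
attachment identity holds to machine precision on every curve tree the
package produces. Because bearing vertices are ordered along the parent
axis, sibling attachments are ordered by construction.

An earlier variant snapped child starts to the *nearest* parent sample;
on zigzag-degraded skeletons that search slides attachments up to ~1 mm
along the axis (sampling pitch quantization plus zigzag phase matching),
which dominated the junction-location error. The parametric rule uses the
topological information directly and has no such bias.

## GMM refinement

The mixture density of a cloud point is

    p(p_j) = ε/n + (1 − ε) Σ_i α_ij N(p_j; s_i′, σ²I),

with membership priors α_ij = exp(−α|μ_i − μ_j|) built once from
local-PCA shape descriptors μ = λ₀/(λ₀+λ₁+λ₂) ∈ [0, ⅓] of 20-nearest-
neighbour cloud neighbourhoods (both for cloud points and for skeleton
points — skeleton-set PCA would be degenerate along a 1-D curve). σ² is
initialized to the mean squared pairwise distance over d = 3 and ε to 0.1.

E-step: posterior responsibilities with the uniform component, computed in
log space (max subtraction), so arbitrarily far points underflow to
outlier mass 1 rather than NaN.

M-step: the displacement is parameterized coherently as s′ = s + G·W with
G[i,i′] = exp(−‖s_i−s_i′‖²/(2β²)) and penalty (λ/2)·tr(WᵀG W); the
expected complete negative log-likelihood is then quadratic in W with the
closed-form solution

    (G + λσ²·diag(P1)⁻¹) W = diag(P1)⁻¹ (P_post · P) − S₀,

where P1 are posterior row sums (this matrix is positive definite even
for coincident centroids, so the solve cannot fail; a jitter fallback is
kept as a guard). σ² is re-estimated from the posterior-weighted residuals
over 3ξ (ξ = total posterior mass) and floored at 10⁻⁸ × (bbox diagonal)²;
ε = clip(1 − ξ/n, 0.01, 0.99). Defaults λ = 5, β = 5 mm.

Convergence: the loop stops when the largest relative change among σ², ε
and the mean point displacement (scaled by the bounding-box diagonal)
falls below 10⁻⁴, capped at 100 iterations (a warning flags the cap).
The penalized objective (mixture NLL + smoothness penalty) is monitored
per iteration and is non-increasing in practice; the trace records NLL,
σ², ε and mean displacement.

The refinement is deterministic: no random initialization anywhere.
Everything depends on pairwise distances only, so the refined skeleton is
equivariant under rigid motions applied to cloud and skeleton together.

### Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| d₀ | 1.0 | mm | resampled point spacing; sets m |
| t, s | 10, 1 | — | spline tension / skew |
| λ | 5 | — | displacement smoothness weight |
| β | 5 | mm | displacement coherence length |
| α | 1 | — | membership decay |
| ε₀ | 0.1 | — | initial outlier weight |
| tol | 10⁻⁴ | — | relative-change stopping rule |
| k (PCA) | 20 | points | descriptor neighbourhood |

β is the most consequential: the field G·W cannot express displacement
features much shorter than β, so high-frequency zigzag must be removed by
the spline stage (it is), while the EM corrects the smooth residual
deviation from the centerline.

## Synthetic plants and what they do(n't) show

The generator grows a tree of bounded-curvature random-walk axes (1 mm
steps; branch lengths 20–40 mm; branching angles 30–60°; curvature
0.01 rad/mm by default), records exact junction positions and
branch-segment arc lengths, samples an area-uniform point cloud on tubes
of known radius (default 1 mm) around each axis with radial Gaussian noise
(default 0.02 mm), and can degrade the true centerline into a
coarse-skeleton-like initialization: alternating lateral offsets
(zigzag, default 0.5 mm) on interior axis points, plus an optional drift
of each junction point and its two axis neighbours toward the bifurcating
branch. Junction overlap regions are double-sampled on purpose, mimicking
scan pile-up. Generation is a pure function of (spec, seed).

These clouds are ideal tubes: no leaves, no occlusion, no outlier clutter,
no scanner-specific noise anisotropy. Passing tests therefore demonstrate
the geometry of the method — centering, junction/segment recovery,
convergence — not robustness to real scan pathologies, which the model
explicitly does not attempt (see Limitations).

Study-condition fixtures used by the tests: a straight tube of length
50 mm and radius r ∈ {0.5, 1, 2} mm, ~5000 surface points, 2% radial
noise, zigzag amplitude 0.5 mm giving m ≈ 50 moving points; and a 3-axis,
2-junction "trident" with ~4–5k points. These sizes keep the full suite
in well under a minute per case on one core while leaving the statistics
stable across seeds.

## Evaluation metrics

Junctions are nodes where two or more branches meet. Predicted junctions
are matched to ground truth one-to-one by minimum-cost assignment
(Hungarian), with a cutoff of 5× the mean nearest-neighbour spacing of the
true junctions; unmatched items are counted, not penalized with a
sentinel value. The junction error is ‖ĵ − j‖ divided by the mean
ground-truth segment length (raw mm values are also reported); the
segment error is |L̂ − L| over the same normalizer, with L̂ measured as
arc length along the predicted skeleton polyline between matched
endpoints (polyline arc length rewards geometric fidelity of curved
branches where an endpoint chord would not). Summary statistics follow
box-plot conventions (median, quartiles, 1.5·IQR outliers).

## Known limitations and observed behaviour

- **Axial end contraction.** On a finite tube the posterior mean of a
  centroid near the cap is pulled inward along the axis (~0.5 mm at the
  default σ²), and the β = 5 mm kernel spreads this along the axis. It
  does not affect perpendicular centering, which is what the skeleton
  quality metrics measure laterally, but absolute axial positions near
  branch tips are biased inward.
- **Thick tubes.** As σ² shrinks, a free Gaussian mixture prefers
  centroids displaced toward the surface shell; for radius ≳ 2 mm the EM
  stage can slightly exceed the spline stage's axis RMSE while remaining
  far inside the tube. Very thick, high-curvature stems are outside the
  validated regime.
- **Junction drift.** A junction-ward shift of the initial skeleton is
  inherited by the attachment's position along the parent axis and is
  only partially recovered; the method assumes the initial skeleton is
  reasonably correct near branch points.
- **No leaves / occlusion / heavy noise.** The mixture has a uniform
  outlier component but no structured-noise or missing-data model.
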