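# Methods

`toothwear` simulates the morphological process of occlusal tooth wear
between two states of the same tooth: an intact surface S0 and a worn
surface S1, given as triangle meshes with arbitrary, unrelated
tessellations. The pipeline produces (i) a *homogeneous wear surface* S_h
— S0's connectivity, S1's geometry — which establishes vertex-wise
correspondence, and (ii) a sequence of intermediate wear morphologies with
per-vertex wear-depth maps, optionally scheduled nonlinearly by an
age-calibrated control function. All lengths are millimetres (scanner
scale); the attrition index is the dimensionless 0–4 ordinal score.

## Model and procedure

**Regions.** Wear is confined to the occlusal surface; the axial walls are
unchanged. Each mesh therefore carries a per-vertex occlusal/axial mask
(an input in real workflows, generated automatically by the synthetic
module). The axial region drives rigid alignment and anchors every later
solve.

**Feature identification.** Anatomical landmarks (cusps, ridges, groove
points) are found by Garland–Heckbert quadric-error edge collapse: the
mesh is simplified to a vertex budget n (default 150) and each surviving
vertex is mapped to the nearest original vertex, so features are exact S0
vertices. Collapse order is deterministic — cost ties break on the
lexicographically smallest vertex-index pair. Boundary shape is preserved
with perpendicular constraint-plane quadrics on boundary edges (weight
1e3 × edge length²) rather than a hard collapse ban, so straight boundary
runs remain collapsible while corners survive. Collapses failing the link
condition or folding a triangle are skipped; if no legal collapse remains
the achieved count is reported.

**Selective alignment.** Classic point-to-point ICP pairs each axial S0
vertex with its closest point on S1's axial surface (point-to-triangle, so
the result is independent of target tessellation density) and solves each
round by Kabsch/SVD. The fitted transform is applied to the whole of S0.
Point-to-point ICP converges linearly and can need thousands of rounds for
1e-6-level recovery on smooth walls; the iteration budget is a parameter
(default 50, which aligns already-posed casts; exact-recovery experiments
use 5000).

**Homogeneous surface.** Feature points are projected along their vertex
normals onto S1 (±normal rays, nearest hit, signed: negative = inward
material loss; closest-point fallback when both rays miss). The signed
distances D_i are interpolated over space by a radial basis field

    f(x) = Σ_j λ_j |x − V_j|³ + c0 + c1 x + c2 y + c3 z

solved as the dense symmetric (n+4)×(n+4) system with the four
orthogonality side conditions Σλ_j = Σλ_j V_j = 0 (affine reproduction).
If the system is rank-deficient (coplanar centers leave one polynomial
coefficient free) the minimum-norm interpolant is taken. Evaluating f at
every S0 vertex and offsetting along the vertex normal (axial offsets
zeroed) gives the initial S_h.

**Contraction and bounding.** The residual is removed iteratively. Each
iteration recomputes S_h's vertex normals, projects every occlusal vertex
P_i along its normal to Q_i on S1, evaluates E = Σ|P_i − Q_i| and stops
when E < ε (default 0.001); otherwise each vertex steps
P_i ← P_i + λ(Q_i − P_i) with contraction factor λ = 0.4 — the partial
step limits self-intersection — followed by one 1-ring weighted smoothing
pass (weight 0.5). Axial vertices are pinned throughout, and the run
aborts with a diagnostic if E fails to decrease five iterations in a row.

Two numerical choices matter here:

* *What is smoothed.* The default smooths the per-iteration displacement
  field (each vertex's step is blended with the 1-ring mean step), not the
  positions. Blending positions with the 1-ring centroid — the textbook
  umbrella pass, available as `smoothing="position"` — pulls converged
  vertices off S1 by ~w·h²·κ per pass and puts a floor under E far above
  the summed stopping threshold; on the standard fixture it stalls at
  E ≈ 17 while displacement smoothing reaches E < 0.001 in ~70 iterations
  and also halves the worst-case correspondence error relative to no
  smoothing at all.
* *Ray-length cap.* A normal ray from a rim or fossa vertex can sail past
  the nearby surface and catch a distant sheet of S1; a vertex that chases
  such a hit destroys its correspondence (observed as a millimetre-scale
  outlier). Hits farther than 5× the 99th percentile of the previous
  iteration's residuals are therefore treated as misses and resolved by
  the closest-point fallback.

E is the printed sum over vertices, so ε = 0.001 scales with mesh size;
`mean_error=True` switches the stopping rule to E/m for very dense meshes.
At convergence with m ≥ 1000 occlusal vertices the mean per-vertex
residual is below 1e-6 mm by construction.

**Morphing.** With S0 and S_h in correspondence, intermediate states use
uniform-weight Laplacian (umbrella) coordinates δ = L V, where row i of L
is v_i − (1/d_i)Σ_{j∈N(i)} v_j. Direction and magnitude are interpolated
separately ("bilinear"):

    δ_MU = (1−u) δ_S/|δ_S| + u δ_T/|δ_T|
    |δ_M| = (1−u)|δ_S| + u|δ_T|
    δ_M  = |δ_M| · δ_MU

taken literally — δ_MU is the convex combination of unit vectors, not
renormalized (`renormalize_direction=True` gives the common variant).
Vertices where either magnitude vanishes (< 1e-12) fall back to linear
interpolation of the raw vectors. Positions are recovered from
min ‖L V − δ_M‖² with the axial vertices anchored. Anchors are enforced
exactly by eliminating the anchored coordinates (the uniform L annihilates
constants, so the unanchored system is singular); a soft penalty-row
variant exists for finite anchor weights, but only hard anchoring keeps
the axial region stationary to solver precision across all frames.
Endpoints are exact: u = 0 reproduces S0 and u = 1 reproduces S_h to
solver tolerance, because the corresponding (δ, anchors) pairs are
consistent.

**Wear maps.** Wear depth of a frame is the Euclidean distance of each
vertex from its S0 position; colours map [0, max depth] linearly from
yellow (255,255,0) to red (255,0,0), unworn vertices in neutral grey.

**Nonlinear schedule.** Population surveys give average attrition index by
age. Both columns are min-max normalized to [0,1] and a cubic is fitted by
ordinary least squares, giving the dynamic control function u(t): wear
fraction as a function of normalized age. Fitting uses the two-decimal
rounded normalized table (the form such surveys are published in);
`--unrounded` fits the exact normalization instead. u is clamped to [0,1]
(the fitted cubic is slightly outside at both ends) and schedules are made
non-decreasing by cumulative maximum. For the built-in lower-first-molar
survey (eruption at 8 y, index 0 — life expectancy 78 y, index 4) the
fitted slope is high on t ∈ [0, 0.25], low on [0.25, 0.7] and high on
[0.7, 1], the three classical phases of physiological attrition (immature
enamel, mineralized plateau, exposed dentin).

## Synthetic data

No scan archive exists for this problem, so the `synth` module generates
parametric stand-ins with known ground truth. The intact tooth is a height
field over an ovoid disk — n Gaussian cusps (default 5, height 1.5 mm,
σ 0.9 mm, apices on a ring at 55 % of the 5 mm base radius) minus a
central fossa (0.6 mm), on a gentle dome, with seeded in-plane jitter —
triangulated by Delaunay and extruded into a barrel-profiled axial skirt
(depth 3 mm). The ovoid outline (±6 % radius modulation) and the skirt
bulge are not cosmetic: a surface of revolution with straight walls leaves
rigid registration under-determined in rotation and vertical translation.
Everything is deterministic per seed, byte-for-byte.

Wear is applied as a known smooth depth field along vertex normals —
`uniform-occlusal` (constant depth) or `per-cusp` Gaussian lobes (default
max 0.5 mm, σ 1.4 mm) — with the skirt untouched, and the worn mesh is
optionally retessellated (midpoint subdivision plus seeded random edge
flips) to break all vertex correspondence, mimicking an independent scan.
The standard study fixture is 5 cusps, ~2,000 cap vertices, seed 1,
per-cusp wear of 0.5 mm, retessellated.

What this does *not* emulate: scanner noise and holes, enamel/dentin
material contrast, facet-like wear planes, mesh anisotropy of real
intraoral scans. Passing tests show the pipeline recovers smooth
normal-direction wear on clean manifold meshes; they do not certify
robustness to scan artifacts.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `n_features` | 150 | – | feature-point budget (QEM target) |
| `contraction_factor` λ | 0.4 | – | step fraction toward the projection |
| `epsilon` ε | 0.001 | mm (sum) | stopping threshold on E |
| `max_iterations` | 200 | – | contraction budget (~70 needed on the standard fixture) |
| `smoothing_weight` | 0.5 | – | 1-ring blend of the displacement field |
| anchor weight | ∞ (hard) | – | axial anchoring in reconstruction |
| `n_frames` | 6 | – | u grid 0, 0.2, …, 1.0 (linear) |
| ICP `max_iterations` / `tolerance` | 50 / 1e-10 | – / mm | registration budget and RMS-change stop |

## Degenerate inputs and tie-breaks

Meshes must be edge-manifold and consistently oriented (checked at load;
the first offending face is named); open boundaries are allowed. A
Laplacian requires m ≥ 4 and no isolated vertices. Duplicate RBF centers
are an error (named pair); coplanar center sets fall back to the min-norm
solve. QEM cost ties break on the smallest (i, j); collapse positions use
the quadric optimum when the 3×3 block is well-conditioned (|det| >
1e-9·scale³), else the best of the endpoints and midpoint. Zero-magnitude
Laplacian coordinates degrade to linear vector interpolation. ICP refuses
collinear or coincident source sets.

## Known limitations

* Self-intersection freedom of S_h is not guaranteed, only discouraged by
  λ < 1 and smoothing; the QC counter (`count_self_intersections`) is
  brute-force and meant for meshes up to a few thousand faces.
* Point-to-point ICP assumes roughly posed inputs (same cast); there is no
  global initialization.
* The literal direction blend (no renormalization) slightly under-scales
  δ_M where δ_S and δ_T disagree strongly in direction; the renormalized
  variant is one flag away.
* The control function is a population average; no uncertainty is
  propagated, and index scales other than 0–4 are out of scope.
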