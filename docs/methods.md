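# Methods

## Model

kinheart simulates cardiac beating motion kinematically: instead of
solving force-equilibrium equations, it prescribes *local* myocardial
contractions and recovers the *global* deformation geometrically with
shape-matching dynamics (SMD).

A heart (or test solid) is a tetrahedral mesh with vertices `x_i` in mm.
Around every vertex `i` a **local region** `N_i` is built from the vertex
plus its 1-ring neighbours; neighbouring regions overlap, which is what
couples them into a continuum-like body. Each region carries

- a unit **fiber direction** `f̂_r`,
- a **label** (`atrial`, `ventricular`, `excluded`) selecting its
  time-contraction curve,
- normalized member **weights** `w_{r,j}` (see *Anisotropic stiffness*).

### Contraction

Activation is a periodic piecewise-linear **time-contraction curve**
`c(t) ∈ [0,1]`, optionally phase-shifted per region by a geodesic
**phase-shift field** (distance from source vertices divided by a
propagation speed) to emulate excitation spread without
electrophysiology. The scale along the fiber is

    s_f = 1 − A_mc · c(t),

where `A_mc ∈ [0,1)` is the **maximum contraction rate** (`A_mc = 0.2`
means the region shortens to 0.8× along the fiber at full activation).
The region's contraction matrix scales by `s_f` along `f̂` and by
`1/√s_f` in both transverse directions:

    T_r = s_f f̂ f̂ᵀ + s_f^{-1/2} (I − f̂ f̂ᵀ),   det T_r = 1,

so every locally contracted rest shape keeps its rest volume. The equal
transverse scales make `T_r` independent of any choice of transverse
basis.

### Shape matching and integration

Per frame, for every region: the rest offsets `q̄_j` (member rest
positions minus the weighted rest centroid) are scaled to `T_r q̄_j`; the
weighted best-fit rotation `R_r` from the scaled rest shape to the
current shape is extracted from the 3×3 weighted covariance by SVD polar
decomposition (reflections repaired by flipping the smallest singular
direction); region goals are `g = c_r + R_r T_r q̄_j` about the current
weighted centroid `c_r`. Because vertices belong to several regions,
per-vertex goals are blended with the same weights, renormalized per
vertex so the blend is an affine combination.

**Stiffness iteration**: the goal computation is applied `M` times, each
pass re-matching against the previous goal buffer. Larger `M` propagates
influence farther per frame — a stiffer body.

**Integration** is the explicit goal-seeking update

    v ← γ v + (g − x)/h + h f_ext/m,    x ← x + h v,

with velocity-retention factor `γ` (damping; `γ = 1` is the literal
undamped update). Masses are lumped uniform-density (tet volume split
equally over its corners); only relative masses matter.

**Global volume preservation**: blended goals generally lose total
volume (inconsistent local contractions compromise). A displacement
field of area-weighted outward boundary normals (zero in the interior)
is scaled by a scalar β found by 1-D bracketing + Brent root solve so
the goal configuration recovers the rest volume; after integration a
second, tiny, correction keeps the realized per-frame drift below 1e-6
relative. Correcting the goals rather than the integrated positions is
deliberate: position-only correction displaces vertices without touching
velocities and was observed to destabilize the explicit update on
thin-layer meshes, whereas goal-space correction is stable at every
discretization we tried.

Pinned vertices are hard constraints, reset to rest position with zero
velocity after each step.

### Anisotropic stiffness

Myocardium is stiffer along the fiber than across it. This enters SMD
through the region weights: `w_j ∝ |f̂·q̄_j|^p/‖q̄_j‖^p + ε`, the
direction cosine between a member's rest offset and the fiber, with
floor `ε` so no weight vanishes; members at the centroid get the mean
unnormalized weight; weights are normalized to sum 1. Uniform weights
(`1/n`) recover isotropic elasticity. Because the weighted rest centroid
depends on the weights, the construction is one-pass: offsets about the
uniform centroid → weights → weighted centroid → final rest offsets.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `h` (s) | time step | 0.01 | benchmark value; sheet test uses 0.005 |
| `cycle_T` (s) | cardiac cycle | 1.1 | benchmark value |
| `A_mc` | max contraction rate | 0.5 | cylinder benchmark value |
| `M` | stiffness iterations | 10 | benchmark value; sheet test uses 3 (soft, to make sag visible) |
| `γ` (damping) | velocity retention | 0.9 | periodically driven explicit schemes accumulate energy; 0.9 removes it without visibly lagging the driven response. 1.0 recovers the literal update |
| `ε`, `p` | weight floor / exponent | 0.05, 1 | scale-free weights that never vanish; config-exposed |
| gravity | body force | off (9800 mm/s² in the sheet test) | |

## Procedural geometry

All experiments run on generated solids, so nothing is downloaded:

- **Thick-walled cylinder** (simplified LV): 45 mm inner diameter, 10 mm
  wall, 50 mm length; 1200 vertices by default, split 5 radial × 20
  circumferential × 9 axial elements. The transmural direction gets the
  most vertex layers (six) because the benchmark's defining feature — the
  helix angle varying linearly from +60° (endocardium) to −60°
  (epicardium) — is sampled across the wall; with only 3–4 layers the
  outer high-helix angles are overweighted and axial shortening is
  exaggerated relative to refined meshes. The split was selected by a
  refinement study at the fixed 1200-vertex budget against finer meshes
  (the refinement trend is exercised in the test suite via the analytic
  volume).
- **Thick sheet** 100×100×20 mm for the gravity/anisotropy test, hung as
  a vertical plate pinned along its top face.
- **Idealized LV**: thick-walled truncated half-ellipsoid, closed apex,
  open base (endocardial base radius 25 mm, wall 10 mm, long axis 70 mm —
  a ~92 mL half-ellipsoid cavity, i.e. a physiological end-diastolic
  volume). This is a synthetic stand-in for image-derived anatomy.

Hexahedral index grids are split into tetrahedra with the
Freudenthal/Kuhn 6-tet decomposition, which is conforming on structured
grids (shared faces always receive the same diagonal), including across
the circumferential wrap seam. The LV apex collapses an index ring to a
point; degenerate tets from the collapse are dropped, leaving a
watertight solid.

What the generators do **not** emulate: real chamber anatomy (no atria,
valves, trabeculae, outflow tracts), image-derived fiber architecture,
regional wall-thickness variation, or pericardial constraints. Passing
tests on these solids show the solver reproduces the benchmark
deformation mechanics, not that it predicts any patient's motion.

## Fiber fields

- **Rule-based**: at each vertex a circumferential/longitudinal/radial
  frame is built from the long axis; the fiber is the circumferential
  direction inclined by `α_helix(depth)` toward the axis and tilted by
  `α_trans` toward the radial direction; `α_helix` interpolates linearly
  in the transmural depth. On-axis vertices (undefined radial direction,
  e.g. the LV apex line) fall back to the longitudinal direction with a
  logged warning.
- **Constraint-interpolated**: a scalar depth field is obtained by
  solving the discrete Laplace equation with Dirichlet constraints;
  orientation constraints are interpolated componentwise harmonically
  and renormalized. The Laplacian is the piecewise-linear FEM stiffness
  matrix (3D cotangent analogue) — chosen over uniform graph weights
  because it reproduces linear fields exactly on any tet mesh, which the
  slab depth-field contract requires.

Fiber sign is irrelevant (`T_r` depends on `f̂ f̂ᵀ` only).

## Measurements

- `W` wall thickness: mean outer minus mean inner surface radius, sampled
  in the central 20% of the rest axial extent (falling back to the
  nearest axial plane on coarse meshes).
- `L` vertical length: axial extent.
- `V` spatial (cavity) volume: divergence-theorem volume of the
  inner-labeled surface closed by planar rim caps fanned from each rim
  centroid with patch-induced orientation.
- `S_ext` slant angle: mean inclination of rest-vertical outer edges
  against the current best-fit axis (the rest axis carried by the
  best-fit rigid rotation of the outer surface), so rigid motions read
  exactly 0°.
- LVEF: `100 (V_ED − V_ES)/V_ED` with ED/ES the cycle extrema of `V`.

Plateau read-outs skip the first 40% of the full-activation window so
the short dynamic lag (a few steps at `γ = 0.9`) has died out.

## Fiber-orientation study calibration

The four-orientation cylinder study (uniform 90°, uniform −60°, uniform
0°, transmural +60→−60°) historically tuned each case's `A_mc` on a 0.05
grid against an independent physics simulation of the same muscle model.
That physics solver is outside this package's scope, so the calibration
is emulated with fixed, documented rates (`ORIENTATION_TUNED_AMC`):
transmural and 90° use the benchmark-matched 0.5 (the 90° cavity metric
is insensitive to the rate); −60° matches a non-pumping target, giving
the smallest grid value 0.05; 0° has only a qualitative target and is
fixed at 0.25. The study's qualitative orderings (transmural pumps best;
uniform helices barely pump; circumferential fibers elongate the
cylinder) hold under this calibration; they are properties of the
calibrated protocol, not of any single common rate.

## Numerical choices

- Tets are stored with positive signed volume (loader repairs inversions
  by a vertex swap); surfaces are extracted outward-oriented, so signed
  tet sums and divergence-theorem integrals agree to 1e-9 relative.
- Indexing is 0-based internally; TetGen's 1-based files are converted
  at the boundary.
- Zero region covariance (all members coincident) yields the identity
  rotation with a logged warning.
- The volume root solve brackets β by geometric expansion, capped so the
  largest vertex displacement stays within 10% of the bounding-box
  diagonal; an unbracketable root raises (pathological shape).
- Degenerate tets contribute zero volume; the generators drop tets below
  1e-12 of the length-scale cube.
- The simulation core is fully deterministic: no randomness anywhere in
  the loop.

## Limitations

Purely kinematic: no stresses, pressures, or force–length/velocity
muscle dynamics — deliberately traded for speed, robustness and
controllability. The ejection fraction sweep on the idealized LV shows
the *relative* effects (anisotropic vs. uniform weights, rate
monotonicity); absolute LVEF values depend on the hand-designed fiber
fields and anatomy of whole-heart models that this package does not
ship. No self-collision handling; no implicit integration; no
electrophysiology (the phase-shift field is a kinematic surrogate).
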