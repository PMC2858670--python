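# Methods

`turingfold` simulates cortical-folding-like morphogenesis: a two-species
reaction-diffusion system evolves on a closed triangulated surface and feeds
back on the geometry by displacing vertices along their normals. This note
records the model, the numerical scheme, the parameter choices that define
the package's "stated world", and the limits of what the synthetic setting
can establish.

## Model

### Kinetics

The morphogens are the Gray-Scott pair: a substrate u fed at rate F and an
autocatalyst v produced by the cubic reaction u v² and removed at rate F + k,

    du/dt = Du Δ_S u − u v² + F (1 − u) − d u
    dv/dt = Dv Δ_S v + u v² − (F + k) v − d v

with Δ_S the Laplace-Beltrami operator of the current surface S(t). The
uniform state (u, v) = (1, 0) always solves the static kinetics; for
F ≥ 4(F+k)² two further uniform states exist (v = [F ± √(F² − 4F(F+k)²)] /
(2(F+k)), u = (F+k)/v). Pattern formation here is of the excitable
Gray-Scott type: (1, 0) is linearly stable and patterns nucleate from
finite-amplitude seeds, not from infinitesimal noise.

### Growing-surface dilution

Because the surface grows, concentrations thin where local area expands. In
a Lagrangian frame (mesh vertices are material points, so no convective term
appears) the correction is the dilution rate d = (1/√g) ∂√g/∂t, where √g is
the square root of the surface-metric determinant — per flat triangle,
exactly twice the triangle area. Discretely, d is a backward difference per
face, (√g(t) − √g(t−dt)) / (dt √g(t)), averaged to vertices with
current-face-area weights; the forward geometry is unknowable before the
step, so a backward difference is the only causal choice. On the first
iteration d ≡ 0.

### Surface deformation

Each vertex moves along its outward unit normal (area-weighted average of
incident face normals):

    x_i ← x_i + dt · α · f_i · n_i

with f a linear function of one morphogen. **The default driver is u.**
Away from the pattern u ≈ 1 and the surface expands steadily; inside the
autocatalytic bands u is depleted (u ≈ 0.3), so pattern regions lag behind
the growth and become the concave folds. This choice makes the seeded
perturbation line develop into the reproducible main sulcus (ensemble
reproducibility ≈ 100% on the line, 0% at the poles) and makes total area
grow monotonically. Driving with v instead turns the pattern into outward
ridges whose only reproducible concavities are the non-growing poles — the
opposite reproducibility structure — so v-driven growth is exposed as a
configuration but not the default.

No self-intersection test is performed; runs are kept short and α small
instead, which also mimics the fact that the developing cortex does not
interpenetrate.

## Discretization

### Finite elements

Linear (P1) elements on the triangle mesh. The consistent mass matrix has
per-triangle entries A/6 (diagonal) and A/12 (off-diagonal); the stiffness
matrix is the standard P1 Laplace-Beltrami form K_ij = e_i·e_j / (4A) with
e_i the edge opposite vertex i — algebraically the cotangent formula, and
per-vertex-diagonal A/h_i² with h_i the triangle height. Verified against a
dense quadrature assembly (independent gradient construction, degree-2
quadrature) to 1e-12, and against the spherical-harmonic spectrum: the
generalized eigenvalues of (K, M) on a subdivisions-4 unit icosphere match
l(l+1) = 2, 6, 12 with multiplicities 3, 5, 7 within 2%.

A lumped (row-sum) mass option exists; the default is consistent mass,
which costs a CG solve per field per step but is the textbook P1 operator.
Consistent mass is not monotone: sharp fronts can undershoot v below 0 by
~1e-3 during transients (a warning fires when fields leave [0, 1] by more
than 1e-6).

### Time stepping

Semi-implicit IMEX with the lagged nonlinear coefficient: diffusion, the
linear decay rates, the dilution rate, and v²-as-coefficient are implicit;
the remaining sources (F feed, u v² production in the v-equation) explicit:

    (M + dt Du K + dt L diag[(vⁿ)² + F + d]) uⁿ⁺¹ = M uⁿ + dt F M 1
    (M + dt Dv K + dt L diag[F + k + d])     vⁿ⁺¹ = M vⁿ + dt M (uⁿ (vⁿ)²)

(L = lumped mass). Both matrices are SPD whenever d ≥ −(F+k), so every step
reduces to two Jacobi-preconditioned conjugate-gradient solves (relative
residual 1e-10, warm-started from the previous field). The scheme is
first-order in dt (measured order 0.8–1.2 on a 162-vertex fixture), exactly
preserves the uniform equilibrium (because L1 = M1), and conserves ∫u under
pure diffusion to the solver tolerance (1e-8 relative over 1000 steps).

### Coupled loop

Per iteration: assemble M, K on the current mesh → one IMEX step using the
dilution field left by the previous deformation → displace vertices →
recompute geometry and the new dilution field (same connectivity, before any
refinement) → refine over-grown faces, linearly interpolating u, v and the
dilution field to inserted midpoints → record area (every iteration) and
snapshots (iteration 1, every `snapshot_every`, and the final one).

### Refinement

A face whose area exceeds 2× the mean face area of the *initial* mesh is
split 1-to-4 at its edge midpoints. Neighbours sharing one split edge are
bisected; two split edges → three triangles; three → full 4-way (red-green
refinement, which keeps the mesh a closed 2-manifold with no T-junctions).
Midpoint subdivision is planar per face, so total area is preserved to
machine precision.

## Analysis

- **Mean curvature**: discrete mean-curvature normal, ‖(K x)_i‖ / (2 A_i),
  signed by comparison with the outward vertex normal (positive = convex =
  gyral). A_i is the **Voronoi** vertex area (¼ Σ w_ij |x_i − x_j|² from the
  cotangent weights): the barycentric area misweights the twelve valence-5
  icosphere vertices by ~15%, while the Voronoi form is exact to 1e-5 on a
  sphere; barycentric is the per-vertex fallback where the Voronoi area
  degenerates on strongly obtuse neighbourhoods. Verified at 5% against an
  implicit-surface finite-difference oracle on an ellipsoid.
- **Folds**: the indicator of strictly negative curvature; fold components
  are connected components of the indicator-1 set under mesh-edge adjacency
  (equivalent to region growing, implemented with sparse connected
  components for determinism; cross-checked against a union-find oracle).
- **Temporal stability map A**: per-snapshot fold indicators resampled to a
  reference sphere (both meshes neighbour-mean smoothed, centred, radially
  projected to the unit sphere, then barycentric interpolation on the pierced
  source face), re-binarized at 0.5, and averaged over snapshots.
- **Ensemble map S**: 100 × mean of final-time fold indicators on the
  reference, in percent.
- **Regime classification**: a run is *homogeneous* (lissencephaly-like)
  when the spatial variance of v at the final snapshot is below 1e-6 (covers
  both extinction and convergence to the nontrivial uniform state);
  otherwise the pattern (v above half its maximum) decides: *stripes*
  (normal-like) when pattern coverage ≥ 0.25 of the vertices, *spots*
  (polymicrogyria-like) below. In this world stripe patterns cover ~0.40 and
  spot patterns ~0.12, stable across seeds. Component elongation
  (graph-diameter / √size, size-weighted) is reported as a metric but is not
  the decision variable: a space-filling labyrinth has O(1) graph elongation
  just like a round blob, and sulcal rims around neighbouring spots merge
  into sphere-spanning concave nets, so elongation does not order the
  regimes reliably at these resolutions. The coverage threshold was
  calibrated once on the documented normal/polymicrogyria parameter pairs
  and frozen.

## Parameters (the stated world)

| parameter | default | rationale |
|---|---|---|
| mesh | icosphere, subdivisions 3 (642 vertices), radius 1 | icosahedral tiling avoids polar artifacts; 4 (2562) for geometry-sensitive tests |
| F, k | 0.04, 0.06 | the documented normal-regime pair; (0.03, 0.06) polymicrogyria, (0.05, 0.05) lissencephaly |
| Du, Dv | 2e-3, Du/6 ≈ 3.33e-4 | sets the Turing wavelength to a few tenths of the sphere radius so a dozen-odd folds fit and are resolvable at 642–2600 vertices; the substrate-dominant ratio 6 keeps the low-F spot regime above its extinction boundary at this resolution (with the classic ratio 2 the spot pair goes extinct) |
| dt | 1 | reaction rates ≤ 0.1/time; implicit treatment keeps the step stable |
| α | 7.5e-4 | u-driven growth doubles the radius over ~1500 iterations — deep folds — while the dilution feedback (d ≈ 2α ≈ 1.5e-3) stays well below the regime margins in F |
| horizon | 1500 (scaled; 4000 full) | patterns nucleate by ~500, folds saturate the sphere by ~1200–1500 |
| band half-width | 0.15 rad | covers ~15% of the sphere, a "broad line" seed |
| band values | (0.5, 0.25) | the classic finite-amplitude Gray-Scott seed |
| noise amplitude | 0.05 | uniform in ±0.05 on u and v inside the band: enough to decorrelate realizations without destroying the seed |
| ensemble size | 10 (scaled; 50 full) | reproducibility statistics at minutes of runtime |
| smoothing iterations | 100 | recovers a near-sphere before radial projection for resampling |

The diffusion scale, α, dt, the seed values and the noise amplitude are the
genuinely open knobs of this model family; the defaults above were fixed by
requiring the three documented (F, k) regime labels to be reproduced at the
scaled resolution, and then frozen. All are exposed in `ExperimentConfig`.

## What the synthetic world does and does not establish

The generator *is* the model: there is no external data. Green tests
establish that the discretization is faithful (spectra, conservation,
refinement arithmetic, oracle equivalence) and that the coupled model, at
the frozen defaults, reproduces the documented qualitative phenomenology:
labyrinthine folding with a zero-prefix/rise/plateau fold-count history, a
reproducible main fold along the seeded line with variable topology (1–2
segments across realizations), and the three-regime (F, k) map. They do not
establish quantitative correspondence with foetal cortical development (no
mechanics, no skull, no real-brain geometry), nor robustness of the regime
map far from the calibrated resolution: wavelength-to-domain and
wavelength-to-mesh ratios are part of the stated world, and pushing F, k
toward regime boundaries at other resolutions will move the labels.

## Numerical edge cases

- Degenerate (zero-area) faces raise with the face index; the simulator
  never creates them (midpoint refinement of valid faces is non-degenerate).
- `solve_spd` raises with the achieved residual if CG stalls (cap
  max(200, 10n) iterations).
- Dilution below −(F+k) (pathological shrinkage) raises before factoring a
  non-SPD matrix.
- First simulation step uses zero dilution by convention.
- Resampling falls back from the nearest source vertex's face star to an
  8-nearest-vertex candidate set when a target ray falls outside the star;
  barycentric weights are clamped to ≥ 0 and renormalized, so constants are
  transferred exactly.
- `smooth_mesh` is plain neighbour averaging and therefore shrinks the
  surface; it is used only to regularize meshes before resampling, never in
  the dynamics.
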