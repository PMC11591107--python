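# Methods

## Scope and overall procedure

`stemopt` optimizes the length of a single-wedge femoral stem in a 2D
coronal-plane model of the proximal femur. The pipeline is:

1. generate (or load) a labelled raster — background 0, cortical 1,
   cancellous 2, stem 3 — with per-pixel relative density;
2. solve the **intact** femur under the weighted daily-activity load set to
   obtain reference element energies U₀,i(k);
3. for each candidate length l: resect the femoral head, insert the stem,
   re-mesh, re-solve, and evaluate the cortical stress objective f(l) and
   the cancellous strain-energy change rate g(l);
4. drive l with a golden-section bracket snapped to the pixel grid, subject
   to g(l) < 40%.

Everything is deterministic given the phantom seed; the search itself uses
no randomness.

## Finite-element model

**Elements.** One square bilinear Lagrange quadrilateral per non-background
pixel; shared pixel corners share nodes (two translational DOFs each).
Plane stress with unit thickness (1 mm) — all reported stresses scale
inversely with the assumed thickness, so comparisons across designs are
thickness-independent. Element stiffness uses full 2×2 Gauss quadrature,
which integrates the bilinear B^T D B integrand exactly; for a square
element the matrix is independent of the side length and linear in E, which
the assembly exploits (one unit matrix per distinct Poisson ratio, scaled by
each element's modulus).

**Materials.** Cortical 22.5 GPa / ν 0.30; Ti-6Al-4V stem 114 GPa / ν 0.32;
cancellous bone from the density power law with E₀ = 15 GPa. The law as
commonly printed gives E(1) = 2.8623 GPa, which contradicts the companion
statement that cancellous tissue reaches E₀ at ρ = 1; both readings ship
(`law_variant="as_printed"`, the default, and `"normalized"`, rescaled so
E(1) = E₀) and the discontinuity at ρ = 0.84 is preserved in both — no
smoothing is applied. Marrow is carried as cancellous material at ρ = 0.01
(E ≈ 4.8 MPa) rather than removed, so the mesh stays simply connected.

**Boundary conditions.** Surface loads are split equally across the selected
surface nodes, so each resultant matches the case magnitude exactly; angles
are measured from the vertical shaft axis, positive medially. The head load
(downward) acts on the superior arc of the femoral head (intact) or
prosthetic head (implanted). The trochanteric load's direction is not
anatomically fixed by its magnitude; the default treats it as the abductor
muscle pull — upward-medial at the case angle — because a downward
trochanteric force leaves the lateral trochanteric bone unloaded in the
intact state, which is not how a femur carries daily loads. The convention
is per-case configurable (`trochanter_vertical="up"|"down"`). The lowest
node row is fully clamped, but only nodes adjacent to bone pixels: a stem
tip reaching the model base must not anchor directly into the support,
which would open an artificial load bypass and make the longest stem
spuriously optimal.

**Solver.** Sparse Cholesky-style LU (SuperLU) of the reduced system, one
factorization per model reused across the three load cases; residuals are
checked against 1e-8·‖f‖ and the energy identity Σ U_i = ½ fᵀu is asserted
to 1e-9 in the tests.

**Stress recovery.** σ_x, σ_y are evaluated from the element B-matrix at the
four corner local coordinates (±1, ±1) and combined as √(σ_x² + σ_y²) — per
element and node, with no inter-element averaging, no shear term and no von
Mises equivalent (a von Mises option exists for sensitivity studies only).
This is the simplest reading of a stress measure indexed by element *and*
node, and it keeps the objective a plain sum of well-defined quantities.

## Functionals

* **g — strain-energy change rate** (%): weighted per-case mean over shared
  cancellous elements of (U₀,i − U_i)/U₀,i. Elements whose pixel was
  resected or became stem drop out; elements with U₀,i < 1e-12 N·mm are
  excluded (the ratio is numerically meaningless; exclusions are counted and
  reported); marrow-density elements (ρ ≤ 0.02) are excluded because their
  near-zero intact energy would otherwise dominate the average. Summands
  keep their sign — elements that gain energy contribute negatively; an
  absolute-value variant is available for sensitivity analysis. g is
  invariant under uniform load scaling.
* **f — cortical stress objective**: the weighted sum of all four corner
  stresses over all evaluated cortical elements (default), or the weighted
  per-case maximum (`objective_mode="max"`). The prose description of the
  design goal ("minimize the maximum stress") and the printed formula (a
  weighted sum) differ; the sum is the default and every output records
  which mode produced it.
* **Evaluation sets**: S_can and S_cor cover the whole cancellous/cortical
  regions except a 5 mm St-Venant layer of cortical elements above the
  clamped base — the clamped section cut raises a mesh-dependent corner
  singularity there that would otherwise dominate both f and the maximum
  stress. Shallow unit-test meshes keep the full set.

## Optimization

Bounds l ∈ [68.75, 117.25] mm (lesser trochanter to model base, measured
from the fixed stem shoulder), grid step equal to the pixel size, stop when
the bracket width reaches three grid steps, constraint threshold 40%.
Golden-ratio probe points are snapped to the grid (ties resolve toward the
current bracket midpoint); infeasible probes receive an infinite objective;
when the bracket closes, every remaining grid point in it is evaluated and
the feasible minimum returned (ties go to the shorter stem). If the final
bracket holds no feasible point the whole grid is scanned before declaring
the problem infeasible. Candidate evaluations are cached by length, and the
per-candidate field solutions are reused across different case weightings,
so the four optimizations of the loading-condition comparison share FE
solves. The trace records every bracket, flags probe patterns inconsistent
with a unimodal objective (the golden-section answer may then be local), and
counts FE evaluations, which are bounded by
2 + 2·⌈log(stop/initial)/log 0.618⌉ plus the final-bracket points.

At the reference image scale the grid step is 0.05 mm and the stop interval
0.15 mm; desk-scale runs use 0.5 mm pixels with the same 1:3 step:stop ratio.

## The synthetic phantom

No clinical image ships with the package, so the phantom module generates
the study geometry analytically: overall 100.4 × 131.2 mm, femoral head
offset 44.6 mm, neck–shaft angle 128°, rasterized at a chosen pixel size
(0.5 mm default → 263 × 201 px, ≈ 24,700 elements). Its features, and why:

* **Closed cortical shell** whose thickness ramps from 1.6 mm around the
  head/trochanter to 5 mm along the diaphysis (a raster needs ≥ 2 px of
  shell, enforced with a diagnostic); the model base is treated as a section
  cut, not a free surface, so no shell wraps around it.
* **Density field**: a smooth proximal-to-distal gradient plus dense ridges
  along the principal compressive (head → calcar) and tensile (head →
  greater trochanter) trabecular arcs. The arcs matter: without them the
  homogenized interior is entirely shielded by the shell in the intact
  state, and stem insertion can only *add* energy to it, inverting the
  shielding trend. Optional seeded Gaussian texture is available
  (`noise_amplitude`); the default is the smooth field, so results are
  bit-reproducible regardless of seed.
* **Marrow canal** at ρ = 0.01 along the diaphyseal axis.
* **Smoothed outline**: the analytic outline is a union of capsules and
  discs whose junction tangent breaks would act as artificial stress
  raisers; a morphological closing/opening in the polygon domain rounds
  them before rasterization. The stem polygon is smoothed the same way.
* **Single-wedge stem**: fixed shoulder/neck/head section, distal wedge that
  stretches with the design length, so profiles at two lengths are
  identical above the wedge start. The quoted implant width (57.8 mm) spans
  the whole mediolateral envelope including the head offset and is stored
  as metadata; the geometry is built from explicit shoulder, tip, neck and
  head parameters. Resection is a plane perpendicular to the neck axis
  through the neck-base saddle; stem pixels may overwrite background and
  cancellous bone but never cortical bone (hard error naming the first
  offending pixel).

**What the phantom does not emulate.** Real femora are 3D; trabecular
micro-architecture is homogenized into a density field; bone–stem contact is
a perfect bond (no press-fit, micromotion or ingrowth); loads are static.
Consequences visible in the results: at mesoscale resolution the one-element
layer bonded to the implant is a non-trivial fraction of S_can, and its
energy *gains* outweigh the diffuse shielding of the far field in the signed
per-element average, so phantom-scale g values are negative (≈ −70…−90% at
0.5 mm) where a 50 µm micro-FE model reports positive rates of 9–32% — there
the interface layer is a vanishing fraction of millions of elements. What is
scale-robust, and what the tests assert, is the *structure* of the problem:
g increases monotonically with stem length (more stem, more shielding
change), the stress objective has an interior minimum, and the optimized
length therefore sits strictly between the bounds with
g(shortest) < g(optimized) < g(longest). Passing tests demonstrate that
structure on the phantom, not agreement with any clinical or micro-FE
magnitude.

## Numerical choices and degenerate inputs

* Node numbering is row-major over pixel corners, DOF order (ux, uy); any
  consistent scheme works — this one is fixed for reproducibility.
* Assembly enforces exact symmetry by averaging K with its transpose
  (summation order across the diagonal differs in floating point).
* Disconnected label regions are reduced to the largest edge-connected
  component with a warning; an empty image is an error.
* A zero load vector short-circuits to zero displacement; an all-fixed or
  unconstrained system raises before factorization.
* Grid snapping uses a 1e-9 relative tolerance for tie detection; lengths
  outside the bounds clamp with a warning.
* Raster IO: labels as 8-bit PNG, density as a float array file, metadata
  (pixel size, origin, seed, landmarks) as a JSON sidecar; round-trips are
  lossless and files with labels outside {0..3} or missing sidecar keys are
  rejected by name.

## Known limitations

Single design variable (length only — neck–shaft angle, offset and thickness
are fixed); 2D plane stress; bonded interface; static loads; the shielding
average is a single scalar that does not localize where energy changes even when the
constraint is met (it can hide local gains); phantom-level magnitudes (stresses in MPa, g in %) are
meaningful only relative to other lengths on the same phantom.
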