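# Methods

## Scientific problem

Fruit firmness is routinely assessed with a puncture test: a small flat-ended
cylindrical probe is driven into the intact fruit at constant speed while the
reaction force is recorded against insertion depth. The first force peak — the
*bioyield point* — marks the onset of tissue rupture; its force and
deformation are the firmness metrics used to track post-harvest softening.
This package builds a finite-element model of the papaya puncture test,
detects the bioyield point on the simulated force–deformation curves, and
validates the model against a packaged table of measured bioyield forces and
deformations for three storage intervals (0, 4, 7 days) and three probe
speeds (1.5, 2, 2.5 mm/s).

## Model

### Geometry and mesh (`punctfem.mesh`)

The sample is modelled as the local axisymmetric cross-section under the
probe: a cylinder of radius 15 mm and depth 20 mm, with a 1 mm band of skin
elements over flesh and a 2 mm-diameter rigid flat probe on the axis.
Meshes are structured tensor-product bilinear quadrilaterals in (r, z):
uniform cells of at most `target_h` (default 0.5 mm) under the probe
footprint (r ≤ 2a) and in the near-surface band, grading geometrically
(ratio ≤ 1.3) up to `refinement_ratio × target_h` toward the far boundaries.
The skin/flesh interface always falls on a grid line and the skin band always
contains at least two element rows. Element quality (aspect ratio, scaled
corner Jacobians) is reported by `mesh_quality`; snapshots are exported as
legacy-ASCII VTK unstructured grids.

### Material model (`punctfem.material`)

Skin and flesh are isotropic bilinear elastoplastic solids: linear elastic
with modulus E up to the yield stress σ_y, then linear hardening with tangent
modulus Et (perfectly plastic at Et = 0). The equivalent isotropic hardening
modulus is H = E·Et/(E − Et). Poisson's ratio follows from moisture content
MC (%) via ν = (0.5·MC + 0.1·(100 − MC))/100, a linear blend between the
fully-fresh incompressible limit (0.5) and the dried-tissue value (0.1);
density comes from cylindrical specimen mass and dimensions. Parameter sets
can be read from the packaged min/avg/max measurement-level grid
(`table_params`) or extracted from uniaxial stress–strain records
(`fit_bilinear`, which fits the through-origin elastic slope, locates the
departure point and intersects the two fitted lines to recover σ_y).

### Finite-element solver (`punctfem.solver`)

Axisymmetric small-strain FE on 4-node quads with 2×2 Gauss quadrature and
B-bar (mean dilatation) treatment of the volumetric terms, which prevents
volumetric locking at the near-incompressible ν ≈ 0.44 of fresh tissue.
Stresses use the Voigt convention [rr, zz, θθ, rz] with engineering shear.
Plasticity is J2 flow with bilinear isotropic hardening, integrated by the
radial-return map; the quasi-static driver assembles the consistent
algorithmic tangent for quadratic Newton convergence.

Contact with the rigid flat punch is a frictionless node-to-rigid-surface
penalty: per-node stiffness proportional to the stiffest layer modulus and
the node's tributary annular area. Candidate nodes are the exposed top
surface under the footprint, tracked on the structured grid so that columns
whose elements have eroded expose the surface beneath (*eroding contact*).
Rupture is modelled by element erosion: an element whose maximum Gauss-point
equivalent plastic strain reaches `eps_p_max` (default 0.5) is permanently
deactivated, its stress zeroed, and the configuration re-equilibrated at the
same punch depth so the recorded force reflects the post-rupture state.

Two drivers are provided:

- **Quasi-static** (default): displacement-controlled punch depth in fixed
  increments with Newton iteration, bisection on non-convergence, and
  erosion/re-equilibration cycles. The constitutive model is
  rate-independent, so probe velocity only sets the time axis; the
  validation study therefore simulates one curve per storage day and reuses
  it across velocities.
- **Explicit central-difference**: lumped mass, CFL-limited time step
  (including a contact-spring bound dt ≤ safety·√(m/k)), optional
  mass-proportional damping and a `time_scale` factor for runtime control.
  It exists for velocity-dependent and severe-erosion scenarios and is
  verified against the quasi-static peak force.

Units are a consistent mm–N–MPa–s system; densities are converted to
tonne/mm³ internally.

### Bioyield detection and statistics (`punctfem.metrics`)

The bioyield point is the first local maximum of the moving-average-smoothed
force after which the force drops by more than `drop_fraction` (default 5%)
of the peak *without first rising above it*; the reported values are read off
the unsmoothed curve at the nearby raw maximum. The validation statistic is
the relative error RE = |measured − simulated|/measured × 100. The module
also runs the material-level sensitivity study (percent force decrease
between the all-max and all-min property levels) and fits the through-origin
quadratic velocity-effect relation Δ = a·v² + b·v.

### Calibration and validation (`punctfem.validation`)

Measured tissue properties span wide ranges, so each storage day gets its own
parameter set constrained to the measured min–max bounds. A *level fraction*
λ ∈ [0, 1] interpolates every property of a tissue piecewise-linearly through
min (0), avg (0.5) and max (1). Calibration is a deterministic inverse
analysis per day: a joint coarse grid over (λ_skin, λ_flesh) — shared across
days through a memoised runner — followed by one refined scan per axis around
the best cell, minimising the mean relative error of the simulated bioyield
force against that day's measured forces, under a simulation budget.
Validation then reports per-condition relative errors and summary statistics
as a deterministic CSV/JSON report.

## Synthetic data (`punctfem.synth`)

Generators mirror the instrument and specimen statistics so every pipeline
stage can be exercised without fruit: puncture curves sampled at 200
points/s at the study's probe speeds over the 10 mm insertion range, with a
linear rise to the bioyield peak, a sharp drop, and a fluctuating
penetration plateau (seeded sinusoid plus optional multiplicative noise);
truncated-normal material-property samples about per-day means; and noisy
bilinear stress–strain records. All generators are pure functions of their
spec and seed, hence bit-reproducible. The bioyield deformation is snapped
onto the sampling grid so the constructed peak is exactly representable,
which makes zero-noise recovery by the detector exact.

## Numerical choices

- `target_h = 0.5` mm with `refinement_ratio = 4` is the shipped default;
  halving `target_h` changes the pre-bioyield force by under 5% in the
  refinement test.
- Penalty scale 100× the layer modulus balances penetration error against
  conditioning; the elastic patch test with a stiffer penalty (1e6) matches
  the exact uniform-compression solution to ~1e-7.
- Newton tolerance 1e-9 on the relative force residual, with stagnation
  acceptance at the round-off floor and bisection of the depth increment on
  non-convergence.
- The quasi-static study stops 30% below the running peak
  (`stop_after_drop = 0.3`), which truncates the post-rupture plateau the
  bioyield metrics do not use.

## Verification

The test suite checks the solver against closed-form oracles: a uniaxial
patch test (exact), Sneddon's rigid flat-punch stiffness F = 2E*aδ on a
converged elastic mesh (within 10%, observed ≈ 5%), a strain-driven uniaxial
radial-return trace against the bilinear law (1e-8), the degenerate elastic
limit Et = E with non-yielding σ_y (1e-10), energy bookkeeping (non-negative,
non-decreasing dissipation), mesh-refinement consistency, determinism, and
exact zero-noise recovery of generator parameters by the bioyield detector.

## Limitations

- Small-strain kinematics: the ~2 mm insertion at bioyield over a 1 mm skin
  band implies locally large strains; rupture depth is therefore more
  uncertain than rupture force, and simulated bioyield deformations deviate
  more from measurement than forces do.
- Erosion with a fixed equivalent-plastic-strain threshold is a coarse
  rupture model; the threshold is a calibration-range choice, not a measured
  quantity.
- The sensitivity spread between the all-min and all-max property levels is
  governed directly by the 8× span of the skin yield stress, so the
  simulated percent force decrease between level extremes is much larger
  than between calibrated storage days.
- Quasi-static mode cannot show probe-velocity effects by construction;
  explicit mode can, but its rate sensitivity comes from inertia and
  damping, not from a measured viscoelastic law.
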