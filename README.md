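# punctfem

Finite-element modelling of the fruit puncture test, built around papaya.

A flat-ended 2 mm probe is driven into intact fruit at constant speed while
the reaction force is recorded; the first force peak (the *bioyield point*)
marks tissue rupture and is the standard firmness metric used to track
post-harvest softening. `punctfem` models this test as an axisymmetric
elastoplastic contact problem — a thin skin layer over flesh, J2 plasticity
with bilinear hardening, penalty contact with the rigid probe, and element
erosion so the probe can actually puncture — then detects the bioyield point
on the simulated force–deformation curves and validates the model against a
packaged table of measured bioyield forces for three storage intervals
(0, 4, 7 days) and three probe speeds (1.5, 2, 2.5 mm/s).

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

Simulate one puncture of an average-property papaya and extract the bioyield
point:

```python
from punctfem import (DomainSpec, ProbeSpec, SolverConfig, build_mesh,
                      detect_bioyield, table_params)
from punctfem.solver import solve_quasi_static

mesh = build_mesh(DomainSpec(), target_h=0.5, refinement_ratio=4.0)
materials = {"skin": table_params("skin", "avg"), "flesh": table_params("flesh", "avg")}
probe = ProbeSpec(radius=1.0, velocity=1.5, max_insertion=10.0)
result = solve_quasi_static(mesh, materials, probe,
                            SolverConfig(increment=0.02, stop_after_drop=0.3))
metrics = detect_bioyield(result.curve)
print(f"mesh: {mesh.n_elems} elements, {mesh.n_nodes} nodes")
print(f"bioyield force:       {metrics.bioyield_force:.2f} N")
print(f"bioyield deformation: {metrics.bioyield_deformation:.2f} mm")
print(f"rupture detected:     {metrics.rupture_detected}")
print(f"erosion events:       {len(result.erosion_history)}")
```

Output (a few seconds on one CPU):

```
mesh: 252 elements, 285 nodes
bioyield force:       17.15 N
bioyield deformation: 2.26 mm
rupture detected:     True
erosion events:       4
```

The same run is available from the command line, along with the full study,
calibration, synthetic data and curve metrics:

```bash
punctfem simulate --out run/            # one puncture, CSV + JSON summary
punctfem validate --out report/         # calibrate + validate all 9 conditions
punctfem synth --out synth/ --seed 1    # synthetic puncture curve
punctfem metrics run/force_deformation.csv
```

## Package layout

- `punctfem.material` — bilinear elastoplastic parameters, moisture/density
  formulas, stress–strain fitting, packaged property-level grid.
- `punctfem.mesh` — layered axisymmetric domain, graded structured quad
  meshes, quality metrics, VTK export.
- `punctfem.solver` — axisymmetric FE with B-bar elements, radial-return J2
  plasticity, penalty contact, element erosion; quasi-static (Newton) and
  explicit (central-difference) drivers.
- `punctfem.metrics` — force–deformation curves, bioyield detection,
  relative-error statistic, sensitivity study, velocity-effect fit.
- `punctfem.synth` — seeded generators of puncture curves, property samples
  and stress–strain records.
- `punctfem.validation` — per-day calibration (grid + refinement inverse
  analysis), nine-condition validation, deterministic reports.
- `punctfem.cli` — `punctfem` command-line interface.
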