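# myoperf

Personalized, multiscale coronary and myocardial blood-flow modelling at desk
scale: closed-loop 0D (lumped-parameter) circulation surrogates, synthetic
vascular tree growth by constrained constructive optimization, Voronoi
perfusion-territory mapping of myocardial blood flow (MBF), single-compartment
Darcy perfusion on a tetrahedral LV mesh, diameter-law versus
perfusion-imaging-informed boundary conditions, and along-branch FFR.  A
seed-reproducible synthetic-patient generator stands in for clinical imaging so
the full personalization pipeline runs from nothing but a seed.

## Layout

| module | role |
| --- | --- |
| `myoperf.core_model` | domain types, CGS unit conventions, VTK/JSON I/O |
| `myoperf.synthetic_patient` | LV shell mesh, epicardial tree, MBF field, clinical targets |
| `myoperf.territories` | Voronoi perfusion territories, MBF integration, flow fractions |
| `myoperf.cco_trees` | synthetic tree growth (CCO), terminal allocation, radius scaling |
| `myoperf.network0d` | RCL circuits, coronary outlet blocks, closed-loop assembly |
| `myoperf.lpn_solver` | backward-Euler DAE integration, steady solves, FFR, cardiac metrics |
| `myoperf.darcy` | Darcy perfusion FEM (linear tets, zero-flux), per-territory MBF |
| `myoperf.tuning` | Stage-1 cardiac-function and Stage-2 flow/pressure personalization |
| `myoperf.cli_pipeline` | `myoperf` CLI and end-to-end orchestration |

## CLI

```sh
myoperf make-patient --seed 1 --out patient/           # mesh.vtk, tree.json, targets.json
myoperf territories --mesh patient/mesh.vtk --tree patient/tree.json \
    --out territories.csv --labeled-mesh labeled.vtk
myoperf grow-trees --mesh patient/mesh.vtk --tree patient/tree.json \
    --n 500 --seed 1 --out trees/
myoperf tune-cardiac --targets patient/targets.json --restarts 2 --out stage1.json
myoperf run-pipeline --seed 1 --trees --mode mpi --out run-mpi/
myoperf run-pipeline --seed 1 --trees --mode murray --out run-murray/
myoperf compare run-mpi run-murray --out summary.csv
```

`run-pipeline` executes territories -> synthetic trees -> 0D tuning at
hyperemia -> Darcy MBF -> FFR and writes per-outlet flow-fraction and
per-territory MBF comparison tables, FFR curves, a labelled MBF mesh, and a
reproducibility manifest.  The 2x2 design (with/without trees x
imaging-informed/diameter-law targets) is covered by the `--trees/--no-trees`
and `--mode` flags.

## Conventions

All internal computation is CGS (cm, g, s; pressures in dyn/cm^2, flows in
mL/s, resistances in dyn.s/cm^5).  Interface values use clinical units (mmHg,
mL/min, mL/min/100 mL) and are converted exactly once at the boundary
(1 mmHg = 1333.22 dyn/cm^2).  Meshes are VTK legacy ASCII tetrahedral grids;
vessel trees and 0D networks are JSON; all tables are CSV.
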