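# serpmix

Simulation toolkit for optimizing polymeric-nanoparticle production in a
glass **serpentine micromixer**.  PLGA nanoparticles form by nanoprecipitation
when a polymer solution (PLGA at 7 mg/mL in acetonitrile) mixes with an
aqueous anti-solvent (TRIS buffer) inside the chip; what the process engineer
controls is the total flow rate (TFR) and the flow-rate ratio (FRR) of the
two streams.  `serpmix` answers the questions that drive that choice in
silico, so formulation screening needs fewer wet experiments:

* **How hard can I push the pumps?**  A 0D lumped hydraulic network
  (Hagen–Poiseuille straights, Dean-corrected bend losses
  K = 32R(0.026·Dn·e^0.661 + 1)θ/(D_h·Re)) finds the limit TFR at the
  cartridge burst pressure (800 mbar).
* **How do the streams mix?**  A deterministic 2D steady laminar
  finite-volume solver (collocated, Rhie–Chow momentum interpolation,
  monolithic velocity–pressure coupling, bounded second-order species
  transport) resolves the solvent mass-fraction field Y on a body-fitted
  structured mesh of the whole serpentine (10 μm cells by default).
* **Where can particles actually form?**  Beyond the classical mixing index
  MI_j = (1 − √(Var_j/Var₁))·100 and mixing efficiency
  ME = (1 − N_unmixed/N_tot)·100, the package computes the
  **area of precipitation** AoP% = area(0.7 < X_ACN < 0.95)/area·100 — the
  solvent-concentration window where the polymer nucleates — and, per AoP
  cell, the **residence time** τ_res = L_i/v_i (centerline distance to the
  outlet over local speed), filtered by the mixing time
  τ_mix = w²/(9·D·(1 + 1/FRR)²).
* **Does the simulation match the real chip?**  An image-validation pipeline
  extracts transverse RGB profiles from channel micrographs (border
  detection, edge trimming), renders the simulated profiles through a
  two-endpoint colormap, and reports per-section percentage differences; a
  seeded synthetic-micrograph generator stands in for the microscope.

## Worked example

The 0D model, on the reference chip (straights L2 = 2.5 mm, L3 = 5.6 mm,
13 × 13 mm; bends R = 800 μm; duct 200 × 100 μm):

```bash
$ serpmix limit-tfr --burst-mbar 800
limit TFR at 800 mbar: 0.2640 ml/min
drop at 0.2 ml/min: 600.9 mbar
```

So the chip tolerates up to ~0.26 ml/min, and the 0.2 ml/min working point
sits safely below the burst pressure — consistent with uninterrupted
operation of the physical cartridge.

The field solver and metrics, from Python:

```python
from serpmix import *
from serpmix.chip_geometry import ChipSpec, build_chip, generate_mesh, locate_sections
from serpmix.mixing_metrics import compute_metrics

spec = ChipSpec()                      # reference serpentine
chip = build_chip(spec)
mesh = generate_mesh(chip, 10.0)       # 10 um cells -> 421,980 quads
op = OperatingPoint(0.2, (1, 1))       # TFR 0.2 ml/min, FRR 1:1
bc = BoundaryConditions.from_operating_point(op, spec, mesh)
flow, species = solve_coupled(mesh, bc, MixtureModel(), SolverSettings())
rep = compute_metrics(mesh, locate_sections(chip, mesh), flow, species,
                      op, MixtureModel().D)
print(f"AoP = {rep.aop_pct:.1f}%  MI(outlet) = {rep.final_mi:.1f}%  "
      f"tau_res median = {rep.tau_res_median:.2f} s  "
      f"v median = {rep.v_median:.2f} m/s")
```

```
AoP = 14.5%  MI(outlet) = 76.7%  tau_res median = 0.90 s  v median = 0.16 m/s
```

Read: at 1:1 the precipitation window covers ~15% of the chip and stretches
along most of its length, the outlet stream is ~77% homogenized, and a
forming particle in the window typically has ~0.9 s to grow before leaving
the chip.  Raising the dilution to 1:7 collapses the window to the first
bends (AoP ≈ 0.5%), slows the in-window fluid and lengthens the residence
times — the hydrodynamic signature behind the coarser, less uniform
particles observed at high FRR.

The full study (all FRRs, tables, VTK fields, optional synthetic-image
validation) runs from a YAML config:

```bash
serpmix simulate --config run.yaml     # writes table4.csv, mi_me_by_section.csv, fields_*.vtk
serpmix validate-images --config run.yaml --frr 1:1
```

## Layout

| module | role |
| --- | --- |
| `serpmix.chip_geometry` | parametric chip, centerline path, structured quad mesh, measurement sections |
| `serpmix.lumped_model` | 0D hydraulic network, Reynolds/Dean numbers, bend losses, limit TFR |
| `serpmix.flow_solver` | 2D laminar flow + species transport (coupled or SIMPLE, Y-dependent mixture properties) |
| `serpmix.mixing_metrics` | MI, ME, AoP, τ_mix, τ_res, study summaries |
| `serpmix.image_validation` | micrograph processing, synthetic micrographs, RGB comparison |
| `serpmix.cli_io` | YAML config, pipeline orchestration, VTK/CSV I/O, CLI |

See `docs/methods.md` for the models, assumptions, numerical choices and
known limitations.
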