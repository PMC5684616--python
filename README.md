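# gbspheroid

Hybrid discrete-continuum (HDC) simulation of glioblastoma tumour-spheroid
growth, with the full in-silico analysis pipeline built on it: parameter
sweeps over doubling time, cell size and proliferation depth; monoclonal vs
polyclonal clonal competition; and parameterization/calibration of the model
against in-vitro growth measurements (hanging-drop spheroid assays of the
U87MG reference line and patient-derived primary glioblastoma lines).

## The model

A central 2D slice of the spheroid lives on a square lattice of side
*L* = 5 mm where each *h* × *h* site (*h* = 14–20 µm) holds at most one cell.
Two compartments advance together on an 8 h iteration clock τ:

**Discrete compartment (cellular automaton).** Each cell carries a phenotype
(doubling time *dt*, proliferation depth *r*) and an age. Cycling cells age
by τ per iteration; on reaching *dt* a cell searches the Moore rings
*k* = 1..*r* around it for an empty site, takes a uniformly random empty site
from the first non-empty ring, pushes the intervening cells one site outward
along the Chebyshev geodesic when *k* ≥ 2, and places an age-0 daughter in
the vacated adjacent site. A cell that finds no space within depth *r*
becomes quiescent: its age freezes and it re-attempts division every
iteration. The bounded pushing range *r* is the model's proxy for mechanical
contact inhibition. Cells die only where oxygen falls below a threshold
*o*<sub>deadly</sub> (disabled by default; see `docs/methods.md`).

**Continuous compartment (oxygen).** Nondimensional oxygen obeys

∂o/∂t = D ∇²o − c(i,j) γ − α o,

with c(i,j) = 1 at occupied sites, Dirichlet boundaries locked at the
maximum concentration (periodically refreshed medium), nondimensionalized by
o_max, τ and L, and advanced one Peaceman–Rachford ADI step per iteration.

Simulations seed 625 cells as a compact disc (the hanging-drop seeding
count) and report projected area *A(t)* = (occupied sites)·*h*² in mm².

## Worked example

```python
from gbspheroid import SimulationConfig, run, equivalent_radius

rec = run(SimulationConfig(seed=1))   # defaults: 18 um cells, dt 25.5 h, r=2, 10 days
print(rec.area_mm2[0], rec.area_mm2[-1], rec.total_cells[-1],
      rec.quiescent_cells[-1], equivalent_radius(rec.area_mm2[-1]))
```

prints (seed 1):

```
0.2025  0.8592  2652  2037  523.0
```

i.e. the seeded disc of 625 cells (0.2025 mm²) grows to 0.8592 mm²
(2652 cells, equivalent radius 523 µm) after 10 simulated days; 2037 interior
cells are quiescent — the spheroid expands through its proliferative rim
while the core is contact-inhibited.

The same run from the shell, plus the other pipeline stages:

```bash
gbspheroid simulate --seed 1 --out out/          # growth_record.csv + manifest
gbspheroid sweep --param depth --reps 20 --out out/sweep
gbspheroid polyclonal --n-phenotypes 100 --reps 50 --out out/poly
gbspheroid synth --dt 30.8 --out out/synth       # synthetic in-vitro tables
gbspheroid estimate --cell-counts out/synth/cell_counts.csv \
    --cell-areas out/synth/cell_areas.csv --out out/params
gbspheroid calibrate --spheroid-areas out/synth/spheroid_areas.csv \
    --line GBP06 --out out/fit
```

`estimate` fits doubling times by log-linear regression on daily cell counts
and mean diameters from segmented cell areas; `calibrate` grid-searches the
proliferation depth *r* ∈ 1..5 that minimizes the RMS discrepancy between
simulated and observed growth curves (this is how the primary lines GBP06
and GBP08 resolve to *r* = 4 and *r* = 3 while U87MG and GBP03 stay at
*r* = 2).

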