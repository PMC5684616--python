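# Methods

## Model overview

The package couples a lattice cellular automaton (one cell per site) to a
reaction–diffusion oxygen field on the same grid. The domain is a square of
side L = 5 mm; the lattice spacing equals the cell size h, so the grid side
is n = floor(1000·L/h) sites (277 at h = 18 µm). One iteration advances the
model by τ = 8 h:

1. one ADI step of the oxygen PDE;
2. removal of cells whose local oxygen is strictly below o_deadly;
3. cycling cells age by τ; every age-ripe cell (age ≥ doubling time)
   attempts division in a uniformly shuffled order.

A division searches Moore rings k = 1..r outward and uses a uniformly
random empty site from the first ring containing one. For k ≥ 2 the cells on
the Chebyshev-geodesic chain toward the target are each shifted one site
outward (the chain is fully occupied by construction, because rings < k were
full); the daughter occupies the vacated 1-Moore site. Pushing never
cascades beyond the chain and never crosses the domain boundary. A cell with
no reachable empty site becomes quiescent: age frozen, division re-attempted
every iteration. Quiescence is reversible the moment space appears.

## Parameters

| parameter | default | meaning |
|---|---|---|
| L | 5 mm | domain side (hanging-drop well scale) |
| h | 14–20 µm (18 default) | cell and lattice size |
| τ | 8 h | iteration time |
| doubling time | per phenotype, 15.5–35.5 h studied | division clock |
| r | 1–5 (2 default) | proliferation depth (contact-inhibition range) |
| initial cells | 625 | hanging-drop seeding count, compact disc |
| γ | 6.25e-17 M cell⁻¹ s⁻¹ | per-cell oxygen consumption |
| o_max | 6.7e-6 M cm⁻³ | oxygen scale (opaque: only o* = o/o_max is used) |
| α | 0.0125 (ND) | oxygen decay rate |
| D_o | 1e-5 cm²/s | oxygen diffusivity — not reported by the source study; this is the standard literature value, exposed in config |
| o_deadly | 0 | hypoxic death threshold (see below) |

## Conventions the reference description leaves open

These were decided once, on modelling grounds, and are exposed as config
switches where noted:

- **Age residual on division** (`age_policy`): default `carry` (parent age ←
  age − dt), so the effective division interval averages dt instead of being
  quantized up to the next multiple of τ (`zero` resets to 0 and gives an
  effective dt of ceil(dt/τ)·τ, e.g. 32 h for dt = 25.5 h at τ = 8 h).
- **Initial ages** (`initial_age_mode`): uniform on [0, dt) per cell, to avoid
  artificial synchronized division waves.
- **Update order**: age-ripe cells are processed in a uniformly shuffled
  order each iteration. Implementation note: divisions only ever consume
  empty sites (a push relocates the empty target along the chain and the
  daughter fills the vacated end), so cells with no empty site within the
  maximum depth at the start of the iteration provably cannot divide in it
  regardless of order. The update therefore shuffles only the ripe cells
  that can see space (a dilation of the empty mask); this is
  distribution-identical to shuffling all cells and is what makes a
  277²-grid run take well under a second.
- **Push geometry**: the sign-step (Chebyshev-geodesic) chain; every step
  reduces the Chebyshev distance to the target by exactly 1.
- **Area metric** (`area_metric`): occupied sites × h² by default (the
  in-silico mass has no internal voids, so this tracks segmented projected
  area); a convex-hull metric over the occupied cell squares is available
  for sensitivity checks and always bounds the site-count area from above.
- **Day-10 read-out**: the record at exactly 10·24 h (iteration 30 at τ = 8 h).

## Oxygen numerics

The PDE is nondimensionalized by o_max, τ and L: D* = D_o·τ/L² (= 1.152 at
defaults), α* = α (given nondimensional), and the per-cell sink
κ* = γ·τ/(o_max·h³) — one cell consuming from its own site volume. This
volumetric conversion is the one genuinely underdetermined scale in the
model (the sink has units M cell⁻¹ s⁻¹ against a concentration field);
κ* can be overridden directly in config.

One Peaceman–Rachford ADI step advances the field per iteration: half the
reaction (decay everywhere, consumption at occupied sites) explicitly,
implicit tridiagonal solves along rows then columns for diffusion, the other
reaction half, then clamping to [0, 1] with boundaries re-locked at 1. The
diffusion solve operates on the deviation w = o − 1 (zero Dirichlet), which
makes the uniform-1 zero-reaction field an exact fixed point in floating
point. The solver is validated three ways: an explicit-Euler oracle at
time-resolved coefficients (max-norm agreement ≤ 1e-3 on grids up to 41²),
exact symmetry preservation, and the discrete maximum principle at
production coefficients. At production coefficients the single big ADI step
acts as a quasi-steady solve of the stiff balance between the Dirichlet
boundary and the interior sink — the standard regime for this model class.

**Hypoxic death is off by default** (o_deadly = 0, and death requires
oxygen *strictly* below threshold). With the volumetric κ* above, interior
oxygen saturates at the clamp 0 for any spheroid more than a few cells
thick, so any positive threshold would necrose the whole core — behaviour
incompatible with the reference growth curves, which grow monotonically and
report no necrosis. The death machinery is fully implemented and tested
with user-set thresholds; whether the original study ever triggered it is
not recoverable from its description.

## Experiments

Monoclonal sweeps run 20 seeded replicates per condition (replicate count
not fixed by the reference; 20 gives a day-10 area CV of ~0.5%) and report
mean day-10 areas plus percent increases between consecutive parameter
values. The polyclonal driver draws n ∈ {10, 100} doubling times i.i.d.
uniform on (15.5, 35.5) h per replicate, assigns them uniformly to the 625
seeded cells (frequencies not stated by the reference), runs 14 days × 50
replicates, and reports mean ± SD area curves plus the doubling-time
envelope of surviving clones. With death disabled no clone goes extinct, so
the surviving min/max are constant; selection of the fastest clone appears
in the cell-count-weighted mean doubling time, which declines toward the
minimum as the fastest clone overpopulates the rim.

## Estimation and calibration

- Doubling time: OLS of ln(count) on time in hours ("exponential linear
  regression" in its standard reading); dt = ln2/slope, SD by the delta
  method from the slope's standard error; a direct nonlinear exponential fit
  is available for sensitivity. Day-0 counts are included unless flagged.
- Cell size: mean equivalent-circle diameter 2·sqrt(area/π) of segmented
  areas.
- Growth curves: per (line, day) mean ± sample SD (n−1); single replicates
  report SD 0 with a logged caveat.
- Depth fitting: integer grid search r ∈ 1..5 (the explored range)
  minimizing the RMS discrepancy between the observed curve and the mean
  simulated curve (linear interpolation to observation days; optional
  SD weighting; ties break toward smaller r). The reference line
  parameterization is dt = 33/25/23/22 h and r = 2/2/4/3 for
  U87MG/GBP03/GBP06/GBP08, with a common 18 µm cell size by default
  (per-line measured sizes 21.5/19/16/15 µm optional — they do not change
  the line ordering).

## Synthetic data

The generators emulate the *structure* of the three in-vitro tables with
known ground truth: daily counts N0·2^(24d/dt) with multiplicative
log-normal noise of median 1 (counts are positive; hemocytometer error
scales with the count; default CV 10%); cell areas from truncated-normal
diameters (default CV 10%, n = 10 cells); spheroid-area replicates from a
simulator curve sampled at 2-day intervals with additive Gaussian noise
(default CV 5%, 24 replicates, matching the assay layout). They do not
emulate the 2–4 day aggregation lag, medium-renewal effects, or the
post-day-8 decline of the real curves — so recovery tests validate the
estimators and the fitting machinery, not the biology of the real assays.

## Known limitations and discrepancies

- 2D central slice only; no motility, adhesion, ECM, or post-day-8
  inhibitory effects (all outside the model's scope).
- The model is exactly scale-free in h while oxygen is inert: day-10 area
  ratios between cell sizes reduce to (h₂/h₁)², i.e. ~30.6/26.6/23.5% for
  14→16→18→20 µm — a decreasing sequence, where the reference reports an
  increasing 21.5/29.8/31.1%. No update-rule convention can reverse that
  ordering without an h-dependent mechanism.
- Sequential updates with the quiescence rule lose 15–20% of rim divisions
  to contention (a ripe cell whose reachable empties were consumed earlier
  in the iteration freezes and loses the iteration). The reference's
  depth-sweep increments imply a nearly frictionless front (r lattice layers
  per doubling time), which no ordering tested here achieves; its
  doubling-time increments are likewise mutually inconsistent under any
  single age-reset convention (one pair matches `carry` within 0.3 points,
  the other matches `zero` within 0.2). Both conventions are provided;
  defaults follow the carry policy throughout, and the shipped reproduction
  tests report the resulting values honestly.
- fit_depth recovery rates are validated on simulator-generated synthetic
  observations at reduced domain size (L = 2.5 mm) — the recovery property
  is scale-independent and the reduced domain keeps the grid search fast.
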