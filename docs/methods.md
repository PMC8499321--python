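# Methods

## Model overview

The simulator is a discrete-time, individual-based model of a clonal
bacterial population on a two-dimensional patch lattice. The physical
system it idealizes is a monolayer of *Pantoea* cells on a thin slab of
rich medium (605 μm × 605 μm × `depth` μm). Space is discretized into
square patches of side `patch_side_um` (default 5 μm; the coarser 10 μm
lattice, 61×61 patches, is used for campaign work). Each patch holds two
extensive quantities — glucose-carbon and ammonium-nitrogen, in grams — and
at most `pmax` live cells. Cells are sessile; the only movement is the
placement of daughters into a neighbouring patch when the mother's patch is
full, which is how colonies spread.

Initial nutrient masses follow from the configured concentrations and the
patch volume `V = patch_side² · depth · 10⁻¹⁵ L`: glucose-C
`= mM·10⁻³·V·6·12.011 g`, ammonium-N `= mM·10⁻³·V·14.007 g`. Founder cells
are placed uniformly at random subject to the per-patch cap, with initial
biomass drawn from the cell-geometry model below.

### Cell mass

Cells are spherocylinders with length L ~ N(1.1, 0.5) μm and width
W ~ N(0.55, 0.25) μm, resampled until L ≥ W > 0. Wet mass is volume times
1.1 g/cm³; biomass-carbon is wet mass × `dry_fraction` (default 0.3) × the
carbon mass fraction of the biomass formula C₄.₁₇H₈O₁.₇₅N (≈0.500,
recomputed from atomic masses rather than hard-coded). The dry:wet ratio is
not a measured quantity for this organism; 0.3 is a standard bacterial
value and is exposed in the run configuration.

### Tick update

One tick represents `steptime` minutes. Order of operations:

1. Both nutrient fields are redistributed: a patch keeps `(1−D)` of its
   mass and sends `D/8` to each existing 8-neighbour. Edge patches retain
   the shares of missing neighbours. This operator is linear,
   mass-conserving to machine precision, and the identity at `D = 0`.
2. Metabolism, for every live cell. Gross glucose demand over the tick is
   `(μmax/60)·dt · S/(K_S+S) · m/efficiency` (m = biomass-C, S = patch
   glucose concentration). When a patch is over-demanded, the available
   glucose is shared in proportion to demand. Maintenance
   `M = 0.0015·(dt/60)·m` gC is paid first and respired. If realized
   uptake U ≥ M, the surplus is split: `ΔC = efficiency·(U−M)` becomes
   biomass, the rest is respired, and `ΔC·(14.007/(4.17·12.011))` gN is
   drawn from patch ammonium — growth is re-limited to the
   nitrogen-feasible amount and the glucose not needed for the realized
   growth stays on the patch. The starvation clock resets. If U < M the
   cell does not grow, respires what it took, and its starvation clock
   advances by `dt`.
3. Death: a cell whose starvation time exceeds 83 min is removed; its
   carbon moves to a dead-biomass ledger (no lysis or recycling).
4. Bipartition: cells with biomass ≥ 2× their birth mass and ≥ 20 min
   since their last division split into two equal halves. The daughter
   goes on the mother's patch if below `pmax`, else on a uniformly random
   non-full 8-neighbour, else the division is deferred (the mother keeps
   her mass). Both cells restart age and birth-mass bookkeeping at the
   halved mass.

Cell-level contention (division placement) is resolved in a freshly
shuffled order each tick from the run's seeded generator; nutrient sharing
is proportional and therefore order-free. A run is fully determined by
(parameter set, seed).

Metabolism here is deliberately simple: a fixed-yield stoichiometric
partition with `efficiency = 0.37`, i.e. a single thermodynamic constant
standing for the full catabolic/anabolic reaction bookkeeping of
thermodynamic metabolic models. The half-saturation constant `K_S` is not
constrained by any measurement in this setting; the default is 0.5 mM
glucose and it is exposed in configuration — at campaign glucose levels
(median 50 mM) uptake is essentially saturated, so results are insensitive
to K_S except near depletion.

### Mass accounting

Two global ledgers close exactly: total carbon
(field glucose-C + live biomass-C + dead biomass-C + respired-C) and total
nitrogen (field ammonium-N + N bound in live and dead biomass at the
formula ratio). The test suite asserts relative drift < 10⁻⁹ across
randomly configured runs; in practice drift is at the 10⁻¹⁶ level.

## Curve summaries

The growth portion of each viable-count curve is fitted to the modified
logistic `y(t) = A/(1+exp(4μ/A·(τ−t)+2))`, whose parameters are the
plateau A, the maximum slope μ (attained at the inflection) and the lag
time τ (tangent-at-inflection intercept). The growth window runs from the
first sustained increase (first point above the initial level by 2% of the
dynamic range, stepped back one sample) to plateau onset (first point
within 2% of the maximum), extended by a few samples to anchor the
asymptote; both thresholds are configurable. Initial guesses are
A₀ = max(y), μ₀ = steepest finite-difference slope, τ₀ clipped to ≥ 0;
parameters are bounded non-negative. A fit counts as converged only when
the optimizer succeeds and R² ≥ 0.9 on the window; non-converged curves
(flat, all-zero, monotone-decreasing, die-outs) are excluded from
replicate averages and a configuration with no converged replicate is
dropped.

Two fit spaces are supported and computed side by side in campaign
datasets: raw counts (A in cells, μ in cells/h) — the primary space — and
`log_ratio`, fitting ln N(t)/N(0) so that μ is a specific growth rate in
h⁻¹. The lag time is a time in both spaces but is not numerically
identical between them: in count space the exponential phase itself looks
flat on a linear axis, so τ_counts > τ_log for the same curve.

## Campaign design

Seven active inputs are sampled independently and uniformly on their
grids: `umax_pa` 0.1–10 h⁻¹ step 0.1; `diffusion_coefficient` 0–1 step
0.01; `pmax` 1–10; `glucose` 0–100 mM step 0.1; `depth` 10–50 μm;
`microorganism` 10–1000 founders; `steptime` ∈ {0.1, 0.6, 1.1, 1.6} min.
Duplicate configurations are resampled so all are distinct. The six
remaining parameters are fixed (efficiency 0.37, maintenance 0.0015
gC·gC⁻¹·h⁻¹, rep 20 min, viability 83 min, ammonium 18.7 mM, world 605 μm).
Uniform independent sampling is the minimal assumption given no stated
design; space-filling designs are deliberately out of scope.

The full-scale protocol is 3,358 configurations × 4–6 replicates (≈18,000
runs, hours of CPU). Desk-scale work — the test suite and the acceptance
script — uses 120 configurations × 4 replicates on the 61×61 lattice with
an 18 h horizon (~480 runs, a few minutes on one CPU). Replicate seeds are
a pure function of (master seed, configuration id, replicate index) via a
seed-sequence hash, so any row can be reproduced in isolation and the
dataset is independent of worker count and completion order.

## Random-forest analysis

Per steptime subset and output, features (the six non-constant inputs) are
z-scored with training statistics (tree ensembles do not need this, but it
keeps one preprocessing convention across models), a random search over six
hyperparameter families (trees 100–1000, depth ∅/10–50, min-split
{2,5,10}, min-leaf {1,2,4}, features-per-split {all, √p, p/3}, bootstrap
on/off) is scored by 3-fold CV R², and the best model is refit and scored
on the held-out 30%. Gini importances are normalized to sum to one;
permutation importance is the mean R² drop over 10 seeded shuffles.
The default search budget is 50 candidates (20 in the time-boxed
acceptance checks); the candidate count is a free budget choice and is
exposed everywhere.

## Network surrogate

A single dense network (7 inputs → 30 → 15 → 3 outputs; ReLU hidden
layers, linear output; 753 trainable parameters) predicts ⟨A⟩, ⟨μ⟩, ⟨τ⟩
jointly across all steptimes. Implementation is scikit-learn's
`MLPRegressor`: Adam, learning rate 0.01, MSE loss, batch 50, 300 epochs,
no early stopping, dropout or weight decay. Inputs and outputs are min-max
scaled to [0,1] with scalers fitted on training data only (the stricter
convention; test values may fall outside the unit interval and are not
clipped). Evaluation: 3-fold CV MAE on the normalized scale, then a
retrain on the full 70% split with the same schedule, reporting normalized
test MAE and per-output R² after inverse-transforming predictions.

## Numerical choices

- Division threshold is 2× the cell's own birth mass with an equal split;
  no asymmetry is modelled.
- The uptake-vs-maintenance comparison uses a 10⁻¹² relative epsilon so a
  last-ulp rounding of a proportionally shared uptake cannot flip the
  exact U = M boundary into the starvation branch.
- Nutrient fields are clipped at zero after subtraction; the clipped mass
  is below 10⁻¹⁵ of a patch's content and ledger closure is asserted at
  10⁻⁹.
- Metabolism and diffusion inner loops are numba-compiled kernels;
  accumulation order matches the index order of the array formulation, so
  results are deterministic.
- Logistic fitting clips the exponent at ±700 to avoid overflow.
- `train_test_split` puts round(0.7·n) rows in training.

## What the generator does and does not emulate

The simulator generates the study's own data; there is no external input.
It captures substrate-limited, spatially heterogeneous colony growth with
hard local crowding, immediate-start growth kinetics and mass-balanced
turnover. It does not model adaptation lag (cells begin growing at once,
so fitted lag times reflect only the first division wave — minutes to an
hour — not the multi-hour adaptation seen in plate experiments),
three-dimensional growth, motility, lysis/nutrient recycling, or any
fluorescence measurement process. Two structural consequences are worth
keeping in mind when comparing against wet-lab or other simulation
results: the 20-min minimum inter-division time bounds the
population-level specific growth rate by 60·ln2/20 ≈ 2.08 h⁻¹ no matter
how large `umax_pa` is, and with rich glucose the plateau is set by the
crowding capacity `pmax` × patch count rather than by nutrient exhaustion,
so ⟨A⟩ responds primarily to `pmax` and the growth inputs. Passing tests
therefore certify internal consistency (conservation, determinism,
recovery of known curve parameters, learnable input–output structure) —
not agreement with any particular laboratory system.

## Known limitations

- Dead cells vanish from the lattice (they do not occupy capacity) and
  their carbon is never recycled.
- The steptime parameter rescales all rates consistently, so model
  behaviour is nearly steptime-invariant by construction; steptime acts
  only through discretization granularity. Analyses that expect strong
  steptime effects will find little signal here.
- Sub-patch spatial structure (cell geometry beyond mass, orientation,
  contact mechanics) is absent.
- The desk-scale campaign (120 configurations) leaves ~20–40 rows per
  steptime subset; forest importances at that size carry substantial
  sampling noise, which is why the larger search budgets and the
  full-scale protocol exist.
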