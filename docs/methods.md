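# Methods

## Model

The environment is a rectangular box (default 1 × 1 m) discretized into a
32 × 32 grid of bins; position is the one-hot vector **r** over the 1024
bins, so every firing field is a length-1024 vector.  Bin centers sit at
((i + 0.5)·width/nx, (j + 0.5)·height/ny) with row-major indexing — the
center convention avoids boundary bias in field evaluation.

Entorhinal cells are a fixed bank **E** (locations × cells); the response
to a location is the corresponding row, **s**ₑ = **E**ᵀ**r**, optionally
plus additive Gaussian noise γₙ·**n** (unclipped — the model equations add
noise directly, and the network tolerates transiently negative drive).
Every field column is rescaled to a maximum of exactly 1.

Hippocampal rates are the solution of the non-negative ℓ1-sparse coding
problem for the current input, computed by the locally competitive
algorithm (LCA): membrane potentials follow τ·du/dt = −u + **A**ᵀ**s**ₑ −
**W s**, with rates s = max(u − β, 0) and **W** = **A**ᵀ**A** − **I**.  At
a fixed point the active units satisfy the KKT stationarity condition
aᵢᵀ(**s**ₑ − **A s**) = β, which the test suite verifies against an
independent bounded quasi-Newton minimizer on small instances.

Learning is online: one location per epoch, Δ**A** = η(**s**ₑ −
**A s**ₕ)**s**ₕᵀ, negative entries clipped to zero, updated columns
renormalized to unit Euclidean length, and **W** refreshed from **A**
after every update.  **W** is held fixed during the integration steps of a
single presentation (it is a parameter of the dynamics, not a state
variable).

## Input generators

**Idealized grid cells** are sums of three cosine gratings with
wavevectors of magnitude 4π/(√3 λ) spaced 60° apart, affinely scaled so
the field lies in [0, 1] with peaks exactly λ apart on a hexagonal
lattice; peak value 1 occurs at the phase origin.  Populations enumerate
the Cartesian product of Nλ spacings (geometric from 28 cm, ratio 1.42 —
so 28, 39.76, 56.46, 80.17 cm; at most four fit the 1 m box), Nθ
orientations evenly covering [0°, 60°) and Nx × Ny phases evenly covering
[0, λ)².

**Realistic grid cells** place one bump γᵥ·exp(−ln 5 · d²/σ²) (value γᵥ/5
at distance σ) on every vertex of the hexagonal lattice intersecting the
box padded by 3σ, with σ = 0.32 λ and per-vertex amplitudes γᵥ ~ N(1,
0.1) capturing field-to-field variability.  Populations draw each cell
from one of four spacing modules (means 38.8/48.4/65/98.4 cm, SD 8 cm;
orientation means 15/30/45/0°, SD 3°; mixture 43.5/43.5/6.5/6.5%).  The
module allocation of a finite population uses deterministic
largest-remainder apportionment followed by a seeded shuffle, so counts
are reproducible (600 cells → 261/261/39/39).  Sampled spacings are
redrawn until positive; orientations wrap modulo 60°.

**Weakly spatial cells** assign i.i.d. uniform(0, 1) activation to every
bin, smooth with a Gaussian kernel of SD 6 cm (1.92 bins; reflective
boundaries, avoiding edge dimming), and min-max rescale to [0, 1].

**Stretched arena**: the box width and grid resolution scale by the
stretch factor and each grid field is re-evaluated at compressed x
coordinates from its stored closed-form parameters (lattice vertices and
amplitudes for realistic cells), so the firing pattern deforms with the
environment.  Weakly spatial fields carry no regeneration rule and cannot
be stretched.

**Trajectories** are smoothed random walks sampled at 20 Hz: heading
performs a wrapped Gaussian random walk (SD 0.2 rad per sample) and speed
a mean-reverting process around 25 cm/s (stationary SD 5 cm/s, clipped at
zero), with reflective walls.  Any smooth, space-filling walk with the
stated mean speed and rate serves; a one-hour walk visits ≥ 95% of bins
and its empirical mean speed is within 5% of target, both asserted in
tests.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ | 10 ms | membrane time constant of the rate dynamics |
| β | 0.3 | firing threshold = ℓ1 penalty weight |
| dt, steps | 0.8 ms, 200 | Euler integration per presentation (16 τ total) |
| η | 0.03 | online learning rate (0.01 for weakly spatial inputs) |
| epochs | 20,000 | presentations (30,000 for weakly spatial inputs) |
| N_h | 100 | hippocampal population size |
| K | 10⁵ | reverse-correlation samples for field recovery |
| γₙ | 0 | SD of additive response noise (0.3 in the noise experiment) |

## Analysis pipeline

Field recovery presents K uniformly sampled locations and averages the
one-hot location vectors weighted by each cell's noise-free converged
rate.  Because locations are discrete, this is computed exactly as a
multinomial visit-count weighting of per-location responses — identical in
distribution to sequential sampling but requiring at most 1024 inference
calls.  Cells with zero total response are flagged silent and counted as
non-place cells (the field normalization is undefined at zero).

Each field is fitted by nonlinear least squares with the isotropic model
Q(x, y) = γ·exp(−ln 5·((x−x_c)² + (y−y_c)²)/σ²), initialized at the map
maximum (σ₀ = 10 cm), with bounds γ ≥ 0, σ ∈ (0, box diagonal], center
within the box padded by 10 cm.  The fit error is (‖F − Q‖₂/‖F‖₂)², an
unweighted whole-map relative squared residual.  A cell is a place cell
iff the fit succeeded, error < 0.15, and σ > 5 cm; the reported "radius"
of a place field is the fitted σ.

Tiling statistics: d_PF is the Euclidean distance from every bin center to
the nearest fitted place-field center; d_ND of a center is the maximum of
its two smallest distances to other centers (second-nearest neighbour;
defined for ≥ 3 centers).  Population sparseness is the fraction of cells
with rate strictly above zero, averaged over all 1024 locations (rates are
exactly zero below threshold, so no cutoff parameter is needed); the power
ratio is mean(s_e²)/mean(s_h²) over all cells and locations.

## Numerical choices

- Euler update order: rates are computed from the current potentials,
  then potentials are updated, once per step (synchronous); potentials
  reset to zero at every presentation so the zero-input fixed point is
  exact.
- Exactly 200 integration steps are run per presentation; no convergence
  test.  A guard aborts with a diagnostic if |u| exceeds 10⁶, and the
  configuration rejects dt/τ ≥ 2 (forward-Euler leak stability).
- The training loop is a JIT-compiled kernel (numba) over explicit loops;
  reference vectorized implementations of inference and the learning step
  are kept as the public functional API and tested to agree with the
  fused kernel to 1e-10.
- Dictionary columns whose norm collapses to zero after clipping (never
  observed in the standard runs) are re-randomized from a seeded pool and
  the event is counted on the returned state.
- All randomness flows through one explicitly passed numpy Generator;
  training is bitwise reproducible under a fixed seed.

## Design notes

- The model is packaged as a scikit-learn style transformer
  (`SparseCodingPlaceMap`): `fit` learns the dictionary from the
  location-by-cell response matrix, `transform` returns sparse rates.
  The functional API (`init_network`, `lca_infer`, `learning_step`,
  `train`, …) shares the same kernels.
- Module proportions must sum to 1 (tolerance 1e-9); degenerate mixtures
  such as (1, 0, 0, 0) are allowed and used by the single-module presets.
- In the stretched-arena experiment the learned connection **A** is kept
  fixed; only recovery runs on the stretched population.
- Preset experiments default to single runs per seed; the acceptance
  tests average three replicate seeds because initialization, training
  locations and sampled grid parameters are all stochastic.

## Problem sizes and runtime

The published configurations run in full: 600 input cells, 100 (or 20)
hippocampal cells, 20,000-30,000 training epochs, K = 10⁵ recovery
samples.  One such run takes ~15-60 s on one CPU (weakly spatial inputs
are slowest because their codes are denser).  Unit tests use reduced
networks (81 inputs, ≤ 30 units, ≤ 5000 epochs).

## Known limitations

- The generators emulate idealized statistics (stationary fields, exact
  module structure, uniform phases, i.i.d. smoothed noise); real grid
  cells show conjunctive tuning, theta modulation, and boundary effects
  that are absent here, so passing tests speak to the model mechanism,
  not to fits of recorded data.
- Measured population sparseness of the learned map (~9% co-active cells
  at β = 0.3) and the weakly-spatial place-cell yield (~79/100) deviate
  from some published point values while all spatial tiling statistics
  agree; see the test suite for the exact tolerances checked.
- Firing-rate dynamics are rate-based and memoryless across
  presentations; spiking, phase precession, 3D environments and the
  biological circuit implementation of the competition are out of scope.
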