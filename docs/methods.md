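# Methods

## Model

`evapkmc` simulates the drying of a particle-laden liquid film as a
lattice gas on a 3D cubic lattice. The domain is a `D x D x (H+1)` prism:
layer 0 is an immobile substrate, layers `1..H` hold the film
(`H = round(z*D)` for aspect ratio `z`). Each cell is exactly one of
substrate, liquid, vapor, or a one-cell particle. Lateral boundaries are
toroidal; the region above the top layer is treated as permanent vacuum
that interacts like vapor (zero coupling), i.e. the film is open to the
ambient from above.

The energy is

```
E = -c * Σ_<ij> w_ij [ ε_ll l_i l_j + ε_ln (l_i n_j + n_i l_j) + ε_nn n_i n_j
                      + ε_ls (l_i s_j + s_i l_j) + ε_ns (n_i s_j + s_i n_j) ]
    - μ Σ_i l_i
```

where `l`, `n`, `s` are the liquid/particle/substrate indicators, the sum
runs once over every unordered nearest (`w = 1`) and next-nearest
(face-diagonal, `w = 1/√2`) pair — 6 + 12 neighbors per cell — and
substrate–substrate pairs are excluded (they never change).
`c = 1/(1+√2)` rescales the widened stencil so that the summed bond weight
of a fully coordinated cell is `c*(6 + 12/√2) = 6`, exactly the
coordination of a nearest-neighbor-only lattice gas. With `ε_ll = 1` this
puts bulk liquid/vapor coexistence at `μ = -3`; simulations run at
`μ < -3`, where vapor is the equilibrium phase and the film evaporates.
The substrate wets like bulk liquid: `ε_ls = ε_ll`, `ε_ns = ε_ln`
(overridable).

Dynamics are Metropolis Monte Carlo. One MC step is:

1. **Evaporation/condensation.** Every liquid and vapor cell is visited
   once, in a freshly shuffled order, and proposes to toggle
   liquid ↔ vapor. The toggle is accepted with probability
   `min(1, exp(-ΔE/kT))` and takes effect immediately (sequential
   updating).
2. **Particle transport.** Every particle makes `N_mov` attempts to hop to
   a uniformly drawn nearest-neighbor cell; the hop is evaluated (same
   Metropolis rule) only if the target is liquid — particles move only
   within the solvent, so a particle with no liquid neighbor is frozen.
   The direction is drawn before the target is checked, so immobilized
   particles consume the RNG stream identically.

`ΔE` is computed from the local 18-cell stencil; unit tests verify it
against a slow full-Hamiltonian reference (`total_energy`) to 1e-9.
Particle count is conserved exactly; liquid is exchanged with an implicit
reservoir through the `μ` term.

## Chemical-potential schedule

The effective `μ` folds the disjoining pressure of a thinning film into a
single evaporation bias and is allowed to depend on the dried-substrate
fraction `ν` (lateral sites whose layer-1 cell holds no liquid):

```
μ(ν) = μ0 - δ / (1 + exp(-(ν - ν_c)/σ))
```

a logistic step: `μ ≈ μ0` while the substrate is mostly wet, dropping by
the jump magnitude `δ` around the critical coverage `ν_c` with sharpness
`σ`. A tanh parameterization would be equivalent up to rescaling of
`σ` and `δ`; the logistic convention is fixed here. `μ` is refreshed once
per MC step from the current `ν`, so the run trace tabulates `μ(ν)`
directly. The midpoint identity `μ(ν_c) = μ0 - δ/2` and the saturation
limits are asserted in tests.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| `D` | lateral side | 400 | cells |
| `z` | film aspect ratio (`H = round(z*D)`) | 0.05 | — |
| `phi` | particle volume fraction | (required) | — |
| `eps_ll` | liquid–liquid coupling | 1 | energy unit |
| `eps_ln` | liquid–particle coupling | 1.5 | `ε_ll` |
| `eps_nn` | particle–particle coupling | 2 | `ε_ll` |
| `kT` | thermal energy | 0.2 | `ε_ll` |
| `n_mov` | particle move attempts per step | 20 | — |
| `mu0` | initial chemical potential | −3.7 (constant) / −3.45 (sigmoidal) | `ε_ll` |
| `delta` | sigmoidal jump magnitude | 0.15 | `ε_ll` |
| `sigma` | jump sharpness | 0.01 | in `ν` |
| `nu_c` | critical dried coverage | 0.15 | — |

`ε_ll = 1` fixes the energy unit, and `kT` is expressed in it
(0.17–0.25 is the physically interesting window). `ε_ln = 1.5` sits midway
between `ε_ll` and `ε_nn = 2`, making a lone particle solvated neutrally;
it is exposed as a configuration parameter. The simulation is fully
dimensionless; the analyzer's `cell_size` (nm per cell) is metadata used
only to report physical areas.

## Randomness and reproducibility

A single `numpy.random.Generator` stream drives a run: initial particle
placement, then per-step sweep shuffling, direction draws and acceptance
draws, in that fixed order. The Monte Carlo hot loops are numba-compiled
and advance the same bit-generator state, so replaying a seed reproduces
the grid and trace bit-for-bit (the CLI writes byte-identical artifacts).

## Termination and trapped solvent

A run stops when no liquid remains or after `max_steps`. In practice,
liquid pockets enclosed by particles have a strongly positive evaporation
`ΔE` (every broken liquid–particle bond costs `ε_ln`) and survive
essentially forever at the studied `μ`, so particle-laden runs typically
terminate at `max_steps` with `ν ≈ 1` and the pattern frozen: particles
can only move within liquid, and almost none remains. The test suite and
the acceptance script therefore use a few hundred steps, which is past
the point where the projected pattern stops changing at the sizes they
run.

## Pattern analysis

The final state is projected to a height map (particle cells per column),
the lattice analogue of an AFM topograph. Grains are connected components
of the occupied projection, holes of the empty one; grains default to
8-connectivity and holes to the complementary 4-connectivity (standard
digital-topology duality, so grain and hole boundaries are consistent).
Components can be labeled with or without wrapping across the lateral
seams — periodic for simulated states, non-periodic for imported images.
Labeling is scipy `ndimage.label` plus a union-find merge across the
seams; tests check it against an independent brute-force flood fill.

Grain summaries use the population (divide-by-n) standard deviation, as
grain-analysis software typically reports. The experimentally motivated
"filter out the smallest features" step is exposed as a minimum grain
area (cells) plus an optional minimum peak height. Hole histograms
accumulate *total hole area per size bin* over log-spaced bins (hole
sizes span orders of magnitude in cellular patterns); a pattern is called
dual-scale when some run of empty bins separates two occupied groups each
holding at least 5% (configurable) of the total hole area.

## What the generator emulates — and what it does not

The initial state is a uniform random suspension: particles placed
uniformly over all fluid layers, no pre-wetting layer, no spatial
correlations. Real drying films also involve hydrodynamic flow
(coffee-ring advection, Marangoni eddies), solute diffusion gradients,
crystallization kinetics, polydisperse and multi-cell solutes, and
substrate heterogeneity — none of which are in the model. Passing tests
therefore demonstrate the lattice-gas mechanism (evaporative dewetting
fronts collecting and depositing particles, modulated by a
coverage-dependent evaporation bias), not a quantitative prediction for
any particular solute.

## Problem sizes used by the tests and the acceptance script

The published dot-pattern geometry is `D = 400, z = 0.05` (H = 20) and
the network geometry `D = 800, z = 0.025` (H = 20). The package's own
checks run scaled-down versions chosen to keep full runs in seconds to a
few minutes:

- dot regime: `D = 128, H = 8, φ = 0.5%`, 250 steps, 5 seeds;
- parameter trends (μ: −3.7 vs −3.6; `N_mov`: 20 vs 5): `D = 192, H = 8`,
  6 seeds per condition, compared with one-sided Mann–Whitney tests at
  α = 0.1. The smaller `D = 128` domain resolves the grain-area trend but
  not the grain-count trend above seed noise at this replication, so the
  trend comparisons use the larger domain;
- sigmoidal regime: `D = 256`, with both the thin (`H = 8`) variant and
  the thickness-preserving (`H = 20`) variant exercised (see
  limitations).

## Known limitations

- **Finite-size limits of the dual-scale signature.** The cellular
  network needs the published projected coverage `φ·H ≈ 0.5` to close its
  walls; with `H = 8` (coverage 0.2) the sigmoidal schedule yields dots
  over one percolating background hole and no dual-scale signature. With
  `H = 20` at `D = 256`, runs do form a cellular network whose hole
  histogram shows the characteristic gap (isolated small holes vs. a
  group of 10^3–10^4-cell network cells), but the small-hole group
  carries well under 5% of the total hole area at this domain size, so
  the strict dual-scale detector usually returns false. Resolving both
  scales with the default detector appears to require domains near the
  published `D = 800`, which is outside the run sizes this package's test
  suite permits itself.
- Single-cell particles only; no cluster moves, so late-stage coarsening
  is slow and slightly update-order dependent.
- The vertical boundary is a hard vacuum; there is no vapor transport
  resistance above the film.
- `ν` is judged from layer 1 only; particle-covered substrate counts as
  dried (no solvent remains there), which makes `ν → 1` reachable even
  when trapped liquid persists higher up.
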