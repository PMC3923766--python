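# Methods

## Model and assumptions

The simulator describes a tissue of N somatic cells that is homeostatic in
cell number. Cell state is a scalar damage level d ∈ [0, 1], interpreted as
the accumulated load of irreversible damage (the motivating case is
mitochondrial DNA mutations, which are duplicated at division and not
repaired). The dynamics are a discrete-time Moran-like process:

1. One elementary step selects a cell uniformly at random.
2. The selected cell dies with probability equal to its damage level
   (linear survival function; the proportionality constant is fixed at 1,
   so ε is directly the initial per-selection death probability — damage is
   already on [0, 1], and any other constant only rescales time).
3. On death, a divider is drawn uniformly from the other N−1 cells
   (well-mixed) or from the two ring neighbours of the vacancy (1D ring
   with periodic boundaries). Removal precedes division, so the dead cell
   is never its own replacement.
4. With probability p the division adds Δ of new damage: Δ/2 to each
   daughter (symmetric mode) or all Δ to one daughter (asymmetric mode);
   otherwise both daughters copy the parent's damage bit-for-bit.
5. The high- and low-damage daughters are assigned to the vacancy and the
   divider's slot in uniformly random order (a deterministic rule would
   bias spatial drift in asymmetric mode on the ring).
6. Damage is clamped at 1 per daughter; the all-ones configuration is
   absorbing. One time unit is N elementary steps.

Assumptions worth making explicit: damage is irreversible (no repair or
dilution, the limiting case for duplicated components); apoptosis is the
only death channel and replacement is instantaneous (strict homeostasis);
divisions are identical in duration (no cell-cycle modelling); the initial
population is homogeneous at damage ε. Failed-death selections still
advance the clock, so each cell is selected once per time unit on average.

Because unmutated inheritance copies the parental float exactly, a cell's
damage equals the clamped fold ε → min(ε + s, 1) → … applied once per
increment (s = Δ/2 symmetric, Δ asymmetric). The fraction f₀ of cells still
at the initial level is therefore computed by exact equality with ε, with
no floating-point tolerance.

## Mean-field hierarchy and its steady state

For the well-mixed system, x_k denotes the fraction of cells with k
mutational increments (damage d_k = ε + k·s, ignoring the cap — valid in
the transient regime where occupied classes sit well below 1). Deaths
occur in class k at rate d_k x_k; the replacing divider is class k with
probability x_k and mutates with probability p. A symmetric mutated
division converts divider and vacancy into two class-(k+1) cells; an
asymmetric one promotes a single daughter. Closing through
⟨d⟩ = Σ d_k x_k:

    symmetric:   ẋ_k = −d_k x_k + (1−2p)⟨d⟩ x_k + 2p⟨d⟩ x_{k−1}
    asymmetric:  ȧ_j = −d_j a_j + (1−p) ⟨d⟩ a_j +  p⟨d⟩ a_{j−1}

Both conserve Σx. Stationarity of the k = 0 equation pins the mean:
d* = ε/(1−2p) (symmetric; requires p < 1/2) or ε/(1−p) (asymmetric), with
existence additionally requiring 0 < d* ≤ 1. The remaining recurrence is
solved by a Poisson distribution over k with mean λ = 2p d*/s — that is,
λ_sym = 4p d*/Δ and λ_asym = p d*/Δ — so x₀ = e^(−λ). It follows
immediately that the asymmetric mode has lower d* and higher x₀ for every
parameter set where both exist, with equality only at p = 0. After the
k = 0 class goes extinct, the same analysis applies with base level
ε + g·s after g extinctions; λ grows with the base level, so each
successor state is shorter-lived — the mechanism of terminal collapse.

The symmetric d* is insensitive to whether a symmetric mutated division is
read as Δ/2 per daughter (the default here; total new damage Δ, matching
the asymmetric total) or Δ per daughter: the lattice rescales and λ halves
or doubles, but ε/(1−2p) is unchanged. A regression test pins this.

## Numerical choices

- The hierarchy is truncated at k_max = 40 classes (doubled automatically
  if the top-class mass ever exceeds 1e-8) and integrated by fixed-step
  classical RK4 with dt = 0.01 time units; steady state is declared at
  max|ẋ| < 1e-10. The system is only mildly stiff (rates ≤ a few per time
  unit at the default parameters).
- The total fraction is a neutral direction of the flow, and the quadratic
  ⟨d⟩-closure turns any numerical drift of Σx away from 1 into slow
  exponential growth of the whole vector (rhs(αx*) = α(α−1)·d·x*). The
  integrator therefore renormalizes the state onto the simplex after every
  step; conservation then holds to < 1e-9 trivially and the renormalized
  flow has the same fixed points.
- Collapse times are first-passage times measured at elementary-step
  resolution (τ = first step / N). Both collapse criteria — f₀ = 0 (loss
  of the initial-level class, the default) and all-damage-one (full
  saturation) — are absorbing events, so the recorded step is exact.
  Unit-boundary detection would bias τ upward by about half a time unit,
  which is visible against the exact oracle on tiny instances.
- The inner loop is compiled with numba and consumes draws from a
  `numpy.random.Generator` in a fixed order (selection, death, divider,
  mutation, placement); a pure-Python step implementation consumes the
  identical stream, and bit-for-bit equality of the two paths is tested.
  One run uses one generator seeded from `ModelParams.seed`; replicate r
  of an experiment uses `base_seed + r`.
- The exact oracle enumerates the states reachable from the all-ε
  configuration — multisets of lattice levels for the well-mixed topology
  (the dynamics are exchangeable), ring configurations modulo rotation and
  reflection for the 1D topology — assembles the sparse one-step matrix,
  and solves the fundamental-matrix system (I − Q)t = 1 for expected
  hitting times. Unreachable targets (p = 0 or ε = 0) are reported as
  infinite rather than raised.
- Degenerate inputs: ε = 0 (frozen dynamics) and ε = 1 (born collapsed)
  validate with a warning; censored collapse times report τ = max_time
  flagged, and a median computed with at least half the replicates
  censored is flagged as a lower bound.

## Statistical checks and their calibration

Plateau agreement at N = 1000 uses the time average over t ∈ [100, 400] of
a 500-unit run; its Monte-Carlo standard error is estimated by batch means
(10 batches of 30 units, long against the observed correlation time of a
few units), and agreement is required within 3 SE.

The Poisson law of the increment histogram is tested on the leading class
fractions (those with ≳20 expected cells) pooled over 20 plateau
snapshots taken from independent replicate runs. Cells within one run
share ancestry, so class counts are overdispersed relative to a
multinomial and a naive pooled chi-square over 20 000 cells is
miscalibrated (it rejects a correct model for a substantial fraction of
seeds). The test therefore uses the chi-square (Hotelling T²) statistic
with the covariance of the class fractions estimated across the 20
replicates, calibrated through the F distribution, at α = 0.01. Per-class
means over 40 independent runs show no systematic deviation from
Poisson(λ) within Monte-Carlo error.

## What the experiments show — and their reach

At the reference study conditions (ε = 0.1, p = 0.1, Δ = 0.2, N = 100,
20 replicates, horizon 1e5 time units, f₀-extinction criterion):

- On the ring, the symmetric system collapses with median τ ≈ 6×10³ while
  the asymmetric system outlives the horizon — damage partitioning
  lengthens population lifetime.
- In the well-mixed topology the initial-level class is self-stabilizing
  (a dip in x₀ raises ⟨d⟩, which feeds births back into every class in
  proportion, restoring x₀), so its extinction is a large deviation whose
  waiting time grows explosively with N: measured median τ is ≈ 8×10² at
  N = 16 and ≈ 6.6×10⁴ at N = 32, and exceeds 10⁶ time units at N ≥ 64
  for both modes. Well-mixed collapse at N = 100 is therefore not
  observable at any feasible horizon at these parameters; orderings and
  scalings in that regime are reported with censored medians flagged as
  lower bounds. The ring is far more fragile and scales temperately:
  median τ grows roughly in proportion to N (measured ≈ 8.5×10² at
  N = 32 up to ≈ 5×10⁴ at N = 1024, about a factor 2 per doubling with
  considerable replicate noise) — global loss of the initial-level class
  waits for the last surviving pocket, and pockets are killed at a
  per-region rate set by a bounded effective neighbourhood. Full
  N-independence of τ is not reached by N = 1024 at these parameters.
- Raising the fragility stabilizes the population (median τ at p = 0.2:
  ≈180 at Δ = 0.05, ≈800 at Δ = 0.1, censored beyond 10⁵ at Δ ≥ 0.2):
  deadlier damage classes are purged faster.
- Halfway to collapse on a ring of 200 cells, the nearest-neighbour damage
  correlation (≈0.8) far exceeds the 99th percentile of its permutation
  null (≈0.15): neighbour-only replacement breeds clusters of damaged
  cells whose boundaries drift toward the more damaged side.

The synthetic populations are the model itself, not data: homogeneous
initial state, a single damage scalar per cell, linear apoptosis risk and
instantaneous replacement. Passing tests show internal consistency of
simulation, analytics and exact enumeration — they do not validate the
biological reading (e.g. real tissues have repair, heterogeneous niches,
and cell-cycle structure).

## Problem sizes used

Tests and the acceptance script run at: N = 1000 × 500 time units for
plateau checks; 20 × 250-unit replicates for the Poisson fit; N = 100,
20 replicates, 1e5-unit horizon for collapse experiments; N ∈ {16…256}
for size scans; 5 000–10 000 replicates of the N = 3 two-level instance
against the exact oracle; 10⁶ single steps for transition-frequency
checks. These sizes give Monte-Carlo errors comfortably below the effect
sizes under test while keeping a full run on one core to a few minutes.
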