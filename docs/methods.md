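# Methods

## Model

A reaction network is a set of molecular species (proteins, unbound gene
promoter sites, and bound protein–DNA complexes), mass-action reactions,
and conservation structure. A microstate is the tuple of copy numbers of
every species; the discrete chemical master equation (dCME)

    dp/dt = A p

governs the probability of every microstate over time. Off-diagonal
`A[to, from]` is the propensity of the reaction taking `from → to`,
computed as the rate constant times the falling factorial of each reactant
count (so a dimer-binding reaction consuming two copies of a protein with
`x` copies has propensity `k·x·(x−1)`). The diagonal negates each column's
off-diagonal sum; columns cancel to zero at machine precision (exact
cancellation is not representable in floating point), and the propagated
mass drift stays below 1e-9 over hundreds of steps.

### Finite-buffer enumeration

The state space is made finite by buffer queues. Species are partitioned
into molecular equivalence groups (MEGs): subsets interconvertible through
mass-balanced reactions. Each MEG `j` with `n_j` member species gets a
buffer capacity `b_j` bounding its total molecular units, giving the size
bound `∏_j C(b_j + n_j, n_j)`. Conventions:

- A free protein copy occupies 1 unit of its MEG.
- A bound complex formed by dimer binding sequesters 2 units of the
  binding protein (the dimer is inside the complex).
- Each gene site holds exactly one copy across its occupancy species
  (unbound + bound forms).

Under these rules the 2-gene toggle switch with buffers (120, 240)
enumerates to (121 + 119) × (241 + 239) = 115,200 microstates: per gene
combination, the repressing protein loses 2 available units whenever its
dimer is bound. Enumeration output is lexicographically sorted in species
order, so runs are byte-reproducible. Reactions whose target would leave
the enumerated space (buffer overflow) are suppressed — a reflecting
boundary, the standard finite-buffer practice.

### Propagation

Default propagation applies the sparse matrix-exponential action
(`scipy.sparse.linalg.expm_multiply`) interval by interval, which is exact
for this linear system up to round-off; a stiff BDF integrator
(`method="ivp"`, tolerance 1e-10) is available as a cross-check and both
must conserve mass to 1e-9. Tiny negative entries from round-off are
clamped to zero.

## Presets and their parameters

Rate constants for the case-study networks are not published, so the
preset defaults are this package's own choices, fixed once to realize the
qualitative regimes of interest; analyses of these runs assert structure
(peak counts, symmetry), never specific probability values.

**Toggle switch** (`toggle_switch_preset`, species Pa, Pb, Da, Db, BDa,
BDb; time unit = protein lifetime): synthesis 12 per unit time from an
unbound gene, degradation 1 per copy, dimer binding 0.002, unbinding
0.015. The synthesis/degradation ratio of 12 puts the expressing mode well
inside even small test buffers; binding/unbinding are slow relative to
protein relaxation, so the four gene-occupancy states are long-lived and
each protein marginal is a well-separated bimodal mixture (repressed mode
at 0, expressing mode near 11). With symmetric rates and equal buffers the
landscape is exactly invariant under exchanging the two genes, which the
tests use as an oracle. Initial condition: zero proteins, both genes
unbound.

**Cascade** (`cascade_preset`): genes A and B are constitutive; gene C's
promoter can be occupied (activated) by a Pa dimer or a Pb dimer. Basal,
A-activated and B-activated synthesis of Pc default to 0.5, 9.5 and 29.5
(degradation 1), giving a trimodal output marginal with modes near 0, 9
and 29; setting both binding constants to zero reduces Pc exactly to a
birth-death species with a truncated-Poisson marginal — the closed-form
limit used in tests.

**Birth-death** (`birth_death_preset`): constant birth `k`, per-copy death
`γ`, truncated at the buffer. Its stationary law is Poisson(k/γ)
renormalized on the buffer range and satisfies detailed balance
`k·π(x) = γ·(x+1)·π(x+1)`; both are used as analytic oracles for the
propagator.

## What the generator does and does not emulate

The simulator reproduces the structure of real dCME output: exact
per-time distributions over an enumerated state space, multistability,
slow peak births, and boundary spikes (the extinct state at copy 0).
It does not emulate the truncation-error artefacts of production solvers
on very large state spaces — the tiny spurious peaks real data contains.
Suspect-peak classification is therefore tested on constructed value sets,
and passing tests show the pipeline's correctness on exact landscapes, not
the behaviour of any particular production solver's error profile.

## Analysis conventions

- **Ingestion tiers**: a probability column's deviation from unit mass is
  accepted below 1e-6 (float noise), logged as a warning up to 1e-2, and
  rejected beyond that (corrupt input). `validate_landscape` reports
  per-time mass and passes at 1e-9.
- **Time ordering**: probability files are sorted by their time stamp on
  ingestion, so the landscape is independent of the order paths are given;
  a glob pattern without a manifest assigns index times 0, 1, 2, ….
- **Projections** are computed over protein-role species only; gene
  occupancy is aggregated out. 1D marginal axes always span the full
  0..max_copies range.
- **Peak detection**: strict one-sided comparison at the boundary indices
  (the extinct state can be a genuine spike); a plateau strictly above its
  flanks yields one peak at its leftmost index (a deterministic, order-
  stable tie-break); detection threshold 1e-12 (solver error floor);
  suspect threshold 1e-6 by default (the cutoff used by the original
  analyses is unpublished) — both configurable.
- **System peaks** are the Cartesian product of per-dimension peaks
  (per-dimension independence assumption). The joint value of a peak state
  is the aggregated probability of all microstates matching its protein
  copy numbers; the per-dimension marginal values are kept alongside. An
  optional flag re-ranks combined peaks by joint value to surface spurious
  combinations on correlated landscapes (off by default).
- **Tracking**: greedy nearest-neighbour matching between consecutive
  steps by L1 distance, closest pairs first, ties broken by
  lexicographically smaller location; matches beyond `max_displacement`
  (CLI default: 10% of the largest protein axis) are rejected. Suspect
  peaks are excluded from tracking by default (configurable) since
  numerical-error peaks appear and vanish erratically.
- **Steady state**: first index from which the sup norm of successive
  column differences stays below the tolerance through the end of the run
  (the qualitative "peaks stop moving" criterion made operational).

## Visualization conventions

Layout geometry is computed by pure functions of (data, options) and
serialized to JSON sidecars (sorted keys, 12-significant-digit floats), so
determinism is tested on bytes rather than rasters. Colour and height
scales are strictly per panel — peak values span orders of magnitude and
cross-panel normalisation hides small peaks. The spaghetti time-intensity
ramp is linear in time index (T equally spaced values ending at full
intensity). The qualitative colormap assigns classes at decade-spaced
fractions of the panel maximum (7 classes). Heatmap overlay curves are
rescaled per cell to the cell's own maximum — they convey shape, not
scale — and when a grid exceeds 2,000 cells only the top cells by temporal
variance keep overlays, to avoid sub-pixel clutter. The 3D surface view is
rendered as static matplotlib frames embedded in a self-contained HTML
page with a frame slider, plus an optional GIF animation.

## Problem sizes

Tests and examples use reduced buffers — toggle (6, 6) through (30, 30),
cascade (10, 10, 40), birth-death buffers 5–30 — where exact propagation
takes seconds; the full (120, 240) toggle enumeration (115,200 states) is
run for the state-space count, which needs no propagation. These sizes are
the package's chosen study conditions: every qualitative regime (bistable
toggle, trimodal cascade output, boundary spikes) is realized at them.

## Known limitations

- The propagator is dense-in-state (every enumerated state carried); it is
  not a substitute for production solvers on million-state systems.
- Peak tracking is greedy and can mis-match when two peaks approach within
  the displacement radius between coarse output steps; refine the time
  grid in that case.
- The product rule for system peaks inherits the per-dimension
  independence assumption; on strongly correlated landscapes it reports
  combinations whose joint value is near zero (these are flagged suspect
  once evaluated).
- No interactive linked-view application is provided; the rendered report
  is static.
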