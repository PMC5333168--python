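# prodland

Analysis of time-varying **probability landscapes** of stochastic gene
regulatory networks computed from the discrete chemical master equation
(dCME).

Gene circuits with low copy numbers of molecular species behave
stochastically: their state is a probability distribution over *microstates*
(copy-number tuples), not a single trajectory. The dCME describes this
distribution exactly as a linear system

```
dp/dt = A p
```

over all `N` microstates, where `A` is the sparse transition-rate operator
assembled from mass-action propensities. The resulting `N × T` probability
matrix — one distribution per output time — is the probability landscape;
its **peaks** mark the stable phenotypic states of the circuit, and small
peaks can correspond to rare but biologically important states.

`prodland` is for researchers who compute such landscapes (or want to
simulate them) and need to analyse and display them. It provides:

- **Ingestion** of the standard plain-text exchange format: one state-space
  table (one microstate per row, one integer column per species) plus one
  probability file per time step, with validation that every distribution
  carries unit mass (`prodland.landscape_io`).
- **A finite-buffer dCME simulator** used as the synthetic-data generator:
  species are partitioned into molecular equivalence groups (MEGs), each
  with a buffer capacity bounding its total molecular units, which makes
  the state space finite — `∏_j C(b_j + n_j, n_j)` is the size bound. A
  protein–DNA complex formed by dimer binding sequesters two protein units.
  Presets: the 2-gene toggle switch, a 3-gene cascade, and the birth-death
  process whose truncated-Poisson stationary law is the analytic benchmark
  (`prodland.cme_simulator`).
- **Exact marginalization** of the landscape onto every protein (1D) and
  every protein pair (2D) by aggregation, conserving probability mass
  (`prodland.projection`).
- **Peak analysis**: a 1D scan marks a copy number as a peak when its
  marginal probability exceeds both neighbours and a `1e-12` threshold;
  per-dimension peaks combine by Cartesian product into system peak states,
  whose joint probabilities are evaluated and, when tiny, flagged as
  *suspect* numerical-error peaks (`prodland.peak_analysis`).
- **Temporal analysis**: per-state time curves, greedy nearest-neighbour
  tracking of peaks into trajectories, and steady-state detection
  (`prodland.temporal_analysis`).
- **Views**: spaghetti plots (one curve per time step, intensity encoding
  time), 1D/2D heatmaps with per-cell time-curve overlays, peak glyphs
  (stacked bars, one per protein; grey = suspect), and animated 3D
  probability surfaces — all with per-panel scales, never normalised across
  panels, so small peaks stay visible (`prodland.visual_layout`).

## Worked example: the genetic toggle switch

Two genes repress each other: a dimer of each protein can occupy the other
gene's promoter. With symmetric rates the circuit is multistable. A reduced
model (buffers 30, 30) is small enough to solve exactly:

```python
import numpy as np
from prodland import toggle_switch_preset, run_simulation
from prodland import find_system_peaks, detect_steady_state

network, initial = toggle_switch_preset(buffers=(30, 30))
landscape = run_simulation(network, initial, np.arange(0.0, 201.0, 25.0))
print("states:", landscape.state_space.n_states)

last = landscape.n_times - 1
for pk in find_system_peaks(landscape, last):
    print(f"peak {pk.location}  joint p = {pk.value:.4f}  suspect = {pk.suspect}")
```

prints

```
states: 3600
peak (0, 0)  joint p = 0.0357  suspect = False
peak (0, 11)  joint p = 0.0512  suspect = False
peak (11, 0)  joint p = 0.0512  suspect = False
peak (11, 11)  joint p = 0.0003  suspect = False
```

The four system peaks are the toggle's four gene-occupancy phenotypes:
both genes repressed (0, 0), each one-sided expressing state at about 11
copies (the synthesis/degradation ratio), and the weakly populated
both-expressing state. At the production buffer sizes (120, 240) the same
preset enumerates 115,200 microstates.

The same pipeline runs from the shell:

```sh
prodland report --preset toggle --buffers 12 --buffers 12 \
    --times 0:20:1 --out runs/toggle
```

which writes the state space and probability files, long-format marginal
CSVs, peak and trajectory tables, and the rendered views (PNG + JSON
geometry sidecars, plus a self-contained HTML surface viewer).

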