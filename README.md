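# bdcolony

Brownian-dynamics simulation of early two-dimensional bacterial microcolonies,
with cluster-scale morphometrics that apply equally to simulated colonies and
to segmented micrographs.

## Science background

Many surface-associated bacteria found new colonies from a single attached,
rod-shaped cell. During the first few division rounds — before the colony
becomes a dense, confluent film — its morphology is set by a competition
between two processes: cells elongate and divide (building local, aligned
order) and cells diffuse on the surface (destroying it). `bdcolony` models
this regime with an individual-based simulation:

* each cell is a **soft repulsive spherocylinder** in the plane (a rod of
  cylinder length `L` capped by hemispheres of diameter `σ`);
* cells **elongate at constant velocity** and **divide transversally** when
  their aspect ratio doubles from the newborn value `L*₀`, producing two
  newborn daughters that together occupy the parent's footprint — divisions
  are therefore synchronized, and colony sizes are powers of two;
* between divisions cells move by **overdamped anisotropic Brownian
  dynamics**: translational diffusion is faster along the rod axis than
  across it, rotational diffusion follows the analytic end-corrected rod
  coefficients, and overlapping cells repel through a WCA-type potential
  acting on the closest-approach distance between their axes.

The single dimensionless control parameter is

```
Γ = t_dif / t_gr
```

the ratio of the time for a newborn cell to diffuse a quarter of its own
cross-section, `t_dif = 0.25 σ² / (D∥ + D⊥)`, to the division time
`t_gr = (L₀ + σ)/v_gr`. Large Γ (division much faster than diffusion) gives
**closed growth**: compact, high-coverage, nematically ordered clusters.
Small Γ gives **open growth**: sparse, fragmented, disordered clusters with
much larger radii. The package also computes the morphometrics used to
characterize this transition — the Monte-Carlo radial coverage profile
`g(r)`, the cluster eccentricity `Φ` from the inertia tensor of the cell
centers, the 2-D nematic order parameter `S₂`, and the major radius (the
largest distance at which `g(r) > 0`) — and can ingest segmented-cell tables
from experiments so the same metrics run on micrograph data.

## Worked example

Simulate one closed-growth colony (Γ = 16.7) and one open-growth colony
(Γ = 0.02) to the 32-particle stage and compare their morphometrics:

```
$ printf 'Gamma: 16.7\nseed: 1\nsnapshot_counts: [32]\nN_max: 32\n' > closed.yaml
$ bdcolony simulate --config closed.yaml --out closed_run
seed 1: wrote 1 snapshots to closed_run
$ bdcolony analyze --in closed_run/snapshot_seed1_N00032.csv --out closed_metrics
 n_particles       S2      Phi  major_radius
          32 0.883057 0.944041          12.0

$ printf 'Gamma: 0.02\nseed: 1\nsnapshot_counts: [32]\nN_max: 32\n' > open.yaml
$ bdcolony simulate --config open.yaml --out open_run      # ~10 s: low Γ means ~10⁶ BD steps
$ bdcolony analyze --in open_run/snapshot_seed1_N00032.csv --out open_metrics
 n_particles       S2      Phi  major_radius
          32 0.225758 0.755343          16.0
```

The closed-growth colony is strongly nematically ordered (`S₂ = 0.88`)
while the open-growth colony is disordered (`S₂ = 0.23`) and spread over a
larger area. `analyze` also writes the full `g(r)` table; `sweep` runs a
replicate-averaged (Γ × L*₀) grid; `analyze --cell-table` applies the same
morphometrics to a segmented-cell CSV (`x, y, theta, total_length` in
declared units). Identical invocations write byte-identical outputs: every
run is a pure function of its configuration and seed.

The same pipeline is available as a library:

```python
import numpy as np
from bdcolony import SimulationParams, run_simulation, coverage_profile, nematic_order

params = SimulationParams(Gamma=16.7, snapshot_counts=(32,), N_max=32, seed=1)
colony = run_simulation(params)[-1]
profile = coverage_profile(colony, dr=0.5, n_points=10_000,
                           rng=np.random.default_rng(0))
print(nematic_order(colony), profile.central_mean(2.0))
```

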