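# mmspar

Multi-modal spatial accessibility scores for supply/demand systems (e.g.
primary-care providers and census units), implemented as a multi-modal
enhanced two-step floating catchment area (E2SFCA) model with Gaussian
distance decay. The package computes, per demand unit:

- **SPAI** (spatial access index), per transport mode and integrated across
  modes — supply per person, accounting for mode-specific catchments,
  travel-time sub-zones, and competition between subpopulations that travel
  by different modes;
- **SPAR** (spatial access ratio), each SPAI divided by its study-area mean —
  a dimensionless score with mean 1 that is far less sensitive to the choice
  of the Gaussian impedance coefficient than SPAI itself.

It also ships an impedance-coefficient sensitivity battery (a Cartesian sweep
over per-mode coefficient grids, descriptive statistics, and one-way ANOVA
contrasts showing SPAI instability vs SPAR stability) and a reproducible
synthetic scene generator (core-clustered supply, car-dominant mode split,
bus service restricted to the urban core) so the whole pipeline runs
end-to-end with no external data.

## Model

1. **Supply-to-demand ratio.** Each supply site i with capacity `C_i` gets
   `R_i = C_i / Σ_modes Σ_units P_k,mode · W(d_ki,mode)`, summing the
   decay-weighted populations that can reach the site within each mode's
   catchment (default 30 min car / 60 min bus).
2. **Access index.** Each demand unit j sums the weighted ratios of sites it
   can reach per mode: `A_j,mode = Σ_sites R_i · W(d_ji,mode)`; the
   integrated score is the sum across modes.
3. **Access ratio.** `S_j = A_j / mean(A)` per score family.

Weights are Gaussian, `W = exp(-d²/β)`, evaluated (by default) at the mean
travel time of the catchment sub-zone containing the trip (car sub-zones
0–10/10–20/20–30 min; bus adds 30–60 min), so weights are stepped in travel
time. Continuous weighting on exact travel times is available as an option.

## CLI

```bash
# decay-weight table per (mode, beta, sub-zone)
mmspar weights --outdir out --decimals 3

# reproducible synthetic scene (CSV files + reachability summary)
mmspar simulate --seed 1 --outdir scene

# three-step access model on CSV inputs
mmspar access --supply scene/supply.csv --demand scene/demand.csv \
    --od car=scene/od_car.csv --od bus=scene/od_bus.csv --outdir out

# coefficient-grid sensitivity sweep + ANOVA battery
mmspar sensitivity --supply scene/supply.csv --demand scene/demand.csv \
    --od car=scene/od_car.csv --od bus=scene/od_bus.csv --outdir out
```

Input schemas: supply `id,capacity[,x,y]`; demand `id,pop_<mode>...[,x,y]`;
one long-format OD CSV per mode `origin_id,dest_id,minutes` where an absent
row means the pair is unreachable. Mode definitions (thresholds, sub-zone
breakpoints, representative times, beta or beta grid) come from a YAML
config (`--config`); the defaults are the 30-min car / 60-min bus setup with
coefficient grids 140..320 (step 15) and 440..1040 (step 50). Coordinates,
when present, are planar kilometres in a local frame; the optional GeoJSON
export labels them as non-geographic.

## Library entry points

```python
from mmspar import (
    SceneSpec, generate_scene, default_modes,   # synthetic scenes
    run_access, e2sfca_single_mode,             # access model
    build_grid, run_grid, hypothesis_battery,   # sensitivity analysis
    weight_table, gaussian_weight, derive_beta, # decay utilities
)

scene = generate_scene(SceneSpec(seed=1))
result = run_access(scene, default_modes(beta_car=140, beta_bus=440))
result.spar_integrated.describe()
```
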