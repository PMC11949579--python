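# braintce

Time-averaged control energy (TCE) of brain network dynamics.

## The problem

Resting-state brain activity wanders through a sequence of large-scale
activation patterns — moments dominated by the visual network, the default
mode network, and so on. Network control theory models this wandering as a
control problem: regional activity `x(t)` evolves on the structural
connectome `A` under linear dynamics, and steering the brain from one state
to another requires an external input `u(t)` whose time-integrated square is
the *control energy* of the transition. Most work prices single transitions
in isolation; this package prices the whole recording. It derives the
empirical sequence of network-dominance states from a parcellated
recording, computes the optimal control energy of every ordered state pair,
and averages the per-region energies along the sequence — giving TCE, a
regional map of the average control cost a person's brain incurred over
time. The package is for researchers working with parcellated fMRI time
series and tractography-derived connectomes who want subject-level control
cost maps and calibrated spatial statistics to compare them against other
brain maps (e.g. metabolic uptake).

## The model

With the connectome stabilized as `A ← A/(λ_max(A) + c) − I` (default
`c = 1`), controlled dynamics are `ẋ = Ax + Bu` with `B = I` (every region
actuated). The optimal input between states `x0` and `xT` over horizon `T`
minimizes

```
J = ∫₀ᵀ (xT − x(t))ᵀ(xT − x(t)) + ρ·u(t)ᵀu(t) dt,      x(0)=x0, x(T)=xT
```

(default `ρ = 1`, `T = 1`), solved exactly through the Pontryagin two-point
boundary-value problem with one augmented matrix exponential. Per-region
energies are `E_i = ∫ u_i²dt`. Given the dominance sequence (per timepoint,
the intrinsic network whose mean z-scored activity is highest and ≥ 0.5 SD;
otherwise discarded), TCE is

```
TCE = (E*₀→₁ + E*₁→₂ + … + E*₍P−1₎→P) / P
```

over the P consecutive retained transitions. Spatial comparisons between
region-level maps use variogram-matched surrogate nulls: surrogates
randomize a map while preserving its spatial autocorrelation
(`y = √β·x′ + √α·z` with the smoothed permutation `x′` matched to the
map's semivariogram), so the resulting p-values stay calibrated on smooth
maps where naive permutation tests wildly over-reject.

## Worked example

Everything runs on synthetic data; no neuroimaging downloads needed.

```python
import numpy as np
from braintce import (
    default_spec, synth_connectome, synth_recording, normalize_adjacency,
    standardize, network_average, dominance_sequence, state_maps,
    transition_energy_matrix, tce, hierarchy_summary,
)

spec = default_spec(seed=1)             # 60 regions, 4 networks, T = 200
conn = synth_connectome(spec)
raw, ledger = synth_recording(spec)

rec = standardize(raw, region_ids=spec.region_ids)
series = network_average(rec, dict(zip(spec.region_ids, spec.network_of_region)))
seq = dominance_sequence(series, threshold=0.5)
states = state_maps(rec, seq)

system = normalize_adjacency(conn)
te = transition_energy_matrix(states, system)
tce_map = tce(seq, te)
summary = hierarchy_summary(seq, te, hierarchy=spec.hierarchy_of_network)

print("states:", states.state_names)
print("transitions P:", tce_map.transition_count)
print("mean TCE:", round(tce_map.values.mean(), 3))
print("within-hierarchy fraction:", round(summary.within_fraction, 3))
```

prints

```
states: ['VIS', 'SMN', 'FPN', 'DMN']
transitions P: 163
mean TCE: 2.812
within-hierarchy fraction: 0.491
```

Four network states were detected, the recording contained 163 retained
transitions, the average per-region control cost of the recording is 2.81
(squared-input units at `T = 1`), and 49% of transitions stayed within a
hierarchy level — for this generator the planted sequence is uniformly
random, so within- and between-level transitions are about equally common.

The same pipeline runs from the shell on TSV inputs:

```sh
braintce synth --seed 1 --outdir fixture/
braintce run --config config.yaml       # connectome/recording/lookup paths
```

writing the dominance sequence, state maps, all pair-energy maps, the TCE
map, the hierarchy summary and a provenance JSON into the output directory.

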