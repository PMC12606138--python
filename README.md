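# placefields

Place-cell analysis for 1-photon miniscope calcium imaging on linear tracks.

Hippocampal CA1 pyramidal cells fire in restricted locations ("place
fields"); how those fields form, stabilise and remap across repeated
exposures to an environment is a central readout in systems neuroscience.
This package implements the full analysis chain from behavioural traces and
deconvolved calcium event trains to place-cell identification, across-session
stability and remapping statistics, optogenetic-zone comparisons,
interneuron activity profiles and longitudinal cell registration — plus a
seeded synthetic-session generator so every stage is testable without raw
recordings. It is aimed at labs running linear-track imaging experiments and
at anyone who wants a tested, reusable reference implementation of these
analyses.

## The statistics at the core

**Rate maps.** Running-gated events (speed > 7 cm/s sustained over ≥ 10 cm,
reward zones excluded) are binned into 40 spatial bins of 2.75 cm on the
140 cm track, divided by occupancy, and Gaussian-smoothed (σ = 1.5 bins).

**Spatial information.** For occupancy probabilities *p*ᵢ and bin rates
*r*ᵢ with mean rate r̄ = Σᵢ *p*ᵢ*r*ᵢ,

```
SI = Σᵢ pᵢ (rᵢ / r̄) log₂(rᵢ / r̄)      [bits/event]
```

SI is the KL divergence between the event-weighted and occupancy position
distributions: nonnegative, and zero iff the rate is spatially uniform.

**Place-cell test.** The observed SI is compared with 1000 circular
time-shifts of the event train along the valid (running) timeline; a cell is
a place cell when the empirical tail probability of the shuffle distribution
falls below α = 0.05. Cells significant in both running directions keep the
direction with the higher event rate. Field centre = bin of maximal
normalised activity; field = contiguous bins ≥ 75% of the centre bin.

**Stability.** Across sessions, per-cell Pearson spatial correlations
(Fisher-transformed for group tests), field shifts (stable ≤ 2 bins,
remapped > 2 bins, lost = no longer a place cell) and the per-bin
population-vector correlation matrix, with mean diagonal scores per
optogenetic / control zone.

**Registration.** Fields of view are aligned by maximising an enhanced
correlation coefficient over a rigid transform; cells are then matched
greedily by normalised cross-correlation of their spatial footprints until
no pair above NCC 0.5 remains.

## Worked example

```python
import numpy as np
from placefields import TrackConfig
from placefields.synth import SessionPairSpec, random_tuning_specs, simulate_session_pair
from placefields.pipeline import analyze_session, compare_sessions

cfg = TrackConfig(opto_zone=(26.0, 59.0), control_zone=(59.0, 92.0))
specs = random_tuning_specs(cfg, n_cells=60, rng=np.random.default_rng(0), peak_rate_hz=5.0)
pair = SessionPairSpec(p_stable=0.5, p_remap=0.3, p_lost=0.2)
sp = simulate_session_pair(cfg, specs, pair, n_laps=40, seed=1)

a1 = analyze_session(sp.session1.traj, sp.session1.events, cfg, seed=2)
a2 = analyze_session(sp.session2.traj, sp.session2.events, cfg, seed=3)
print(f"session 1: {len(a1.place_cell_ids)} / {len(a1.table)} cells are place cells")

report = compare_sessions(a1, a2)
print("retention:", report.table["retention"].value_counts().to_dict())
print("zone PV scores:", {k: round(v, 3) for k, v in report.zone_scores.items()})
```

prints

```
session 1: 60 / 60 cells are place cells
retention: {'stable': 30, 'remapped': 17, 'lost': 13}
zone PV scores: {'opto': 0.468, 'control': 0.54, 'ends': 0.565}
```

All 60 strongly tuned simulated cells are detected; the recovered retention
mix (50% / 28% / 22%) matches the generating mixture (0.5 / 0.3 / 0.2), and
the population-vector zone scores sit around 0.5, reflecting that half the
cells kept their fields between sessions.

The same stages are available from the shell:

```
placefields simulate --config conf.yaml --seed 1 --out s1/
placefields analyze s1/ --out r1/
placefields stability s1/ s2/ --out st/
placefields register s1/ s2/ --out reg/
```

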