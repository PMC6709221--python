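# hinet — heartbeat-induced cortical network analysis

Does the heartbeat do more than evoke local cortical responses — does it
transiently *synchronize* distant cortical regions into a network? `hinet`
implements the full analysis chain needed to ask that question of
heartbeat-locked electrophysiology (MEG/EEG-style multi-region recordings
with a simultaneous ECG), and a synthetic-data generator that plants known
coupling so every stage can be validated end to end.

The package is for researchers working on cardiac interoception,
heartbeat-evoked responses (HERs), and resting-state phase-coupling
analyses.

## What it computes

1. **Heartbeat-locked epochs.** Pan-Tompkins R-peak detection on the ECG,
   reassembly of segmented recordings with explicit NaN gaps, epoching from
   −900 to +1800 ms around each R-peak with rejection of gap-containing
   epochs.
2. **Theta phase coupling.** Complex Morlet coefficients (4–7 Hz, 4 cycles,
   20 ms steps over −300..+600 ms) and the debiased weighted phase-lag
   index across trials,

   wPLI‑D = [ (Σⱼ Iⱼ)² − Σⱼ Iⱼ² ] / [ (Σⱼ |Iⱼ|)² − Σⱼ Iⱼ² ],   Iⱼ = Im(aⱼ b̄ⱼ),

   which is immune to zero-lag (volume-conducted) relations by
   construction.
3. **The heartbeat-induced network (HIN).** Edge-wise paired t tests of
   induced (+200..+600 ms) vs baseline (−300..−100 ms) matrices, thresholded
   at t = 2.51, connected-component scoring and permutation (sign-flip) FWE
   control — the network-based statistic. Significant components define the
   heartbeat-induced synchronization (HIS) matrix.
4. **Artifact controls.** ECG–region coupling changes (FDR-corrected) rule
   out cardiac field artifacts; trial-shuffled forward/inverse-modelled
   surrogates (LCMV beamformer round trip) rule out phase-locked evoked
   responses masquerading as induced coupling.
5. **Network characterization.** Hubs (strength, weighted betweenness on
   1/w lengths), consensus Louvain modularity (agreement-matrix iteration,
   τ = 0.2) with significance against weight-preserving random networks,
   within-module degree z / participation-coefficient connector hubs
   (z > 2.5, P > 0.3), between-module interaction graphs, hemispheric
   asymmetry, and the post-heartbeat synchronization time course.
6. **Affect.** PCA of seven affect scores to a mood component, stepwise
   regression on module synchronizations, robust-regression and Spearman
   checks.

## Worked example

Simulate a 12-subject group in which heartbeats induce theta bursts with
fixed phase lags on two region pairs, then infer the network:

```python
import numpy as np
from hinet import (SimulationConfig, simulate_group, extract_epochs,
                   morlet_tf, connectivity_stack, HeartbeatNetworkModel)

sim = SimulationConfig(
    n_regions=8, n_sensors=16, n_heartbeats=200, sampling_rate=200.0,
    mean_ibi=1300.0, ibi_sd=100.0,
    coupled_edges=[(0, 1, np.pi / 2, 1.0), (1, 2, np.pi / 3, 1.0)],
    burst_amplitude=3.0, seed=0,
)
stacks = []
for subj in simulate_group(sim, n_subjects=12, master_seed=0):
    epochs = extract_epochs(subj.sources, subj.rpeaks)
    stacks.append(connectivity_stack(morlet_tf(epochs)))

model = HeartbeatNetworkModel.from_stacks(stacks)
results = model.fit(n_permutations=499, seed=1)
print(results.summary())
print(results.hubs(top=3).round(3).to_string(index=False))
```

Output:

```
Heartbeat-induced network (NBS) results
==============================================
subjects:            12
regions:             8
t threshold:         2.51
permutations:        499
components found:    1
  component 0: 2 edges, stat=568.87, FWE p=0.002
HIN edges:           2
HIN density:         0.0714

  region  strength  betweenness
region_1     1.841          1.0
region_0     0.957          0.0
region_2     0.884          0.0
```

Exactly the two planted edges (0–1, 1–2) survive the familywise-error
threshold: the component of 2 edges has FWE p = 0.002 (the permutation
floor at 499 flips is 1/500), the network density is 2/28 = 7.1 %, and the
shared region 1 is the hub — the largest summed edge weight (1.84, the sum
of both induced-minus-baseline wPLI-D increases) and the only node on a
shortest path between others. From `results` one can go on to
`consensus_modules()`, `between_modules(partition)`, `node_roles(partition)`
and `plot_timecourse(stack)`; `MoodAffectModel` relates module
synchronization to affect scores.

A command-line interface wraps the same pipeline:

```sh
hinet simulate --regions 20 --heartbeats 200 --edge "0,1,1.5708" --out rec.h5
hinet analyze --subjects 15 --regions 8 --permutations 500 --seed 1 --out out/
hinet report out/summary.json
```

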