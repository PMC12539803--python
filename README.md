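# oromotor

Analysis of how orofacial sensorimotor cortex (OSMCx) encodes the
three-dimensional direction of tongue movements during natural feeding and
drinking — directional tuning of single neurons, factor-analysis population
trajectories, and population decoding — together with a synthetic-session
generator with known ground truth, so every stage of the pipeline can be
validated end to end without recorded data.

It is written for systems/computational neuroscientists working with
simultaneously recorded 3D tongue kinematics (200 Hz marker trajectories in
a cranial coordinate frame) and spike trains from primary motor (MIo) and
somatosensory (SIo) orofacial areas, including sessions with a temporary
oral nerve block that removes tactile feedback.

## The model and statistics at its core

**Movement direction.** Over each 100 ms interval of feeding, the 3D angle
of tongue-tip motion is

&theta; = tan⁻¹( ‖v₁ × v₂‖ / v₁ · v₂ ),

with v₁, v₂ the positions at the interval's start and end. The displacement
Δ = v₂ − v₁ is classified by component signs into eight octants (AntSupL …
PostInfR), into six 10° left-right bins on [−30°, 30°), and into yaw/pitch
angles. For drinking, direction is the spout (left/middle/right) targeted by
each lick, and rates are taken in a ±250 ms window around minimum
protrusion.

**Single-neuron tuning.** A neuron's directional modulation is tested by a
rank-based bootstrap (resampling rates into an equal number of trials per
direction, 1000 times); tuned neurons are then fit with the classic cosine
model

f = b₀ + bₓdₓ + b_y d_y + b_z d_z,

whose significant fits (overall F-test) yield a preferred direction
PD = (bₓ, b_y, b_z)/‖·‖ on the unit sphere. Depth of tuning is the
directional index DI = (max − min)/max of per-direction mean rates;
variability is the Fano factor (spike-count variance/mean), with a
mean-matched variant for cross-region comparison. PD distributions are
compared with a spherical Rayleigh test and a circular concentration
(k) test.

**Population trajectories.** Spike counts in 10 ms bins follow the factor
analysis model y ~ N(&mu;, C′C + R) with diagonal R; dimensionality m is
chosen by threefold cross-validated likelihood, and trial-averaged counts
projected through the posterior mapping give latent trajectories per
direction. Direction separation is the per-bin Euclidean inter-trajectory
distance (first m = 20 factors), contrasts are the geometric index
GI = (d₁ − d₂)/(d₁ + d₂), and dynamics are summarised by cumulative path
length.

**Decoding.** A K = 7 nearest-neighbour classifier on z-scored rates
(stratified 80/20 splits, 100 iterations, 28-neuron subsamples) predicts the
three-class direction; an LSTM regressor (five-fold CV, 85/15, five
28-neuron groups, mean R²) predicts the continuous direction angle from
binned counts.

## Worked example

```python
import numpy as np
from oromotor import SimConfig, generate_session
from oromotor.tuning import rate_matrix_from_session, tuning_summary, rayleigh_test_sphere

cfg = SimConfig(behavior="feeding", n_trials=10, trial_dur=10.0, seed=42)
session = generate_session(cfg)                       # kinematics + spikes + ground truth
rm = rate_matrix_from_session(session, balance=True, seed=0)
table = tuning_summary(rm, B=1000, seed=0)            # one row per neuron

mio = table["area"].isin(["rMIo", "cMIo"])
print(f"samples per octant: {np.sum(rm.labels == rm.labels[0])}")
print(f"tuned MIo: {table.loc[mio, 'modulated'].mean():.2f}")
print(f"tuned SIo: {table.loc[~mio, 'modulated'].mean():.2f}")
pds = table.dropna(subset=["pd_x"])[["pd_x", "pd_y", "pd_z"]].to_numpy()
stat, p = rayleigh_test_sphere(pds)
print(f"PDs: n={len(pds)}, Rayleigh stat={stat:.1f}, p={p:.2e}")
```

prints

```
samples per octant: 39
tuned MIo: 0.90
tuned SIo: 0.55
PDs: n=39, Rayleigh stat=41.9, p=4.31e-09
```

The session was generated with 80% of motor and 52% of somatosensory
neurons truly cosine-tuned, with preferred directions clustered toward
anterior-superior-left movements: the bootstrap flags most MIo and about
half of SIo neurons as directionally modulated, and the fitted PDs are
strongly non-uniform on the sphere, as the generator intended.

The same pipeline is scriptable from the shell:

```bash
oromotor simulate --config sim.yaml --seed 3 --out sess
oromotor tune sess --seed 1 --out tuned
oromotor report sess --seed 1 --out report
```

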