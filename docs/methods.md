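# Methods

This note documents the models, conventions and numerical choices behind
`oromotor`, and what the synthetic-data generator does and does not emulate.

## Coordinate frame and direction conventions

Positions are in mm in a cranial frame with the origin at the posterior
nasal spine: x posterior(−)/anterior(+), y left(−)/right(+),
z inferior(−)/superior(+). The 3D movement angle over an interval is
computed as `atan2(‖v1×v2‖, v1·v2)` on the *position* vectors at the
interval endpoints — numerically exact at 0° and 180°, unlike the arccos
form — while all categorical labels (octants, left-right bins, yaw/pitch)
are derived from the *displacement* v2 − v1, since the labels describe the
movement, not the position. Zero displacement components are assigned to
the positive side (anterior/right/superior) so octant labelling is a
deterministic partition; zero-length displacements are flagged undefined
and excluded from tuning samples. Left-right bins are half-open
[a, a + 10°) over [−30°, 30°), with −30° included and +30° excluded;
rightward is positive. Marker smoothing is a 4th-order zero-phase
Butterworth low-pass at 30 Hz (order chosen as the common default for
kinematic smoothing; zero-phase so event times are not lagged).

Feeding analysis windows are consecutive non-overlapping 100 ms intervals
tiled within each annotated gape cycle; drinking windows are ±250 ms around
each minimum protrusion (licks whose full window does not fit inside the
trial are dropped so window lengths stay uniform).

## Synthetic sessions

The generator's role is parameter recovery: every downstream statistic can
be checked against known ground truth. It emulates

- **Feeding**: a ~2 Hz asymmetric protrusion–retraction cycle (60% of the
  cycle protruding, so anterior-superior directions dominate), a vertical
  component lagging the anterior one by a per-cycle random 5–20% of the
  cycle (without this lag the two components are perfectly coupled and half
  the octants never occur), low-amplitude lateral and high-frequency jitter
  proportional to the configured amplitudes (so zero amplitude gives a
  constant trajectory), and per-cycle amplitude jitter. Defaults: 10 mm
  anterior, 6 mm vertical, 1.5 mm lateral amplitude — plausible macaque
  tongue excursions.
- **Drinking**: smooth out-and-back licks (sin² profile) at 1.5 Hz from a
  rest position to one of three spouts (±8 mm lateral, ~12 mm anterior),
  with isotropic endpoint scatter (SD 0.8 mm). The lick period is snapped
  to an even number of 200 Hz samples so maximum protrusion falls exactly
  on a grid sample.
- **Neurons**: inhomogeneous Poisson spiking with the rectified cosine rate
  max(0, b0 + k·(u·pd)) on 100 ms direction windows — the minimal
  generative model whose fitted tuning is cosine and whose count
  variability is Poisson (Fano ≈ 1). Default baseline 20 spikes/s,
  modulation 20 spikes/s, both jittered ±30% per neuron. Preferred
  directions are von Mises–Fisher (κ = 2) around anterior-superior-left;
  tuned fractions default to 0.8 in motor areas and 0.52 in somatosensory
  areas, mirroring the qualitative motor/somatosensory asymmetry at a
  50-neuron desk scale.
- **Nerve block**: endpoint SD ×3, speed ×0.7, tuned fraction ×0.6, and a
  von Mises–Fisher rotation (κ = 20) of each surviving preferred direction.
  A sham condition is generated identically to control; only its seed
  differs.

Not emulated: tongue biomechanics, jaw kinematics, multi-marker tongue
shape, cycle-type structure (all cycles are labelled `chew`; cycle-type
classification is manual in real data), bout structure within trials,
non-Poisson spiking history effects, and electrode/sorting artefacts.
Passing tests therefore demonstrate that the *pipeline* is correct and
calibrated, not that real OSMCx data will show any particular effect size.

A session-level caveat worth knowing: natural-style feeding kinematics are
direction-anisotropic (movement directions cluster along the protrusion
axis), so cosine-fit PD recovery from a full synthetic session is
noticeably worse (~25–30° median angular error) than from the balanced
within-octant direction sampler (~5° at 50 samples/octant). Both are
exercised in the tests; the strict recovery bound applies to the balanced
design where direction coverage actually supports it.

## Statistical choices

- **Bootstrap modulation test.** Rates are ranked within a neuron; the
  statistic is the largest absolute deviation of a per-direction mean rank
  from the grand mean rank. Its null distribution is obtained by resampling
  the rates with replacement into an equal number of trials per direction,
  ignoring labels (exchangeability under no modulation), B = 1000 times; a
  neuron is modulated when the observed statistic exceeds the 95th
  percentile. Resampling under the pooled null makes the familywise type-I
  error equal to α by construction (measured 5.2% on 500 untuned neurons);
  per-direction confidence intervals around the observed deviations would
  not be calibrated, because eight correlated 95% intervals are tested at
  once.
- **Cosine fit regressors** are the eight octant centroid unit vectors
  (±1, ±1, ±1)/√3 — one representative vector per direction group — rather
  than per-sample displacement directions. The PD is reported only when the
  overall F-test is significant at α = 0.05.
- **Directional index** DI = (max − min)/max over per-direction mean rates:
  bounded in [0, 1], invariant to multiplicative rate scaling.
- **Drinking preferred direction** is the bootstrap distribution (B = 1000)
  of the maximal-rate spout under within-spout resampling, with ties broken
  uniformly at random. Note that for a single finite dataset this
  distribution concentrates on the spout with the luckier sample mean;
  uniformity under exchangeable rates holds only averaged over datasets.
- **Mean-matched Fano factor**: per-neuron mean counts are binned into a
  20-bin common histogram; each group is greedily down-sampled to the
  bin-wise minimum, repeated 50 times with a seeded generator, and the
  per-neuron Fano factors of retained neurons are averaged.
- **Circular k-test**: Fisher's variance-ratio concentration test
  f = [(n₂−1)(n₁−R₁)]/[(n₁−1)(n₂−R₂)] against F(n₁−1, n₂−1), two-tailed.
  The approximation assumes concentrated samples; a warning is issued when
  the pooled mean resultant length is below 0.7.
- **Spherical Rayleigh test**: 3n‖mean vector‖² against χ²(3); p-values
  verified uniform under the uniform-sphere null.
- **No multiple-testing correction** is applied across neurons; per-neuron
  tests are reported raw, and population claims are made through the
  proportion comparisons (chi-square of homogeneity, without continuity
  correction so identical proportions give a statistic of exactly zero).

## Factor analysis

Counts are binned at 10 ms (10 bins per feeding window, 50 per drinking
window), neurons below 1 spike/s are excluded, and bins are smoothed with a
10 ms-SD Gaussian kernel (truncated, constant-padded: interior spike mass
is preserved; a few percent can leak at window edges). The EM fit is
scikit-learn's `FactorAnalysis` (LAPACK SVD per step, deterministic;
convergence tolerance 1e-3, max 500 iterations — non-convergence warns and
returns the best model). The per-iteration log-likelihood trace is exposed
and checked non-decreasing to within a 1e-8 relative round-off slack.
Dimensionality is selected by threefold cross-validated held-out
log-likelihood over a candidate list.

Projection to latent space uses the posterior expectation
E[z|y] = (I + CR⁻¹Cᵀ)⁻¹CR⁻¹(y − μ); the default workflow fits the model on
single-trial observations and projects trial-averaged counts, which is
well-defined because the map is linear. Shared variance explained by k
factors is the cumulative eigen-spectrum of C′C over its total. When fewer
than the requested 20 factors exist, distance computations use what is
available and warn. The control-condition model is the reference space
when comparing control and nerve-block trajectories, so condition effects
are measured in a common basis.

## Decoding

KNN: per-iteration stratified 80/20 splits whose seeds derive only from
(config seed, iteration index), so populations compared under one seed see
identical partitions (asserted via recorded split hashes); z-scoring
parameters come from the training fold only; a fresh random 28-neuron
subsample is drawn per iteration when the population is larger; ties fall
back to the nearest neighbour (scikit-learn's behaviour at odd K with three
classes). The chance-level calibration uses 3000 trials: the 100 iterations
reuse one dataset, so the Monte-Carlo error of mean accuracy is governed by
trial count, and 3000 trials bring it to about one percentage point.

The LSTM decoder is a single-layer LSTM with linear readout implemented in
numpy (Adam, truncated BPTT over 20-step subsequences, mini-batches of 4,
gradient-norm clipping at 5; gradients verified against finite
differences). Tests run a reduced 32-unit/20-epoch network; the
400-unit/50-epoch configuration is available through `DecodeConfig`.
Neuron groups are drawn with replacement only when subsampling a strictly
larger population — sampling the whole population with replacement would
randomly discard ~37% of neurons. Feeding targets are the continuous
left-right angle; drinking targets are −45/0/45° per spout. Decoder
performance across behaviors/regions/conditions is compared with OLS
including pairwise interactions (statsmodels); single-level factors are
dropped automatically.

## Problem sizes and determinism

Default test problem sizes (10-trial sessions of 10 s, 50–100 neurons,
B = 1000 bootstraps, 3000-trial decoder calibrations, 10-seed
dimensionality recovery) were chosen so each check has comfortable
statistical resolution at interactive runtimes. Every stochastic step takes
an explicit seed or `numpy` Generator; identical configuration plus seed
reproduces sessions, resamples, splits and fits bit-identically.

## Known limitations

- The generator's kinematic parameter values are plausible but not
  calibrated to measured tongue kinematics; absolute effect sizes carry no
  empirical meaning.
- The exact yaw/pitch decomposition used downstream of the octant analysis
  follows the conventional spherical convention (yaw from the anterior
  axis in the horizontal plane, pitch as elevation); other decompositions
  would permute labels near the poles.
- The concentration k-test loses accuracy for diffuse angular samples
  (pooled resultant < 0.7); it warns rather than switching approximations.
- Across-session neuron stability testing (waveform-based) is out of
  scope; synthetic sessions share neuron identities by construction.
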