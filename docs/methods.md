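# Methods

`hinet` infers and characterizes the network of cortical region pairs whose
theta-band phase synchronization increases after a heartbeat, together with
the artifact controls that make "induced" a defensible claim, and a
synthetic-data generator that plants known structure for validation. This
note documents the model, the choices behind every tunable, and what the
synthetic validation does and does not establish.

## Pipeline model

1. **Heartbeat anchoring.** R-peaks are detected in a single-channel ECG by
   the Pan-Tompkins cascade: 5–15 Hz zero-phase Butterworth band-pass,
   derivative, squaring, 150 ms moving-window integration, adaptive
   signal/noise thresholds with a 200 ms refractory period and search-back
   at half threshold once 1.66× the running RR average elapses without a
   detection. Each detection is snapped to the local ECG maximum, so the
   reported index is the R-peak sample. Segmented recordings are first
   reassembled at their original offsets with NaN in uncovered spans.

2. **Epoching.** One epoch per R-peak, −900 to +1800 ms, fixed length
   `round(2700 ms × fs / 1000)` samples (1373 at 508.68 Hz). Epochs touching
   a missing sample are rejected and counted; peaks whose window exceeds the
   recording are dropped silently. Epochs are allowed to overlap neighbouring
   heartbeats — the window is wider than a typical interbeat interval and no
   overlap exclusion is applied (see *Known limitations*).

3. **Time–frequency decomposition.** Complex Morlet wavelets, unit energy,
   Gaussian envelope with σ_t = n_cycles/(2πf), truncated to a compact
   support of exactly `n_cycles` carrier periods (4 cycles by default; 1 s at
   4 Hz, hence the ±500 ms padding requirement that the −900..+1800 ms epoch
   satisfies for the −300..+600 ms analysis grid at 20 ms steps).
   Coefficients are computed by FFT convolution and sampled on the grid;
   requesting a grid point whose wavelet support leaves the epoch is an
   error, never an edge-padded estimate.

4. **Connectivity.** The debiased weighted phase-lag index. With per-trial
   cross-spectrum imaginary parts I_j,

       wPLI-D = [ (Σ I_j)² − Σ I_j² ] / [ (Σ |I_j|)² − Σ I_j² ].

   Zero-lag (purely real) cross-spectra give exactly 0 — the estimator's
   immunity to instantaneous linear mixing (volume conduction / field
   spread). The imaginary parts are computed term-by-term
   (`ya·xb − xa·yb`, separately rounded) rather than through the fused
   complex multiply, so mathematically proportional channels yield exact
   zeros in floating point as well. The estimator may be slightly negative
   in finite samples; values are reported unclipped, since the paired tests
   downstream depend only on differences. A vanishing denominator (all
   I_j = 0) returns 0: no lag evidence. wPLI-D is computed per pair, per
   grid time point and per frequency (4–7 Hz in 1 Hz steps for theta), then
   averaged across frequencies. The −300:20:600 grid has 46 points; the two
   analysis windows are the baseline (−300 to −100 ms, 11 points) and the
   induced window (+200 to +600 ms, 21 points), endpoint-inclusive.

5. **Network inference (NBS).** Per-subject baseline and induced matrices
   are compared by edge-wise paired t tests (positive t = increase). Edges
   with t ≥ 2.51 form a graph; each connected component is scored by the sum
   of its edge t values. The null distribution of the maximum component
   score is built by flipping each subject's condition labels independently
   with probability ½ (paired-design sign flip; the whole matrix is swapped
   per subject). FWE p per component is (b+1)/(m+1), so the smallest
   attainable p is 1/(m+1); when the requested permutation count reaches the
   2^n distinct assignments the null is enumerated exhaustively instead and
   p is the exact orbit fraction. The HIS (heartbeat-induced
   synchronization) matrix carries the group-mean induced-minus-baseline
   difference on the edges of significant components and zero elsewhere;
   density is edges / C(n,2). One-sided inference is used for the network
   (it is defined by increases); the ECG control below is two-sided.

6. **Artifact controls.**
   *Cardiac-field control:* wPLI-D between the identically epoched ECG and
   every region, both windows, two-sided paired t per region with
   Benjamini–Hochberg correction. A common electromagnetic artifact would
   couple the ECG to exactly the implicated regions.
   *Evoked-response control:* trial-shuffled forward/inverse surrogates.
   Per region, the trial assignment of its source vertices is permuted
   (jointly within a region, independently across regions and surrogate
   sets), the result projected through the leadfield, reconstructed with the
   same LCMV filter as the real data, ROI-averaged, and the full wPLI-D
   stack recomputed. Shuffling destroys induced (non-phase-locked) coupling
   while preserving evoked components and all linear signal spread. Network
   synchronization = Σ over HIS edges of (induced − baseline) window means;
   the Monte Carlo p is the plain fraction of surrogate sets at or above the
   real value, so exceeding all 20 surrogates gives p = 0 < 1/21.

7. **Source model.** Scalar (single-orientation) sources and a dense
   leadfield. LCMV rows w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹ with diagonal loading
   C + reg·mean(diag C)·I; unit gain on each source's own column holds by
   construction. The covariance is estimated from all epochs' concatenated
   sensor data; default regularization 5% of the mean sensor variance — a
   conventional loading in beamformer practice, and the round-trip is exact
   in the invertible noiseless case with reg = 0.

8. **Graph characterization.** Strength = incident weight sum. Betweenness
   is Brandes' unnormalized pair-dependency count on edge lengths 1/w
   (stronger synchronization = shorter path; raw counts can be of order n²
   on connected graphs). Modularity
   Q = 1/(2μ) Σᵢⱼ [Aᵢⱼ − γ·sᵢsⱼ/(2μ)] δ(gᵢ,gⱼ) with 2μ the total
   (double-counted) weight and γ = 1. Louvain runs are seeded; consensus
   partitioning iterates (n runs → agreement matrix D → threshold τ = 0.2 →
   re-partition D) until D is binary block-diagonal, and Q is reported on
   the original matrix. Significance compares consensus Q with
   weight-preserving random networks: same node count, same edge count, the
   exact weight multiset shuffled onto uniformly resampled edge slots; p is
   the fraction of null Q at or above the observed. Node roles use the
   within-module degree z (population SD within each module, so module
   z-scores have mean 0, SD 1 exactly; singleton or zero-variance modules
   get z = 0 with a warning) and the participation coefficient
   P = 1 − Σₛ(κᵢₛ/sᵢ)²; connector hubs satisfy z > 2.5 and P > 0.3.
   Between-module interaction is the module-pair sum of inter-module edge
   weights, with strength/betweenness applied at module level. The HIN time
   course sums the wPLI-D stack over HIS edges per grid point, optionally
   baseline-subtracted over (−300, −100) ms.

9. **Affect analysis.** Seven survey scores (six negative affect scales and
   positive affect) are z-scored and reduced by PCA on the correlation
   matrix (scales differ, so correlation rather than covariance); the first
   component is sign-fixed to load positively on positive affect. The
   component is regressed on within- and between-module synchronization by
   forward–backward stepwise OLS (enter p < 0.05, remove p > 0.10 — common
   defaults, exposed as parameters), with bisquare robust regression and
   Spearman correlation as outlier-resistant checks on any selected
   predictor. An intercept-only outcome is a valid result.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis assumes, at
a controllable scale. Defaults mirror a resting-state MEG study: 195
regions, 248 sensors, 840 heartbeats, 508.68 Hz sampling, interbeat
intervals Normal(981.8, 151.5) ms truncated below at 300 ms (a physiological
floor that also keeps QRS templates disjoint).

* **ECG**: a stereotyped P-QRS-T template (R amplitude 1) at each peak over
  baseline noise (SD 0.02) — enough morphology to exercise every
  Pan-Tompkins stage, not a cardiac dipole model.
* **Induced coupling**: per coupled edge and heartbeat (with probability
  `coupling_prob`), a Hann-windowed theta burst (default carrier 5.5 Hz)
  spanning the configured post-R window is added to both endpoint regions.
  The burst's absolute phase is uniform per heartbeat; the between-region
  phase difference equals the edge's lag. Lags of 0 or π are rejected at
  validation: they carry no imaginary cross-spectrum and are undetectable
  by any lag-based metric. The Hann support keeps the baseline window
  clean. Shared endpoints across edges superpose their bursts, so planted
  paths experience realistic interference.
* **Evoked components**: the identical deterministic waveform at every
  heartbeat in each evoked region, with a fixed region-specific phase
  offset (golden-angle spaced). Distinct offsets matter: they create the
  lagged, trial-consistent spurious synchronization that only the surrogate
  control can separate from genuinely induced coupling; identical phases
  everywhere would be absorbed by the estimator's zero-lag immunity and
  leave nothing to control for.
* **Noise**: white Gaussian per region (SD 1 by default), with an optional
  1/f flag. White is the default deliberately — the phase-based estimator's
  null calibration must not be an artifact of spectral shape. The default
  burst amplitude (2, i.e. 2:1 against the noise SD; validation scenarios
  use 3) is a free effect-size parameter: no empirical value for the
  real-world induced effect size is asserted anywhere in the package.
* **Forward model**: an SVD-constructed sensors×regions matrix with
  log-spaced singular values giving exactly the requested condition number
  (orthogonal columns at 1). Abstract mixing, not volume conduction.
* **Affect**: a latent mood = slope × z(module synchronization) + noise,
  loading positively on the positive-affect column (+0.82) and negatively
  (−0.70..−0.85) on the six negative columns, plus unique noise (SD 0.6),
  written on a T-score-like scale.

Subjects are simulated i.i.d. with per-subject seeds spawned from one master
seed; identical seeds reproduce every array bit for bit.

**What passing tests do not show.** The generator's noise is stationary,
Gaussian and spatially white; real MEG has 1/f backgrounds, correlated
sensor noise, non-neural artifacts and imperfect head models. Recovery of
planted edges at high SNR demonstrates that the machinery is correct, not
that real effects of unknown (likely far smaller) size are detectable at
these sample sizes. The affect model plants a one-factor structure that real
survey batteries only approximate.

## Validation problem sizes

Validation runs use reduced scales chosen for statistical power per unit
compute, not study realism: 8–20 regions, 200 Hz sampling, 60–200
heartbeats, 15 subjects, 199 permutations, consensus with 200 runs and 50
random networks (the analysis defaults remain 5000 permutations and 10,000
runs / 100 networks).

One fixture choice deserves its own record. In planted-recovery scenarios
the simulated heart is slow: interbeat intervals 1300 ± 100 ms instead of
the generator's 981.8 ± 151.5 ms default. At ~980 ms spacing, the 4 Hz
wavelet support (±500 ms) reaches across neighbouring heartbeats, so a
trial's analysis windows pick up smeared burst energy from adjacent
heartbeats. For region pairs that both carry bursts but are *not* coupled,
this induces cross-trial dependence that inflates their paired-t
suprathreshold rate several-fold above nominal (measured ≈0.06 vs 0.0125 at
t ≥ 2.51, df 14), and such edges attach to the significant component,
degrading edge-level precision. A pure-noise pipeline null is exactly
nominal (≈0.011), and at 1300 ms spacing the burst-pair rate returns to
nominal (≈0.010): the inflation is a property of overlapping epochs, which
the pipeline deliberately permits, not of the estimator or the test. The
slow-heart fixture isolates edge-recovery behaviour from that overlap
effect; the effect itself is a documented limitation below.

## Numerical choices

* Sample/ms conversion: `round(ms × fs / 1000)`; the time axis is
  R-peak-centred with 0 ms at the R-peak sample.
* Zero-variance edges in paired t tests get t = 0 with a warning (never
  ±inf); permutation t values with degenerate variance are zeroed silently.
* Ties in Louvain are resolved by the seeded node order of
  `networkx.community.louvain_communities`; all stochastic steps
  (permutations, surrogate shuffles, consensus runs, null networks) consume
  seeds derived from a single master seed through `SeedSequence`.
* Consensus non-convergence after 20 iterations raises an error carrying the
  last agreement matrix; in the modularity-significance null loop a
  non-converging random network falls back to its best single-run Q.
* Window membership is endpoint-inclusive with a 1e-6 ms tolerance.
* The empty HIS network (no significant component) is a valid result
  propagated as density 0, not an error.

## Design decisions on genuinely open points

* **Permutation unit**: the paired NBS swaps each subject's whole
  induced/baseline matrices (the standard paired design); edge-wise swapping
  within subjects was considered and rejected as it breaks the topology the
  component statistic relies on.
* **Betweenness lengths**: 1/w rather than −log w; standard for
  synchronization-strength graphs and consistent with large integer
  centrality magnitudes on dense weighted networks.
* **Q normalization**: null term sᵢsⱼ/(2μ) with the conventional 1/(2μ)
  prefactor; any alternative global normalization cancels when comparing
  partitions on a fixed graph.
* **Degrees of freedom**: n − 1 throughout for paired tests.
* **Modularity null**: weight-multiset-preserving rewiring (same edge
  count, weights shuffled onto random slots). A degree-sequence-preserving
  alternative would hold more structure fixed; the multiset null matches
  the "preserved weight distribution" reading and is the implemented one.
* **Stepwise thresholds** 0.05/0.10 and **PCA on correlations** are
  conventional defaults, both exposed as parameters.

## Known limitations

* Overlapping epochs plus finite wavelet support couple neighbouring trials
  at physiological heart rates; near 60 BPM this inflates false synchrony
  between regions that both receive heartbeat-locked bursts (quantified
  above). Analyses at real heart rates should treat edge-level membership
  of the detected component more cautiously than network-level existence,
  which the max-statistic FWE control protects regardless.
* The NBS permutation test is mildly conservative at 199 permutations
  (empirical null rejection ≈0.035–0.045 at nominal 0.05) due to the
  discrete p grid and datasets with no suprathreshold edge.
* The surrogate control's Monte Carlo p with 20 sets resolves no finer than
  1/20; for evoked-only data the real value is exchangeable with the
  surrogates by construction, so its rank is uniform and occasional extreme
  ranks are expected.
* LCMV here is algebraic machinery on abstract leadfields; no claim is made
  about realistic volume conduction, head geometry or depth bias.
* Hemispheric asymmetry requires the caller to supply the left/right edge
  split; the synthetic generator has no geometric hemispheres.
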