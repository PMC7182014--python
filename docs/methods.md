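# Methods

## Model and procedure

The package treats resting-state brain activity as a trajectory through a
discrete repertoire of whole-brain BOLD phase-locking (PL) states.

1. **Phase extraction.** Each region's signal is demeaned and extended to
   its analytic form with the Hilbert transform, yielding an instantaneous
   phase θ(n, t) and amplitude A(n, t). The first and last samples are
   dropped (boundary artifacts of the transform), so a scan of T samples
   contributes T − 2 observations.
2. **Instantaneous coherence.** At each retained TR the pairwise phase
   coherence is dPC(n, m, t) = cos(θ(n, t) − θ(m, t)), computed as
   cosθ·cosθᵀ + sinθ·sinθᵀ. This is the Gram matrix of the unit phasors
   (cos θ, sin θ), hence exactly symmetric, positive semidefinite, with
   unit diagonal and trace N.
3. **Leading-eigenvector reduction.** The dominant eigenvector V1(t) of
   dPC(t) (full symmetric eigendecomposition; exactness over speed at
   N ≤ 512) summarizes the phase-locking pattern at t in 1 × N numbers.
   Eigenvectors are sign-ambiguous, so each V1 is flipped to satisfy
   mean(V1) ≤ 0 (exact-zero ties: first nonzero element negative; the flip
   is idempotent). Under this convention the minority community whose
   phase is shifted away from the dominant orientation carries the
   positive entries. Near-degenerate leading eigenvalues (gap < 1e-10)
   keep the deterministic solver output and emit a warning.
4. **State partition.** The V1 observations pooled over the discovery
   session are clustered by k-means under the cosine distance
   d(x, c) = 1 − x·c/(|x||c|). Each of `n_replicates` (default 100)
   replicates initializes its centroids on k distinct observations drawn
   from a seeded stream; clusters emptied during iteration are re-seeded
   with the worst-fitting observation; iteration stops when labels are
   stable or after 300 rounds; the replicate with minimal total
   within-cluster cosine distance wins. States are re-indexed by
   descending pooled occupancy, so state 1 is always the most frequent
   (in practice the globally synchronized) pattern. Assignment ties break
   to the lowest centroid index, making runs order-stable and
   bit-for-bit reproducible given the seed.
5. **Validation projection.** Scans of the held-out session are assigned
   to the already-fitted centroids by nearest cosine distance; the
   centroids are never refit.
6. **Trajectory statistics**, per scan (stationarity within scan assumed):
   fractional occupancy Π_α; dwell time DT_α as mean maximal-run length ×
   TR; joint transition probability Π_αβ over the T′ − 1 consecutive
   pairs; conditional transition matrix W_αβ = Π_αβ / Π′_α.
7. **Reliability.** Intra-class correlation
   ICC = (MSE_b − MSE_w)/(MSE_b + MSE_w) between two sessions with the
   one-way random-effects decomposition at two repeats (MSE_b =
   2Σ(x̄_s − x̄)²/(S − 1), MSE_w = ΣΣ(x_sj − x̄_s)²/S), which equals the
   classical ICC(1,1). Categories: low (0–0.2], fair (0.2–0.4], moderate
   (0.4–0.6], substantial (0.6–0.8], almost perfect (0.8–1]; non-positive
   values are reported as "negative", zero-variance metrics as
   "undefined".
8. **Network overlap.** A reference atlas of M networks and an N-region
   parcellation on a shared grid reduce to an M × N voxel-proportion
   matrix. Centroids are rectified (negatives → 0, keeping the shifted
   community) and correlated with each network row by Pearson's r, with
   two-sided p from the t transform at N − 2 degrees of freedom and
   Bonferroni correction per partition (α/k) or per state (α/M).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `tr` | 0.72 | s | sampling interval of the emulated acquisition |
| `k` | 5 | — | within the silhouette-optimal range; separates the canonical subsystems |
| `n_replicates` | 100 | — | stabilizes the k-means solution |
| filter band | none | Hz | headline analysis keeps all frequencies up to Nyquist (0.694 Hz at TR = 0.72 s); optional 2nd-order Butterworth band-pass applied zero-phase |
| `eq4_literal` | False | — | see "Transition-matrix normalization" |
| `include_boundary_runs` | True | — | see "Dwell-time boundary runs" |
| `silhouette_subsample` | 20000 | samples | full pairwise cosine distances are quadratic in the pooled count; a seeded uniform subsample bounds memory |

## Synthetic generator

The generator emulates N regional oscillations at a carrier frequency
(default 0.05 Hz) whose phase configuration switches between k planted
patterns: pattern 1 is global in-phase; patterns 2..k shift a disjoint
minority community (default N//k contiguous regions, always fewer than
N/2) by π. Switching follows a homogeneous Markov chain started at its
stationary distribution so finite-T occupancies are unbiased. The default
chain has global-state self-transition 0.77, ghost self-transitions 0.45
and ghost→global return 0.24, putting the stationary occupancy of the
global state at 0.24/(0.23 + 0.24) ≈ 0.51 and giving mean ghost dwell
times near two TRs — the regime reported for empirical resting-state
phase-locking dynamics. Noise enters as independent per-region,
per-sample Gaussian jitter of the phase argument (default SD 0.3 rad) and
additive Gaussian amplitude noise (default SD 0.2 on unit-amplitude
signals). One integer seed drives all streams (chain, jitter, noise;
per-scan seeds are derived deterministically per subject and session).

What the generator does **not** emulate: hemodynamic convolution,
spatially correlated noise, region-specific spectra, scanner drifts, and
subject-level heterogeneity (sessions of a "subject" are independent
realizations). Consequently, passing recovery tests demonstrates the
correctness of the estimator chain on data obeying the model's
assumptions; they say nothing about hemodynamic confounds in real data,
and test–retest ICC on synthetic cohorts hovers around zero by
construction (there is no subject fingerprint to detect).

## Numerical choices

- **Zero-phase filtering.** The Butterworth band-pass is applied forward
  and backward (`sosfiltfilt`, reflect padding), because a causal filter's
  frequency-dependent delay would corrupt the Hilbert phases downstream.
  The effective magnitude response is |H(f)|² of the designed order.
  Degenerate band edges fall back to pure high-/low-pass.
- **Transition-matrix normalization.** Dividing the joint Π_αβ by the
  occupancy over all T samples leaves W rows summing to 1 ± O(1/T). The
  default divides by the occupancy over the first T − 1 samples, making W
  exactly row-stochastic (required for graph and stationary analyses);
  `eq4_literal=True` reproduces the literal ratio. The discrepancy is at
  most one sample's worth of probability per row.
- **Dwell-time boundary runs.** Runs truncated by the scan window are
  included by default (`include_boundary_runs=False` drops the first and
  last run). Absent states get missing (NaN) dwell times and W rows, not
  zeros, so group averages are unbiased.
- **Degenerate inputs.** Constant region signals are rejected by name;
  non-symmetric matrices are rejected; a centroid that is constant after
  rectification (the all-negative global state) has no defined Pearson
  correlation and is reported with r = NaN, p = 1, matching "none".

## Known limitations

- **Transition smearing.** The Hilbert transform is temporally nonlocal:
  phases ring across roughly ±2 samples around an instantaneous pattern
  switch. With ghost dwell times near two TRs, the first/last sample of
  short runs is systematically absorbed into the global state: the
  pipeline's group Ŵ deviates from the planted chain by ≈ 0.05–0.06 in
  ∞-norm (vs ≈ 0.015 sampling error when estimating from the true label
  sequences), and the measured global-state occupancy exceeds the planted
  stationary value by ≈ 0.1. Per-TR label agreement is exact only in the
  idealized regime where a scan holds one pattern; with switching it is
  near- but not exactly perfect even at zero noise (adjusted Rand ≈ 0.9
  at self-transition 0.95). This is a resolution limit of TR-level
  Hilbert phase estimates, not an estimator defect.
- P-values for network overlap treat regions as independent samples;
  spatial autocorrelation is not corrected.
- The silhouette subsample trades exactness for memory at large pooled
  counts; values are deterministic given the seed but not identical to
  the full computation.

## Problem sizes used in tests and the acceptance script

Synthetic cohorts use N = 30 regions, k = 5 states, T = 1198 samples and
20 subjects × 2 sessions (the package's chosen desk-scale study
conditions); Markov-estimator consistency uses single chains of length
10⁵; filter checks use 4096-sample sinusoids; the k sweep demonstration
uses a small well-separated cloud.
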