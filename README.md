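# plstates

Analysis of spontaneous brain activity as trajectories through discrete
BOLD **phase-locking states**, for researchers studying dynamic functional
connectivity in resting-state fMRI.

At each repetition time (TR) the instantaneous phase θ(n, t) of every
brain region's BOLD signal (Hilbert transform of the demeaned, optionally
band-passed signal) defines a phase-coherence matrix

    dPC(n, m, t) = cos(θ(n, t) − θ(m, t)),

whose leading eigenvector V₁(t) captures the whole-brain phase-locking
pattern in a single 1 × N vector. Cosine-distance k-means over the pooled
V₁ observations of a discovery session partitions phase space into k
states (centroids V_cα, ordered so state 1 is the most frequent, globally
synchronized pattern); held-out sessions are projected onto the fitted
centroids without refitting. The label trajectory x̄(t) is then summarized
per scan by

- fractional occupancy   Π_α = (1/T) Σ_t 1[x̄(t) ∈ R_α],
- dwell time             DT_α = mean duration of consecutive visits to α (s),
- transition matrix      W_αβ = Π_αβ / Π_α, a homogeneous Markov chain,

and test–retest reliability of each metric across two same-day sessions is
quantified by the intra-class correlation
ICC = (MSE_b − MSE_w)/(MSE_b + MSE_w). State centroids can additionally be
scored against reference intrinsic functional networks (voxel-proportion
vectors per parcel) by Pearson correlation with Bonferroni correction.

A synthetic generator of Markov-switching phase-locked signals with
exportable ground truth (planted ±π community patterns, known transition
matrix) makes the entire chain testable without access to restricted
neuroimaging data.

## Worked example

```python
import numpy as np
from plstates import SyntheticSpec, analyze_scans, simulate_dataset

spec = SyntheticSpec(seed=7)          # N=30 regions, k=5 states, T=1198, TR=0.72 s
cohort = simulate_dataset(spec, n_subjects=10)
result = analyze_scans(
    [ts for ts, _ in cohort["LR"]],   # discovery session
    [ts for ts, _ in cohort["RL"]],   # validation session (assigned, not refit)
    k=5, n_replicates=50, seed=1,
)

print("group fractional occupancy:", result.group_occupancy.round(3))
dt = np.nanmean([m.dwell_time for m in result.discovery_metrics], axis=0)
print("group dwell times (s):     ", dt.round(2))
print("group transition matrix W:")
print(result.group_w.round(3))
print("silhouette (k=5):", round(result.silhouette, 3))
```

prints

```
group fractional occupancy: [0.594 0.108 0.104 0.103 0.091]
group dwell times (s):      [3.76 1.49 1.46 1.44 1.44]
group transition matrix W:
[[0.807 0.052 0.049 0.05  0.042]
 [0.279 0.511 0.065 0.077 0.069]
 [0.281 0.078 0.504 0.072 0.066]
 [0.3   0.063 0.078 0.496 0.064]
 [0.284 0.076 0.081 0.065 0.494]]
silhouette (k=5): 0.725
```

Reading: the globally synchronized state 1 dominates (≈ 0.59 of the time,
dwelling ≈ 3.8 s per visit, 0.81 probability of persisting to the next
TR), while the four planted "ghost" states are brief (≈ 1.4–1.5 s, about
two TRs) and preferentially transition back to state 1 (first column
≈ 0.28–0.30) rather than to each other — the asymmetry that motivates the
Markov-chain description. The generator plants exactly this regime
(stationary global occupancy 0.511, self-transition 0.77); the measured
occupancy is slightly higher because phase estimates smear across state
transitions (see `docs/methods.md`, "Known limitations").
`result.icc_table` holds the per-metric ICC between the two sessions —
near zero here, since synthetic subjects carry no individual fingerprint.

The same pipeline is scriptable from the shell:

```bash
plstates simulate --n-subjects 10 --seed 7 --out data/
plstates run --config config.json     # discovery/validation paths, k, seed, ...
```

producing centroids, per-scan labels and metrics, the group transition
matrix and its GraphML/DOT graph, the ICC table, and a manifest with
checksums for reproducibility.

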