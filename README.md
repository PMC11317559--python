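# markovworm

Markov models of *C. elegans* behavior across scales: from eigenworm
posture time series to foraging trajectories.

## The problem

A crawling worm's posture is summarized per video frame by five
"eigenworm" coefficients `a = (a1..a5)` sampled at `δt = 1/16 s`.  The
instantaneous posture is not a Markov state — the direction of the body
wave, for instance, is only visible over time — so naive models of `a(t)`
need memory.  This package implements the opposite strategy: expand the
state first, then model simply.

1. **Delay embedding.** Stack `K` consecutive frames into one vector
   (sequence space `X_K`).  Choose `K*` as the smallest window at which
   the entropy rate

   `h = − Σ_i π_i Σ_j P_ij log2 P_ij`

   of the symbolized dynamics stops decreasing: past that point, more
   history adds no predictability.
2. **Microstates.** Partition `X_K*` into `N*` k-means cells (`N*` = the
   largest partition count before finite-size sampling starts reducing
   the estimated entropy).  The dynamics become a sparse Markov chain
   `p_j(t+τ) = Σ_i P_ij(τ) p_i(t)`, with the lag `τ*` validated by
   requiring the implied timescales `Λ_i⁻¹ = −τ/ln Re(λ_i)` to be
   independent of `τ`.
3. **Coarse-graining.** The second eigenvector `ϕ₂` of the reversibilized
   operator `P_r = (P + Π⁻¹PᵀΠ)/2` orders microstates along the slowest
   reaction coordinate.  A single threshold on `ϕ₂`, chosen to maximize
   the smaller of the two set coherences
   `χ(S) = Σ_{i,j∈S} π_i (P_r)_ij / π(S)`, splits behavior into
   metastable macrostates (runs vs pirouettes); iterating inside the
   largest-measure state yields finer mesoscopic states with dwell-time
   and kinetic statistics.
4. **Posture to path.** Linear resistive force theory
   (`F_i = α_t v_i^t t̂ + α_n v_i^n n̂`, zero net force and torque) turns
   posture sequences into 2D centroid trajectories; the drag ratio
   `α = α_n/α_t` is calibrated by matching reconstructed to measured
   paths, and trajectories are summarized by `MSD(τ) = 4Dτ`.
5. **Foraging.** Simulating the chain constrained to a single mesoscopic
   state and scattering food uniformly in a disc of radius `r` yields
   per-state efficiencies `p(food|r,S)`, their occupancy-weighted average
   `p(food|r) = Σ_S π(S) p(food|r,S)`, and the probability-matching
   comparison of efficiency vs occupancy.

A synthetic-data module generates posture series with a known hidden
forward/reversal/turn process, exact Markov-chain fixtures, and Brownian
or ballistic tracks, so that every stage is testable without any
recorded data.

## Worked example

```python
import numpy as np
import markovworm as mw

# a 35-minute synthetic worm under the default study conditions
cfg = mw.SyntheticWormConfig(duration_frames=16_000, seed=11)
series, truth = mw.generate_posture_series(cfg)

# embed, partition, and fit the microstate chain
part = mw.partition(mw.delay_embed(series, K=8), N=60, seed=0)
model = mw.estimate_transition_matrix(part.labels, tau_frames=8,
                                      n_states=60, dt=series.dt)
spec = mw.spectrum(model, n_modes=5)
print(f"slowest relaxation time: {spec.relaxation_times_s[1]:.2f} s")

# split along the slowest reaction coordinate; compare with the truth
hier = mw.build_hierarchy(model, 2)
seq = mw.project_labels(hier.labels_at(2), part.labels[::8])
hidden = truth.hidden_label_per_frame[:len(part.labels):8][:len(seq)]
rev = hidden == truth.state_names.index("reversal")
acc = max(np.mean(seq == rev), np.mean(seq != rev))
print(f"reversal-state recovery accuracy: {acc:.3f}")

# propagate posture into a 2D path and estimate diffusion
traj = mw.posture_to_trajectory(series, mw.RFTParams(alpha=30, dt=series.dt))
curve, fit = mw.msd_and_diffusion(traj, fit_range_s=(60, 100))
print(f"effective diffusion D = {fit.D:.2f} BL^2/s (linear: {fit.linear})")
```

Output:

```
slowest relaxation time: 1.58 s
reversal-state recovery accuracy: 0.980
effective diffusion D = 0.19 BL^2/s (linear: True)
```

The slowest mode of the fitted chain (~1.6 s) reflects the hidden
behavioral switching; the top-level metastable split isolates the
reversal regime — the direction of the body wave, invisible in a single
frame — with 98% frame accuracy; and the resistive-force trajectory has
reached its diffusive regime by 60–100 s lags, with an effective D of
about 0.2 body lengths squared per second.

The same workflow is available from the shell:

```sh
markovworm simulate-data --out worm.csv --frames 16000 --seed 11
markovworm embed --input worm.csv --k-grid 1:11 --n-grid 10,20,40,80
markovworm msm --input worm.csv --k 8 --n 60 --tau-grid 1:16
markovworm coarsen --msm msm.h5 --levels 2
markovworm path --postures worm.csv --alpha 30 --msd-fit 60:100
markovworm run --config run.yaml      # full pipeline with a manifest
```

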