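# Methods

This note documents the models, estimators, parameters, and numerical
choices behind `markovworm`, and what the synthetic-data tests do and do
not establish about real recordings.

## Observable and units

The observable is a 5-dimensional eigenworm coefficient series `a(t)`
sampled at `δt = 1/16 s`.  Lengths are measured in body lengths (BL),
times in seconds, rates in events/s, diffusion in BL²/s.  Tangent-angle
profiles `θ_i` (radians, one per body segment) accompany the modes when
available; otherwise they are reconstructed through the mode basis below.

### Synthetic eigenworm basis

The empirical eigenworms are principal components of tracked worm
centerlines and are not shipped with the package.  `basis.py` provides a
synthetic orthonormal stand-in over `M = 32` segments: a quadrature pair
of two-wavelength body waves (modes 1–2), an arc bend with tangent
profile `1 − cos(πs)` (mode 3), and a higher-harmonic quadrature pair
(modes 4–5).  Three consequences are used throughout: a rotation in the
`(a1, a2)` plane translates the body wave along the body; the summed
tangent angle (overall curvature `γ`) is dominated by `a3` (small
leakage from the wave-sine modes survives orthogonalization); and mode 3
carries *net* body curvature, so a bend sustained while the wave runs
physically reorients the worm under the drag model.  The last point is
load-bearing: a bend profile without net curvature (or a bend applied to
a frozen wave) is a reciprocal stroke that linear drag cannot convert
into rotation.  Quantitative posture statistics (mode variances, wave
dispersion) are *not* reproduced, and nothing downstream assumes they
are.

## Synthetic worm generator

The hidden behavioral process is semi-Markov over named states
(default: forward / reversal / turn) with geometric dwell times, making
the composite process exactly Markov at the frame level — a known-truth
case for the embedding selector and the implied-timescale diagnostic.  A
heavy-tailed Lomax dwell option (shape 1.5 by default; 1.3 in the
non-Markov tests) provides a deliberate violation.

Defaults (the study conditions used by tests and the acceptance script):

| parameter | value | rationale |
|---|---|---|
| duration | 33,600 frames (35 min); tests use 8k–16k | recording length of the reference dataset; tests scale down for runtime |
| dt | 1/16 s | reference sampling rate |
| forward dwell | 120 frames (7.5 s) | run durations of off-food foraging |
| reversal dwell | 24 frames (1.5 s) | brief backward bouts |
| turn dwell | 48 frames (3 s) | deep reorientation bouts |
| body-wave frequency | 0.45 cycles/s | crawling wave rate off food, maintained through turns |
| amplitude | 4 (mode units) | gives tangent-angle excursions of O(0.5 rad) |
| turn amplitude (a3) | 10 | net body bend ~3 rad, reorienting heading by tens of degrees per bout |
| turn sign | ventral/dorsal 50/50 | balanced bias; recorded per event in the ground truth |
| noise SD | 0.05 | small observation noise |

The turn settings were chosen so the resulting centroid tracks show the
ballistic-to-diffusive MSD transition between roughly 10 and 100 s that
foraging worms exhibit (scaling exponent falls from ~1.9 at 30–60 s lags
to ~1.3 at 60–100 s under the default drag ratio).

State switching follows a run-and-pirouette motif (forward → reversal or
turn; reversals mostly continue into turns; turns mostly resolve into
forward runs).  Turn visits write one signed raised-cosine pulse into
`a3` (smooth, bounded, analytically integrable), capped at 3 s.  The
configured `phase_velocity` is the rate of increase of the `(a1, a2)`
phase angle; the measured body-wave phase velocity
`ω = −(1/2π) d/dt atan2(a2, a1)` is its negative, and the ground-truth
object records the expected ω per state to keep signs unambiguous.

What passing tests show: the estimators recover planted structure
(dwells, transition probabilities, metastable blocks, drag ratios,
diffusion coefficients) under realistic sizes and noise.  What they do
not show: performance under real-data complications — tracking errors,
nonstationary adaptation of pirouette rates over a recording, posture
statistics outside the synthetic basis span.

## Embedding selection

The entropy rate uses the plug-in (maximum-likelihood) Markov-chain
estimator on the lag-1 symbol sequence.  It is biased downward when the
`N × N` transition table is under-sampled — the selector exploits
exactly this: `N*` is the largest grid value whose plateau entropy has
not dropped below the next-smaller `N`'s by more than that value's
bootstrap SD.  `K*` is the smallest window with
`|h(K) − h(K+1)| < SD(h(K))` (bootstrap SD across worms, or across eight
contiguous blocks for a single series), plus an optional safety margin of
extra delays.  No bias correction is applied; because selection compares
entropies at equal `N` (for `K*`) or looks for the *onset* of bias (for
`N*`), the plug-in estimator is adequate.

k-means uses k-means++ with a recorded seed and multiple restarts (best
inertia); above 256 cells a mini-batch variant keeps pooled fits
tractable.  Empty cells cannot survive scikit-learn's reassignment, but
the effective cell count is reported separately regardless.

## Transition operator and spectrum

Counts `C_ij = #{t: s(t)=i, s(t+τ)=j}` never cross worm boundaries;
ensemble models pool counts before row normalization.  Reducible chains
are restricted to the largest *closed* strongly connected component
(dropped states are logged).  Eigenproblems are dense below 600 states
and ARPACK above; the reversibilized operator's eigenvectors come from
the symmetrized problem `D^{1/2} P_r D^{-1/2}` (exact for reversible
operators, numerically symmetric by construction), normalized to
`Σ π φ² = 1` with the largest-magnitude entry positive.

The lag `τ*` is chosen as the smallest lag whose slowest implied
timescale is within 10% of the median over larger lags; relative growth
of more than 20% across the grid flags non-Markovianity.  A
marginal-preserving random permutation of the symbols provides the
significance floor for spectral modes.

Decoding places a uniformly drawn member window (K frames) of each
visited microstate at the symbol step (τ frames), cross-fading overlaps
linearly and bridging gaps by interpolation; the two edge windows are
placed unfaded.

## Metastable coarse-graining

The split threshold scan runs over all `N − 1` cuts of the `ϕ₂` order
(ties broken by microstate index, thresholds midway between consecutive
values).  Detailed balance of `P_r` makes the π-weighted cross-flow
symmetric, so the running within-set mass is updated incrementally in
O(nnz) overall.  The metastability score is the minimum of the two set
coherences (both sets must be sticky); a split whose coherences do not
exceed the sets' stationary masses is flagged non-metastable, since
`χ(S) → π(S)` for structureless chains.  Subdivision always targets the
current largest-measure state, conditions the counts on its microstates,
renormalizes, reversibilizes, and splits again; microstates stranded
outside the sub-chain's recurrent component inherit the label of their
most frequent successor.

Dwell times pool both states' complete dwells (the censored first and
last runs are dropped) and are fit by maximum likelihood with a
two-exponential mixture after subtracting half a symbol step (dwells
measured on a lattice overestimate the underlying continuous dwell by
half a step on average; without the correction the fast timescale is
biased up by ~5%).  Standard errors come from the observed information
(numerical Hessian in log-timescale coordinates); component overlap makes
them substantially larger than single-exponential SEs, and bootstrap CIs
are available as an alternative.  Fits are refused below 20 dwells.
Kinetic rates use the standard estimator
`κ_{A→B} = (#A→B transitions)/(total time in A)`.

## Behavior signals and events

`ω` is the negated, unwrapped, centrally differenced `(a1, a2)` phase
over `2π` (cycles/s); frames with the phase undefined at the origin are
interpolated and flagged.  `γ` is the per-frame sum of tangent angles.
Default event thresholds (config-exposed): reversals enter at `ω < 0`
with an exit hysteresis band of 10% of ω's interquartile range; turns
enter at `|γ| > 3 SD(γ)` with a 10% hysteresis on exit; both require a
0.5 s minimum duration — roughly a quarter body-wave period, so that
sub-half-second phase dips (wave jitter, and the snippet-boundary jitter
of decoded simulations at moderate N) are not counted as behavior.  The
3-SD turn threshold clears the noise floor of a turn-free signal while
sitting far below genuine turn excursions.  The sign of γ during a turn
assigns ventral (positive, by convention; configurable) versus dorsal.

## Resistive force theory

Per segment, drag is `F_i = t̂t̂ᵀ v~_i + α n̂n̂ᵀ v~_i` with the
tangential coefficient set to 1 (only the ratio `α = α_n/α_t` enters the
balance; crawling propulsion requires `α > 1`).  Tangents come from the
discrete chain (`t̂_i = (cos θ_i, sin θ_i)`), torque is taken about the
instantaneous centroid, and the zero net force/torque condition is a
3×3 linear solve (batched over frames; least-squares fallback with a
warning for degenerate postures such as a straight body under isotropic
drag).

Two entry points serve two situations.  The forward model
(`posture_to_trajectory`) follows the physical scheme: the inputs are
worm-centric shapes, so the *entire* frame-to-frame coordinate change is
shape change and feeds the force balance whole; the balance `(V, Ω)` is
the propulsion generated by that shape change.  Splitting off a best-fit
rotation first would silently hand physically real rotation to a
kinematic bookkeeping term and suppress turning (a sustained bend with a
running wave turns at ~24°/s through the balance, and at ~0°/s if the
registration eats it).  `rft_solve`, by contrast, is for *measured*
skeleton pairs that may carry genuine lab-frame rigid motion: it
recovers that motion exactly by least-squares rigid registration
(centroid shift plus best-fit rotation) and adds the balance solution of
the registered residual, so a purely rigid displacement is reported as
observed for every α.  Paths integrate `heading += Ω dt`,
`x += R(heading) V dt` by explicit Euler, adequate because `dt` is small
against the body-wave period.

Calibration of α minimizes the mean RMS distance between reconstructed
and measured centroid paths over non-overlapping 60 s windows, each
re-anchored at the measured window start with the initial heading aligned
to the first second of measured motion (windowing keeps unbounded drift
from dominating the objective).  The CI bootstraps over windows.

MSD is the time-averaged mean over all lag pairs; `D` is the
least-squares slope over lags 60–100 s divided by 4.  The log-log
scaling exponent over the fit range flags non-diffusive curves
(|exponent − 1| > 0.3), distinguishing ballistic (exponent 2) from
diffusive (exponent 1) behavior robustly under correlated MSD noise.

## Foraging

Constrained chains renormalize counts within a mesoscopic state's
microstates, dropping (with a warning) states whose every observed
transition leaves the subset.  Food encounter uses `n_food` points
uniform in the disc of radius `r` about the trajectory start, "found"
when the trajectory passes within the sensing radius (default 1 BL) of
any point; `p` averages over trajectories × independent scatters (a
lower-variance version of one scatter per replicate), with a normal CI.
Probability matching normalizes the per-state `p` at the largest radius
and compares with occupancy via Pearson correlation and maximum absolute
discrepancy.  Note that the *synthetic* worm has no mechanism coupling
its occupancies to foraging efficiency, so its matching correlation is
an output, not a design target; the pipeline's correctness is instead
checked against constructed ground truth (designed 2:1:1 efficiencies
with matched occupancy).

## Pipeline and reproducibility

One master seed expands into per-stage seeds through
`numpy.random.SeedSequence.spawn` in fixed stage order (data, embed, msm,
events, coarsen, path, forage), so stages can be rerun in isolation.
Every run writes a manifest with the config hash, stage seeds, file list,
and headline results; reruns with the same config reproduce all results.

### Problem sizes

Tests and the acceptance script run 2–3 synthetic worms of 4,000–16,000
frames with 10–80 microstates, 10⁵-step tracks, and 10⁶-step chain
fixtures — sizes chosen so every statistical recovery criterion has the
power its tolerance requires while the whole suite completes in about a
minute.  The full-scale setting (12 worms × 33,600 frames, 1,000
microstates, 30 spectral modes) is exercised by the same code paths and
is configurable throughout.

## Known limitations

- The synthetic basis fixes γ ∝ a3; real eigenworms mix curvature across
  modes, so absolute γ thresholds do not transfer to real data without
  recalibration.
- Dwell-time mixtures assume two exponentials; processes with more
  timescales need a model-order choice the package does not automate.
- The Markov model is stationary by construction; slow adaptation
  (e.g. declining pirouette rates after removal from food) is outside
  its scope and will appear as implied-timescale growth.
- Metastable splits are hard partitions along ϕ₂; fuzzy or
  multi-dimensional reaction coordinates are not supported.
- RFT is linear and memoryless: no body elasticity, no granular force
  laws, no substrate heterogeneity.
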