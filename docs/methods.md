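# Methods

`hmmar` identifies fast transient network states in multichannel
electrophysiological recordings and describes each state spectrally. This
note documents the model, the numerical choices, the synthetic-data
generator, and the limits of what the test suite demonstrates.

## Model

The recording `y_t ∈ R^N` (samples × channels, sampling rate `fs`) is
modelled as a hidden Markov chain over `K` states. Conditional on state
`k`, the observation model is a multivariate autoregression (MAR) over a
lag set `A`:

    y_t | x_t = k  ~  N( Σ_{l∈A} y_{t−l} W_l^(k),  Σ^(k) ),

so each state carries its own multiregion spectral signature (power,
coherence, directed interactions). The chain is first-order Markov with
transition matrix `Θ` and initial distribution `η`.

Lag sets may be uniform (`{P0+1, …, P}`) or exponentially spaced
(`{P0+1} ∪ {P0+⌊Q^m⌋}` truncated at `P`), concentrating parameters on the
most autocorrelated lags while keeping a few long lags for low
frequencies. Lags are integer sample delays at the analysed sampling rate;
transforms use `exp(−i2πfl/fs)` with `f` in Hz.

### Priors

All priors are conjugate:

- `W_l,ij^(k) ~ N(0, σ_ij^(k)⁻¹ α_l^(k)⁻¹)` — two-level automatic relevance
  determination. The per-connection precisions `σ_ij` prune channel pairs
  (spatial sparsity, optionally symmetric); the per-lag precisions `α_l`
  prune lags jointly for all channels (spectral sparsity).
- noise: per-channel Gamma precisions (diagonal `Σ`, the default) or a
  Wishart precision (full `Σ`, optionally shared across states);
- `Θ` rows and `η`: Dirichlet.

Default hyperparameters are weakly informative: Gamma shapes and rates
`1e−3`, Dirichlet counts 1, Wishart degrees `N+1` with scale
`I · var(data)`. These are standard diffuse conjugate choices; the data
are used on their native scale (z-score before fitting if channels have
wildly different units).

### Variational inference

Exact posteriors are intractable; inference is mean-field variational
Bayes with conjugate coordinate updates:

1. **Observation update** — per state, a responsibility-weighted Bayesian
   regression for the free coefficients (prior precision
   `E[σ_ij]E[α_l]`), then the noise and the two ARD Gamma updates. The α
   update uses the *refreshed* σ expectations: the product `σ·α` is only
   jointly identified, and stale expectations make the pair oscillate,
   destroying the free-energy descent guarantee.
2. **Transition update** — Dirichlet counts from the pairwise transition
   marginals and segment-initial responsibilities.
3. **State update** — forward–backward per segment with expected-log
   parameters (`exp E[log Θ]`, expected emission log-likelihood),
   per-sample normalisation for numerical stability, batched across
   segments of equal length. The first `P` samples of each segment lack a
   full lag window; they receive uniform emission evidence and are
   excluded from the regressions (autoregressions never cross segment
   boundaries).

The variational free energy (negative evidence bound) is the sum of KL
divergences of all posterior factors against their priors minus the log
normaliser of the forward pass; it is non-increasing across cycles up to
round-off and is asserted so in the tests (tolerance `1e−6·|F|`).
Convergence: relative change `< 1e−5` per cycle, cap 100 cycles.

**Initialisation.** Ridge-regularised MAR fits in non-overlapping windows
of `P` samples, k-means on the coefficient vectors, responsibilities
seeded at 0.9 for the winning cluster. A window of one maximum-lag span
(≈ one typical state lifetime in the simulation scenario) seeds a markedly
better basin than longer windows, which mix states. Restarts vary the
k-means seed; with several restarts each is probed for a short cycle
budget (default 20) and only the lowest-free-energy basin is run to
convergence — basins in this model separate by hundreds of free-energy
units within the first cycles, so the probe reliably identifies the
winner at a fraction of the cost of converging every restart.

**State count.** `select_num_states` refits per candidate `K` with shared
seeds and ranks converged free energies. The fits must run to
convergence: larger `K` converges more slowly, and comparing partially
converged free energies systematically favours small `K`.

**State "dropping".** States are never deleted; occupancy below `1e−3` of
the series is reported. With weakly informative priors the inference may
also express parsimony by converging duplicate states onto the same
dynamics rather than emptying one — the free energy still ranks the
smaller `K` first, which is the reliable parsimony signal.

**Variants.** `make_variant` produces the restricted observation models:
`ar-only` clamps cross-channel coefficients to zero (transitions driven by
power spectra), `cross-only` pins self-coefficients at their global
maximum-likelihood values (transitions driven by cross-channel coupling),
`gaussian-envelope` drops all lags and models Hilbert amplitude envelopes
with state-specific Gaussians (implemented as a MAR with an empty lag set
plus an intercept regressor).

## State-specific spectra

The statewise multitaper weights each sample by the power-preserving
weights `ρ_t^(k) = γ_tk √(T / Σ_t γ_tk²)` (so `Σ ρ² = T` exactly), then
applies Slepian tapers (default NW = 4, R = 7) and averages cross-spectral
outer products over tapers and windows, window-weighted by mean state
mass. Windows default to 2 s, non-overlapping; with uniform unit
responsibilities the estimator reduces bit-for-bit to the standard
multitaper. Coherence follows directly from the cross-spectral matrix.

The displayed mean-one weight normalisation seen in some descriptions of
this estimator does not satisfy the power-preservation constraint
`Σρ² = T`; the constraint is taken as authoritative here.

**PDC.** Partial directed coherence uses the original column-normalised
form `PDC_ij = |Ā_ij| / √(Σ_m |Ā_mj|²)` with
`Ā(f) = I − Σ_l W_l^T e^{−i2πfl/fs}`. Non-parametrically, `Ā = H⁻¹` where
`H` comes from Wilson's spectral-matrix factorisation `S = H Z H*`
(minimum phase, zeroth impulse-response coefficient = identity). The
factorisation self-checks its reconstruction residual on every call
(default contract `1e−6`; a relaxed `1e−2` on noisy multitaper spectra).
On MAR-derived spectra it converges in well under 100 iterations to
residuals around `1e−9` and recovers the parametric PDC to ~`1e−12`.
Building the two-sided spectrum requires `S(−f) = S(f)*` — the elementwise
conjugate, *not* the Hermitian adjoint, which is a no-op on Hermitian
matrices and silently corrupts every directional (phase) quantity while
leaving power untouched.

**Caveat.** Because weighting is multiplication in time, the spectrum of
the state time courses convolves into the statewise spectra.
`gamma_spectrum_diagnostic` reports each state course's spectrum and the
fraction of its power inside the analysis band, warning above 0.2 and
pointing to the parametric spectra (`parametric_spectra` on the fitted
coefficients) as the alternative.

## Sign disambiguation

Source-reconstructed MEG dipole time courses have arbitrary polarity per
channel and session. Under the assumption that pairwise *partial*
correlations (from shrinkage-regularised precision matrices) keep their
sign across trials, the correct assignment maximises
`Σ_{i<j} |Σ_trials s_i s_j r_ij|`. The exact problem is NP-hard; the
implementation uses greedy single-flip coordinate ascent with random
restarts (deterministic per seed, lowest-index tie-break, objective
monotone along the path) and matches exhaustive search on all instances
with `N · trials ≤ 16` in the tests. The flipping unit is the trial;
sessions can be handled by passing one block per session.

## Synthetic-data generator

The simulator emulates a two-channel, three-state scenario with known
ground truth; its defaults are the study conditions for every recovery
test:

- per-state 1/f^α coloured noise via the truncated binomial-expansion
  recursion (`a_k = (k−1−α/2)a_{k−1}/k`), α = 0.9, 0.7, 0.5, order 35;
- oscillations at 6, 12, 18 Hz embedded by *moving* the nearest-angle
  root pair of the characteristic polynomial onto `0.97·e^{±i2πf/fs}`.
  Root replacement (rather than multiplying in an extra pole pair) keeps
  the model order and the low-frequency gain of the coloured-noise
  process unchanged, so the resonance appears as a local maximum on the
  1/f background instead of re-tilting it; appending a 6 Hz pole pair
  amplifies DC ≈27-fold and, at radii ≥ 0.97, makes the generated series
  numerically explode. Radius 0.97 is the smallest at which all three
  resonances dominate their local background in the statewise multitaper
  computed with the *true* state courses (checked across 10 seeds);
- directional coupling by multiplying the per-lag diagonal coefficient
  matrices with mixing matrices: identity (state 1), 0.5 below the
  diagonal (state 2), 0.5 above (state 3) — opposite directions. Every
  generated MAR is checked for companion spectral radius < 1;
- state lifetimes Gamma(shape 1.48, rate 0.03 per sample at 200 Hz; mean
  ≈ 49 samples ≈ 0.25 s), alternating visits with no immediate
  self-repeat (otherwise merged visits would not be Gamma);
- a within-trial schedule: states equiprobable except 1.5–2.0 s (state 2
  at 0.8) and 2.0–2.5 s (state 3 at 0.8), mimicking an event at 2.0 s;
  100 trials × 4 s × 200 Hz (80 000 samples) at full scale;
- unit-variance white Gaussian innovations; a 4·P-sample burn-in per
  trial is discarded.

What the generator does *not* emulate: volume conduction / spatial
leakage, measurement noise on top of the process noise, non-Gaussian
artefacts, inter-subject variability, or sign flips (the sign-flip module
is tested on its own planted-solution data). Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to real MEG confounds.

## Task statistics

Fractional occupancy epochs the state time courses around events (soft
responsibilities; occupancies sum to one at every peri-event time).
Lifetimes use the argmax hard path by default (Viterbi available).
Regularised time–frequency maps are the occupancy-weighted sum of state
spectra, `TF(t, f) = Σ_k measure_f^(k) γ_tk`, epoched and baseline
corrected by the per-frequency mean over a pre-event window.

Cluster-extent permutation tests form clusters at `|t| > 3`
(4-connectivity in 2-D), score them by extent, and compare against the
null distribution of the maximal extent under random sign flips of the
observation-level maps; each tail is tested separately at α = 0.05
(defaults as in the motor-task analyses this workflow supports). The
"cluster threshold 3" is read as a t-statistic threshold; it is
configurable. Calibration is verified per tail: under a simulated global
null the false-positive rate stays within the binomial slack of the
nominal level over 500 repetitions. The permutation unit (trials or
subjects) is whatever the caller passes as observations.

## Problem sizes used in the validation suite

The recovery and model-selection checks run the scenario at 40 trials
(32 000 samples) — the same generator at reduced length, chosen so the
whole validated workflow (four candidate state counts plus the recovery
fits) completes in minutes while leaving the qualitative results
unchanged; the scale checks run the full 100 trials. The acceptance
script (`scripts/acceptance.py`) fits K = 2…5 with three restarts each at
40 trials.

## Known limitations

- Full-covariance noise couples all channels' coefficients in one joint
  Gaussian; fine at few channels, costly at many.
- The Gaussian-envelope variant models envelope means/variances only; no
  envelope orthogonalisation or leakage correction is provided.
- Free energies are comparable across `K` only at matching convergence
  tolerance and identical data (including segment structure).
- The statewise multitaper inherits a resolution floor from the windowing
  and from the state-course convolution noted above; very low frequencies
  need long windows and high state occupancy to be reliable.
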