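# hmmar

Fast transient brain states in multichannel electrophysiological time
series, inferred with a hidden Markov model whose observation models are
multivariate autoregressive (MAR) processes — together with state-resolved
spectral estimation, MEG sign-ambiguity correction, a validated
synthetic-data generator, and task-locked statistics.

## Who this is for

Electrophysiologists (MEG/EEG/LFP) who want to describe how multiregion
oscillatory activity reorganises at sub-second time scales *without*
sliding windows and *without* knowing task timings. The model segments a
recording into recurring states, pooling over every (possibly ~100 ms)
visit to a state, and then describes each state by its power spectra,
coherence and partial directed coherence (PDC).

## The model

For channels `y_t ∈ R^N` and hidden states `x_t ∈ {1..K}`:

    y_t | x_t = k ~ N( Σ_{l ∈ A} y_{t−l} W_l^(k), Σ^(k) ),
    P(x_t = k₁ | x_{t−1} = k₂) = Θ_{k₂k₁},  P(x_1 = k) = η_k,

with a lag set `A` (uniform or exponentially spaced with offset `P0` and
lapse `Q`), two-level ARD priors on the coefficients
(`W_l,ij^(k) ~ N(0, σ_ij⁻¹ α_l⁻¹)` — per-connection and per-lag Gamma
precisions), Gamma/Wishart noise and Dirichlet chain priors. Inference is
conjugate variational Bayes; the variational free energy monitors
convergence and ranks candidate `K` (lower is better).

State spectra come from a *statewise multitaper*: samples weighted by the
power-preserving responsibilities `ρ_t = γ_t √(T/Σγ²)` before Slepian
tapering (NW = 4, R = 7 default), giving cross-spectra, coherence, and —
via Wilson's minimum-phase spectral factorisation — non-parametric PDC.
`docs/methods.md` has the full account.

## Worked example

Generate the bundled three-state scenario (two channels; 1/f^α states
with oscillations at 6, 12, 18 Hz and opposite cross-channel coupling;
Gamma-distributed ~0.25 s state lifetimes), fit with no knowledge of the
event timings, and describe the recovered states:

```python
from hmmar import (paper2016_preset, simulate, fit, HMMMARConfig,
                   TrainingConfig, build_lag_set, statewise_multitaper,
                   TaperConfig, state_lifetimes)

truth = simulate(paper2016_preset(n_trials=40, seed=11))
cfg = HMMMARConfig(K=3, lagset=build_lag_set(35, 0, "uniform"),
                   training=TrainingConfig(seed=0))
result = fit(truth.data, cfg)
print(f"free energy: {result.free_energy:.1f} "
      f"({len(result.free_energy_trace)} cycles, converged={result.converged})")

spectra = statewise_multitaper(truth.data, result.stc,
                               TaperConfig(NW=4, R=7, window_length=800),
                               freq_range=(1, 48))
lt = state_lifetimes(result.stc, segments=truth.data.segments, fs=truth.data.fs)
for k in range(3):
    print(f"state {k}: peak {spectra.peak_frequency(k):5.2f} Hz, "
          f"occupancy {lt['percent_occupancy'][k]:4.1f} %, "
          f"mean lifetime {1e3 * lt['mean_lifetime_s'][k]:5.1f} ms")
```

Output:

```
free energy: 89890.4 (61 cycles, converged=True)
state 0: peak 12.25 Hz, occupancy 36.5 %, mean lifetime 283.2 ms
state 1: peak 17.75 Hz, occupancy 33.7 %, mean lifetime 268.3 ms
state 2: peak  5.50 Hz, occupancy 29.8 %, mean lifetime 260.8 ms
```

The three recovered states peak within a fraction of a hertz of the
generating 12, 18 and 6 Hz oscillations (state labels are arbitrary), the
occupancies are near the generating thirds, and the ~270 ms mean
lifetimes reflect the Gamma(1.48, 0.03/sample) visit durations — even
though each 6 Hz visit spans only about 1.5 oscillation cycles.

## Command line

```sh
hmmar simulate --preset paper2016 --trials 100 --seed 1 --out sim/
hmmar signflip --data sim/data.txt --restarts 20 --seed 7 --out flipped/
hmmar fit      --data sim/data.txt --k 3 --order 35 --restarts 3 --seed 0 --out fit.h5
hmmar spectra  --fit fit.h5 --data sim/data.txt --nw 4 --tapers 7 --fmin 1 --fmax 48 --out spec.h5
hmmar tf       --fit fit.h5 --spectra spec.h5 --data sim/data.txt --window -2:2 --out tf.h5
hmmar test     --maps tf.h5 --mode 2d --threshold 3 --alpha 0.05 --nperm 5000 --seed 3 --out mask.txt
hmmar select-k --data sim/data.txt --k-min 2 --k-max 5 --seed 0
hmmar pipeline --config run.yaml
```

Time series travel as delimited text (`# fs <Hz>` header; companion
`.segments`/`.events` files with 0-based half-open indices) or a small
documented binary format; fits and spectra as HDF5 containers.

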