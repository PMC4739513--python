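"""Synthetic multichannel data with known transient-state structure.

The generator produces data from ``K`` alternating multivariate
autoregressive (MAR) processes.  Each state's within-channel dynamics are a
truncated 1/f^alpha ("coloured noise") autoregression with an oscillatory
pole pair embedded at a state-specific frequency; cross-channel directional
interactions are introduced by multiplying the per-lag coefficient matrices
by a mixing matrix.  State visits alternate with Gamma-distributed lifetimes,
and the state-selection probabilities follow a time-varying schedule within
each trial, emulating an event-locked modulation of state occupancy.

Every generated model is checked for stationarity (companion spectral radius
below one), and the full ground truth — generating coefficients, state path
and event times — is returned for downstream recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import TimeSeriesData
from .model import (
    InvalidConfigurationError,
    LagSet,
    NonStationaryModelError,
    companion_spectral_radius,
)


# ---------------------------------------------------------------------------
# Per-state MAR construction


def onef_ar_coefficients(alpha: float, P_gen: int) -> np.ndarray:
    """AR coefficients of a truncated 1/f^alpha process.

    Uses the recursion ``a_0 = 1, a_k = (k - 1 - alpha/2) a_{k-1} / k`` for
    the expansion of ``(1 - z^{-1})^{alpha/2}``, truncated at ``P_gen`` lags.
    Returned in regression convention: ``x_t = sum_k b_k x_{t-k} + e_t`` with
    ``b_k = -a_k``.  The resulting process has log-log PSD slope close to
    ``-alpha`` over the mid band.
    """
    if not (0 <= alpha < 2):
        raise InvalidConfigurationError("alpha must lie in [0, 2)")
    if P_gen < 1:
        raise InvalidConfigurationError("P_gen must be >= 1")
    a = np.empty(P_gen + 1)
    a[0] = 1.0
    for k in range(1, P_gen + 1):
        a[k] = (k - 1 - alpha / 2.0) * a[k - 1] / k
    return -a[1:]


def _ar_poly(b: np.ndarray) -> np.ndarray:
    """Characteristic polynomial coefficients [1, -b_1, ..., -b_P]."""
    return np.concatenate(([1.0], -np.asarray(b, float)))


def embed_oscillation(
    ar_coeffs: np.ndarray, freq_hz: float, fs: float, radius: float = 0.97
) -> np.ndarray:
    """Embed an oscillatory resonance in a univariate AR model.

    The characteristic-polynomial roots are adjusted so that a conjugate
    pair sits at modulus ``radius`` and angles ``±2 pi freq_hz / fs``: the
    existing complex pair closest in angle (or, failing that, the two roots
    of smallest angle) is moved onto the target pair.  Replacing rather than
    appending roots keeps the model order and, crucially, the low-frequency
    gain of the underlying coloured-noise process unchanged, so the
    resonance appears as a local PSD maximum at ``freq_hz`` on top of the
    1/f background rather than re-tilting it.  Stationarity is asserted on
    the result.

    With ``radius = 0`` the pair moves to the origin, leaving the remaining
    coefficients approximately equal to the input's.
    """
    if not (0 < freq_hz < fs / 2):
        raise InvalidConfigurationError("freq_hz must lie in (0, fs/2)")
    if not (0 <= radius < 1):
        raise InvalidConfigurationError("radius must lie in [0, 1)")
    theta = 2 * np.pi * freq_hz / fs
    roots = np.roots(_ar_poly(ar_coeffs))
    ang = np.angle(roots)
    pos = np.flatnonzero(ang > 1e-9)
    if len(pos):
        i = pos[np.argmin(np.abs(ang[pos] - theta))]
        conj_dist = np.abs(roots - np.conj(roots[i]))
        conj_dist[i] = np.inf
        j = int(np.argmin(conj_dist))
        keep = np.delete(roots, [i, j])
    else:  # all-real roots: sacrifice the two smallest-magnitude ones
        idx = np.argsort(np.abs(roots))[:2]
        keep = np.delete(roots, idx)
    new_roots = np.append(
        keep, [radius * np.exp(1j * theta), radius * np.exp(-1j * theta)]
    )
    poly = np.real(np.poly(new_roots))
    if np.any(np.abs(new_roots) >= 1):
        raise NonStationaryModelError(
            f"oscillation at {freq_hz} Hz destabilises the AR polynomial "
            f"(max root modulus {np.max(np.abs(new_roots)):.4f})"
        )
    return -poly[1:]


def build_state_mar(diag_coeffs: np.ndarray, mixing: np.ndarray) -> np.ndarray:
    """Assemble a state's MAR coefficients from per-channel ARs and mixing.

    ``diag_coeffs`` is ``(P, N)`` (per-lag, per-channel self coefficients);
    each per-lag diagonal matrix is multiplied by the ``N x N`` mixing matrix
    ``A`` to introduce cross-channel (directional) interactions.  With
    ``A = I`` all cross terms are zero.  Returns stacked coefficients of
    shape ``(P*N, N)``; raises if the companion spectral radius is >= 1.
    """
    diag_coeffs = np.atleast_2d(np.asarray(diag_coeffs, float))
    mixing = np.asarray(mixing, float)
    if not np.all(np.isfinite(mixing)):
        raise InvalidConfigurationError("mixing matrix must be finite")
    P, N = diag_coeffs.shape
    if mixing.shape != (N, N):
        raise InvalidConfigurationError(
            f"mixing must be ({N}, {N}), got {mixing.shape}"
        )
    W = np.concatenate([np.diag(diag_coeffs[l]) @ mixing for l in range(P)])
    lagset = LagSet(lags=tuple(range(1, P + 1)), P=P, P0=0, Q="uniform")
    rho = companion_spectral_radius(W, lagset, N)
    if rho >= 1:
        raise NonStationaryModelError(
            f"generated MAR is non-stationary (spectral radius {rho:.4f})"
        )
    return W


# ---------------------------------------------------------------------------
# Configuration


def _default_mixing() -> list[np.ndarray]:
    return [
        np.eye(2),
        np.array([[1.0, 0.0], [0.5, 1.0]]),
        np.array([[1.0, 0.5], [0.0, 1.0]]),
    ]


def _default_schedule() -> list[tuple[float, float, tuple[float, ...]]]:
    third = 1.0 / 3.0
    return [
        (0.0, 1.5, (third, third, third)),
        (1.5, 2.0, (0.1, 0.8, 0.1)),
        (2.0, 2.5, (0.1, 0.1, 0.8)),
        (2.5, 4.0, (third, third, third)),
    ]


@dataclass
class SimConfig:
    """Configuration of the transient-state generator.

    Defaults reproduce the validated two-channel, three-state scenario:
    states coloured as 1/f^{0.9, 0.7, 0.5} with oscillations at 6, 12 and
    18 Hz, identity mixing for state one and opposite off-diagonal coupling
    (0.5) for states two and three, Gamma(1.48, rate 0.03) state lifetimes in
    samples (mean about 49 samples = 0.25 s at 200 Hz), 100 trials of 4 s at
    200 Hz, and a state-probability schedule that favours state two in
    1.5-2.0 s and state three in 2.0-2.5 s of each trial, mimicking an event
    at 2.0 s.
    """

    N: int = 2
    K: int = 3
    P_gen: int = 35  # generating MAR order (uniform lags 1..P_gen)
    alpha_exponents: tuple[float, ...] = (0.9, 0.7, 0.5)
    osc_freqs: tuple[float, ...] = (6.0, 12.0, 18.0)
    osc_radius: float = 0.97
    mixing: list[np.ndarray] = field(default_factory=_default_mixing)
    fs: float = 200.0
    n_trials: int = 100
    trial_seconds: float = 4.0
    lifetime_shape: float = 1.48
    lifetime_rate: float = 0.03  # per sample; mean lifetime = shape/rate samples
    event_window_probs: list[tuple[float, float, tuple[float, ...]]] = field(
        default_factory=_default_schedule
    )
    event_time_s: float = 2.0
    noise_std: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (
            len(self.alpha_exponents)
            == len(self.osc_freqs)
            == len(self.mixing)
            == self.K
        ):
            raise InvalidConfigurationError(
                "alpha_exponents, osc_freqs and mixing must have K entries"
            )
        cursor = 0.0
        for t0, t1, probs in self.event_window_probs:
            if abs(t0 - cursor) > 1e-9 or t1 <= t0:
                raise InvalidConfigurationError("schedule windows must tile the trial")
            if len(probs) != self.K or abs(sum(probs) - 1.0) > 1e-9:
                raise InvalidConfigurationError(
                    "schedule probabilities must sum to 1 over K states"
                )
            cursor = t1
        if abs(cursor - self.trial_seconds) > 1e-9:
            raise InvalidConfigurationError("schedule must cover the whole trial")

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))

    @property
    def order(self) -> int:
        """Order of the generating MAR."""
        return self.P_gen

    def lagset(self) -> LagSet:
        P = self.order
        return LagSet(lags=tuple(range(1, P + 1)), P=P, P0=0, Q="uniform")

    def schedule_probs(self, t_seconds: float) -> np.ndarray:
        for t0, t1, probs in self.event_window_probs:
            if t0 <= t_seconds < t1:
                return np.asarray(probs, float)
        return np.asarray(self.event_window_probs[-1][2], float)


def paper2016_preset(**overrides) -> SimConfig:
    """The validated simulation scenario (two channels, three states)."""
    cfg = SimConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated data set."""

    W_true: list[np.ndarray]  # per-state stacked (P*N, N) coefficients
    Sigma_true: list[np.ndarray]
    lagset: LagSet
    state_path: np.ndarray  # (T,) integer labels
    event_samples: np.ndarray  # absolute sample index of each trial's event
    data: TimeSeriesData
    config: SimConfig

    def gamma_true(self) -> np.ndarray:
        """One-hot (T, K) responsibility matrix of the generating path."""
        return np.eye(self.config.K)[self.state_path]


# ---------------------------------------------------------------------------
# Sampling


def state_generators(cfg: SimConfig) -> list[np.ndarray]:
    """Per-state stacked MAR coefficient matrices implied by the config."""
    W_states = []
    for k in range(cfg.K):
        base = onef_ar_coefficients(cfg.alpha_exponents[k], cfg.P_gen)
        with_osc = embed_oscillation(
            base, cfg.osc_freqs[k], cfg.fs, cfg.osc_radius
        )
        diag = np.tile(with_osc[:, None], (1, cfg.N))  # same AR per channel
        W_states.append(build_state_mar(diag, cfg.mixing[k]))
    return W_states


def sample_state_path(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample one trial's state path as alternating Gamma-lifetime visits.

    The state of each visit is drawn from the schedule probability at the
    visit's start time, excluding an immediate self-repeat (otherwise merged
    visits would no longer have Gamma lifetimes).
    """
    T = cfg.trial_samples
    path = np.empty(T, dtype=int)
    t = 0
    prev = -1
    while t < T:
        probs = cfg.schedule_probs(t / cfg.fs).copy()
        if prev >= 0 and cfg.K > 1:
            probs[prev] = 0.0
            probs = probs / probs.sum()
        state = int(rng.choice(cfg.K, p=probs))
        lifetime = max(1, int(round(rng.gamma(cfg.lifetime_shape, 1.0 / cfg.lifetime_rate))))
        path[t : t + lifetime] = state
        t += lifetime
        prev = state
    return path


def _generate_trial(
    W_states: list[np.ndarray],
    path: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    P = cfg.order
    N = cfg.N
    T = path.size
    burn = 4 * P
    y = np.zeros((P + burn + T, N))  # P leading zeros as initial history
    e = rng.normal(scale=cfg.noise_std, size=(burn + T, N))
    ext_path = np.concatenate([np.full(burn, path[0]), path])
    for t in range(burn + T):
        # history row vector ordered lag 1 .. P to match the stacked blocks
        hist = y[t : t + P][::-1].reshape(-1)
        y[t + P] = e[t] + hist @ W_states[ext_path[t]]
    return y[P + burn :]


def simulate(cfg: Optional[SimConfig] = None, seed: Optional[int] = None) -> SimulationTruth:
    """Generate a full multi-trial data set with ground truth.

    Fully reproducible from ``cfg.seed`` (or the ``seed`` override).  Each
    trial is an independent segment with its own burn-in (discarded), state
    path, and a single event marker at ``event_time_s``.
    """
    cfg = cfg or paper2016_preset()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    W_states = state_generators(cfg)
    Sigma = [np.eye(cfg.N) * cfg.noise_std**2 for _ in range(cfg.K)]
    T_trial = cfg.trial_samples
    event_offset = int(round(cfg.event_time_s * cfg.fs))
    values = np.empty((cfg.n_trials * T_trial, cfg.N))
    state_path = np.empty(cfg.n_trials * T_trial, dtype=int)
    segments, events, event_samples = [], [], []
    for trial in range(cfg.n_trials):
        a = trial * T_trial
        path = sample_state_path(cfg, rng)
        values[a : a + T_trial] = _generate_trial(W_states, path, cfg, rng)
        state_path[a : a + T_trial] = path
        segments.append((a, a + T_trial))
        events.append((trial, a + event_offset))
        event_samples.append(a + event_offset)
    data = TimeSeriesData(values=values, fs=cfg.fs, segments=segments, events=events)
    return SimulationTruth(
        W_true=W_states,
        Sigma_true=Sigma,
        lagset=cfg.lagset(),
        state_path=state_path,
        event_samples=np.asarray(event_samples),
        data=data,
        config=cfg,
    )
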