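"""Multivariate autoregressive (MAR) observation model.

A MAR model with lag set ``A`` writes each sample as a linear combination of
lagged samples across all channels,

    y_t = sum_{l in A}  y_{t-l} W_l  +  e_t ,      e_t ~ N(0, Sigma),

with ``y_t`` a row vector of ``N`` channels and ``W_l`` an ``N x N``
coefficient matrix whose entry ``(i, j)`` couples channel ``i`` at lag ``l``
to channel ``j`` now.  The lag set need not be contiguous: an exponential
spacing concentrates statistical power on the most autocorrelated (short)
lags while retaining a few long lags for the low frequencies.

This module provides the lag-set parametrisation, connection clamping plans,
maximum-likelihood (least squares) global MAR fits, and the parametric
spectra (PSD, coherence, partial directed coherence) implied by a set of MAR
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import scipy.linalg

from .datatypes import TimeSeriesData


class InvalidConfigurationError(ValueError):
    pass


class SingularFitError(np.linalg.LinAlgError):
    pass


class NonStationaryModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Lag sets


@dataclass(frozen=True)
class LagSet:
    """Set of positive integer lags used by the autoregression.

    ``lags`` is strictly increasing; ``P`` is the declared maximum lag
    (order), ``P0`` the offset below which no lags are used, and ``Q`` the
    exponential lapse (or the string ``"uniform"``).
    """

    lags: tuple[int, ...]
    P: int
    P0: int
    Q: float | str

    def __post_init__(self) -> None:
        lags = self.lags
        if len(lags) == 0:
            return  # empty lag set: pure Gaussian observation model
        if any(l2 <= l1 for l1, l2 in zip(lags, lags[1:])):
            raise InvalidConfigurationError("lags must be strictly increasing")
        if lags[0] < self.P0 + 1 or lags[-1] > self.P:
            raise InvalidConfigurationError(
                f"lags must lie in [{self.P0 + 1}, {self.P}]"
            )

    def __len__(self) -> int:
        return len(self.lags)

    @property
    def max_lag(self) -> int:
        return self.lags[-1] if self.lags else 0

    @property
    def n_regressors_per_channel(self) -> int:
        return len(self.lags)


def build_lag_set(P: int, P0: int = 0, Q: float | str = "uniform") -> LagSet:
    """Construct the lag set ``A`` for maximum lag ``P``, offset ``P0``.

    With ``Q="uniform"`` the set is ``{P0+1, ..., P}``.  With a numeric lapse
    ``Q >= 1`` the set is ``{P0+1} ∪ {P0 + floor(Q^m) : m = 1, 2, ...}``
    truncated at ``P``, duplicates removed.
    """
    if P <= P0:
        raise InvalidConfigurationError(f"need P > P0, got P={P}, P0={P0}")
    if P0 < 0:
        raise InvalidConfigurationError("P0 must be non-negative")
    if Q == "uniform":
        lags = tuple(range(P0 + 1, P + 1))
        return LagSet(lags=lags, P=P, P0=P0, Q="uniform")
    Q = float(Q)
    if Q < 1:
        raise InvalidConfigurationError("exponential lapse Q must be >= 1")
    lags = {P0 + 1}
    if Q == 1.0:
        return LagSet(lags=(P0 + 1,), P=P, P0=P0, Q=Q)
    m = 1
    while True:
        lag = P0 + math.floor(Q**m)
        if lag > P:
            break
        lags.add(lag)
        m += 1
    return LagSet(lags=tuple(sorted(lags)), P=P, P0=P0, Q=Q)


# ---------------------------------------------------------------------------
# Clamping


@dataclass
class ClampingPlan:
    """Which MAR connections are free to vary across states.

    ``state[i, j]`` is one of ``"free"``, ``"zero"`` (fixed to zero) or
    ``"global"`` (fixed to the maximum-likelihood stationary value held in
    ``global_coeffs``).  Clamped connections do not drive state transitions.
    """

    mode: Literal["free", "diagonal-only", "cross-only"] = "free"
    state: Optional[np.ndarray] = None  # N x N array of strings
    global_coeffs: Optional[np.ndarray] = None  # (n_lags*N) x N

    @classmethod
    def free(cls, n_channels: int) -> "ClampingPlan":
        state = np.full((n_channels, n_channels), "free", dtype=object)
        return cls(mode="free", state=state)

    @classmethod
    def diagonal_only(cls, n_channels: int) -> "ClampingPlan":
        """Only self-connections vary: cross-channel terms fixed to zero."""
        state = np.full((n_channels, n_channels), "zero", dtype=object)
        np.fill_diagonal(state, "free")
        return cls(mode="diagonal-only", state=state)

    @classmethod
    def cross_only(cls, n_channels: int, global_coeffs: np.ndarray) -> "ClampingPlan":
        """Self-connections pinned at their global ML values; cross terms free."""
        if not np.all(np.isfinite(global_coeffs)):
            raise InvalidConfigurationError("global_coeffs must be finite")
        state = np.full((n_channels, n_channels), "free", dtype=object)
        np.fill_diagonal(state, "global")
        return cls(mode="cross-only", state=state, global_coeffs=np.asarray(global_coeffs, float))

    def validate(self, n_channels: int, n_lags: int) -> None:
        if self.state is None:
            self.state = np.full((n_channels, n_channels), "free", dtype=object)
        if self.state.shape != (n_channels, n_channels):
            raise InvalidConfigurationError("clamping plan shape mismatch")
        if np.any(self.state == "global"):
            if self.global_coeffs is None or self.global_coeffs.shape != (
                n_lags * n_channels,
                n_channels,
            ):
                raise InvalidConfigurationError(
                    "fixed-global connections require global_coeffs of shape "
                    f"({n_lags * n_channels}, {n_channels})"
                )
            if not np.all(np.isfinite(self.global_coeffs)):
                raise InvalidConfigurationError("global_coeffs must be finite")

    def free_mask(self, n_channels: int, n_lags: int) -> np.ndarray:
        """Boolean (n_lags*N, N) mask of coefficients that are free."""
        self.validate(n_channels, n_lags)
        per_lag = self.state == "free"
        return np.tile(per_lag, (n_lags, 1))

    def fixed_values(self, n_channels: int, n_lags: int) -> np.ndarray:
        """(n_lags*N, N) matrix of fixed coefficient values (zero where free)."""
        self.validate(n_channels, n_lags)
        fixed = np.zeros((n_lags * n_channels, n_channels))
        if np.any(self.state == "global"):
            mask = np.tile(self.state == "global", (n_lags, 1))
            fixed[mask] = self.global_coeffs[mask]
        return fixed


# ---------------------------------------------------------------------------
# Design matrices


def build_design(
    data: TimeSeriesData, lagset: LagSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lagged design matrix for a MAR regression.

    Returns ``(X, Y, target_idx)`` where ``X`` stacks, for every valid target
    sample, the lagged rows ``[y_{t-l1}, ..., y_{t-lL}]`` (shape
    ``(n_targets, L*N)``), ``Y`` the targets and ``target_idx`` their
    absolute sample indices.  The first ``P`` samples of every segment serve
    only as regressors — lagged windows never cross a segment boundary.
    """
    y = data.values
    L = len(lagset)
    N = data.n_channels
    P = lagset.P if L else 0
    X_parts, Y_parts, idx_parts = [], [], []
    for a, b in data.segments:
        if b - a <= P:
            continue
        t = np.arange(a + P, b)
        if L:
            X_seg = np.empty((t.size, L * N))
            for j, lag in enumerate(lagset.lags):
                X_seg[:, j * N : (j + 1) * N] = y[t - lag]
        else:
            X_seg = np.empty((t.size, 0))
        X_parts.append(X_seg)
        Y_parts.append(y[t])
        idx_parts.append(t)
    if not X_parts:
        raise SingularFitError("no segment long enough to form MAR targets")
    return (
        np.concatenate(X_parts),
        np.concatenate(Y_parts),
        np.concatenate(idx_parts),
    )


def fit_global_mar(
    data: TimeSeriesData, lagset: LagSet
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood (least squares) stationary MAR fit over all data.

    Returns ``(W, Sigma)`` with ``W`` of shape ``(L*N, N)`` in the stacked
    lag-block convention and ``Sigma`` the residual covariance.  Used to
    populate :class:`ClampingPlan` global values.
    """
    X, Y, _ = build_design(data, lagset)
    n, p = X.shape
    if n <= p:
        raise SingularFitError(
            f"insufficient samples for least squares: {n} targets, {p} regressors"
        )
    W, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < p:
        raise SingularFitError("rank-deficient MAR design matrix")
    resid = Y - X @ W
    Sigma = resid.T @ resid / max(n - p, 1)
    return W, Sigma


# ---------------------------------------------------------------------------
# Stationarity and parametric spectra


def stack_to_lag_matrices(W: np.ndarray, lagset: LagSet, n_channels: int) -> np.ndarray:
    """Reshape stacked coefficients ``(L*N, N)`` to per-lag ``(L, N, N)``."""
    L = len(lagset)
    return W.reshape(L, n_channels, n_channels)


def companion_spectral_radius(W: np.ndarray, lagset: LagSet, n_channels: int) -> float:
    """Spectral radius of the MAR companion matrix (< 1 means stationary)."""
    if len(lagset) == 0:
        return 0.0
    N = n_channels
    P = lagset.max_lag
    W_lags = stack_to_lag_matrices(W, lagset, N)
    # companion acts on stacked column-vector history; blocks use W_l^T
    comp = np.zeros((N * P, N * P))
    for j, lag in enumerate(lagset.lags):
        comp[:N, (lag - 1) * N : lag * N] = W_lags[j].T
    if P > 1:
        comp[N:, :-N] = np.eye(N * (P - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def mar_transfer(
    W: np.ndarray, lagset: LagSet, n_channels: int, freqs: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency response of a MAR model.

    Returns ``(Abar, H)`` with ``Abar(f) = I - sum_l W_l^T e^{-i 2 pi f l / fs}``
    (column convention) and ``H(f) = Abar(f)^{-1}``, each of shape
    ``(F, N, N)``.
    """
    N = n_channels
    freqs = np.asarray(freqs, float)
    W_lags = stack_to_lag_matrices(W, lagset, N)
    phases = np.exp(
        -2j * np.pi * np.outer(freqs, np.array(lagset.lags)) / fs
    )  # (F, L)
    A_col = W_lags.transpose(0, 2, 1)  # A_l = W_l^T
    Abar = np.eye(N)[None] - np.einsum("fl,lij->fij", phases, A_col)
    H = np.linalg.inv(Abar)
    return Abar, H


def parametric_spectra(
    W_states: list[np.ndarray],
    Sigma_states: list[np.ndarray],
    lagset: LagSet,
    freqs: np.ndarray,
    fs: float,
):
    """Per-state PSD, coherence and PDC implied by MAR coefficients.

    For each state the cross-spectral matrix is ``S(f) = H(f) Sigma H(f)^*``
    with transfer function ``H(f) = (I - sum_l W_l^T e^{-i2 pi f l/fs})^{-1}``;
    partial directed coherence follows Baccala & Sameshima's original
    column-normalised form, ``PDC_ij(f) = |Abar_ij(f)| / sqrt(sum_m
    |Abar_mj(f)|^2)``.

    Returns a :class:`~hmmar.spectral.SpectralEstimate`.
    """
    from .spectral import SpectralEstimate, coherence_from_csd

    freqs = np.asarray(freqs, float)
    if np.any(freqs < 0) or np.any(freqs > fs / 2):
        raise InvalidConfigurationError("freqs must lie in [0, fs/2]")
    K = len(W_states)
    N = Sigma_states[0].shape[0]
    F = freqs.size
    csd = np.empty((K, F, N, N), dtype=complex)
    pdc = np.empty((K, F, N, N))
    for k in range(K):
        W = np.asarray(W_states[k], float)
        Sigma = np.asarray(Sigma_states[k], float)
        rho = companion_spectral_radius(W, lagset, N)
        if rho >= 1:
            raise NonStationaryModelError(
                f"state {k}: companion spectral radius {rho:.4f} >= 1"
            )
        Abar, H = mar_transfer(W, lagset, N, freqs, fs)
        csd[k] = H @ Sigma @ H.conj().transpose(0, 2, 1)
        denom = np.sqrt(np.sum(np.abs(Abar) ** 2, axis=1, keepdims=True))
        pdc[k] = np.abs(Abar) / denom
    psd = np.real(np.einsum("kfii->kfi", csd))
    coherence = coherence_from_csd(csd)
    return SpectralEstimate(
        freqs=freqs,
        csd=csd,
        psd=psd,
        coherence=coherence,
        pdc=pdc,
        provenance="parametric",
    )


# ---------------------------------------------------------------------------
# Model configuration


@dataclass
class PriorConfig:
    """Hyperparameters of the conjugate Bayesian hierarchy.

    Gamma priors are (shape, rate); defaults are weakly informative.  The
    Wishart prior for full noise covariance uses ``wishart_dof`` degrees of
    freedom and a scale proportional to the data variance (set at fit time
    when left as None).
    """

    noise_shape: float = 1e-3  # Gamma shape for diagonal noise precisions
    noise_rate: float = 1e-3
    sigma_shape: float = 1e-3  # per-connection ARD
    sigma_rate: float = 1e-3
    alpha_shape: float = 1e-3  # per-lag ARD
    alpha_rate: float = 1e-3
    dirichlet_trans: float = 1.0  # nu0, per transition-matrix entry
    dirichlet_init: float = 1.0  # zeta0
    wishart_dof: Optional[float] = None  # defaults to N + 1
    wishart_scale: Optional[np.ndarray] = None

    def validate(self) -> None:
        for name in (
            "noise_shape",
            "noise_rate",
            "sigma_shape",
            "sigma_rate",
            "alpha_shape",
            "alpha_rate",
            "dirichlet_trans",
            "dirichlet_init",
        ):
            if not getattr(self, name) > 0:
                raise InvalidConfigurationError(f"prior {name} must be positive")


@dataclass
class TrainingConfig:
    max_cycles: int = 100
    tol: float = 1e-5  # relative free-energy change per cycle
    n_restarts: int = 1
    restart_cycles: int = 20  # probe cycles per restart before committing
    seed: int = 0
    init_window_factor: int = 1  # init windows span factor * max lag samples

    def validate(self) -> None:
        if self.tol <= 0:
            raise InvalidConfigurationError("tolerance must be positive")
        if self.max_cycles < 1 or self.n_restarts < 1:
            raise InvalidConfigurationError("max_cycles and n_restarts must be >= 1")


@dataclass
class HMMMARConfig:
    """Full configuration of an HMM with MAR observation models."""

    K: int
    lagset: LagSet
    noise_cov: Literal["diagonal", "full"] = "diagonal"
    noise_shared: bool = False
    symmetric_sigma: bool = False
    clamping: Optional[ClampingPlan] = None
    observation: Literal["mar", "gaussian-envelope"] = "mar"
    priors: PriorConfig = field(default_factory=PriorConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def validate(self, n_channels: int | None = None) -> None:
        if self.K < 1:
            raise InvalidConfigurationError("K must be >= 1")
        self.priors.validate()
        self.training.validate()
        if n_channels is not None and self.clamping is not None:
            self.clamping.validate(n_channels, len(self.lagset))
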