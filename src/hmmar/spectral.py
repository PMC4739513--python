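"""State-specific non-parametric spectral estimation.

Once an HMM has produced per-sample state responsibilities ``gamma``, the
spectral content of each state can be estimated without reference to the
autoregressive parameters: samples are weighted by their responsibility and
passed through a Slepian multitaper, so that each state's cross-spectral
density pools over every (possibly very short) visit to that state.  From the
cross-spectral matrices we derive PSD and coherence directly, and partial
directed coherence (PDC) by first factorising the spectrum into a
minimum-phase transfer function with Wilson's algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional
import warnings

import numpy as np
import scipy.linalg
import scipy.signal

from .datatypes import TimeSeriesData


class EmptyStateError(ValueError):
    pass


class DegenerateSpectrumError(ValueError):
    pass


class FactorizationError(RuntimeError):
    pass


@dataclass
class TaperConfig:
    """Multitaper configuration: ``R`` Slepian tapers at time-bandwidth
    product ``NW`` on non-overlapping windows of ``window_length`` samples.

    The frequency resolution is ``2 * NW / (window_length / fs)`` Hz.
    """

    R: int = 7
    NW: float = 4.0
    window_length: Optional[int] = None  # defaults to 2 s of samples
    window_step: Optional[int] = None  # defaults to window_length

    def validate(self) -> None:
        if not (1 <= self.R <= 2 * self.NW - 1):
            raise ValueError(
                f"need 1 <= R <= 2*NW-1, got R={self.R}, NW={self.NW}"
            )

    def resolve(self, fs: float) -> tuple[int, int]:
        wl = self.window_length if self.window_length else int(round(2 * fs))
        step = self.window_step if self.window_step else wl
        return wl, step


@dataclass
class SpectralEstimate:
    """Per-state spectral description on a common frequency grid.

    ``csd`` has shape ``(K, F, N, N)`` (Hermitian at every frequency),
    ``psd`` is its real diagonal, ``coherence`` and ``pdc`` lie in [0, 1]
    with PDC columns normalised so that ``sum_i pdc[..., i, j]**2 == 1``.
    """

    freqs: np.ndarray
    csd: np.ndarray
    psd: np.ndarray
    coherence: np.ndarray
    pdc: Optional[np.ndarray] = None
    provenance: Literal["parametric", "multitaper"] = "multitaper"
    taper: Optional[TaperConfig] = None

    @property
    def n_states(self) -> int:
        return self.csd.shape[0]

    @property
    def n_channels(self) -> int:
        return self.csd.shape[-1]

    def peak_frequency(self, state: int, channel: int = 0) -> float:
        """Spectral peak of one state and channel.

        Returns the most prominent local maximum of the PSD (falling back
        to the global maximum when the spectrum is monotone), which is the
        conventional reading of "peak" for spectra riding on a 1/f
        background.
        """
        psd = self.psd[state, :, channel]
        idx, props = scipy.signal.find_peaks(psd, prominence=0)
        if idx.size == 0:
            return float(self.freqs[np.argmax(psd)])
        return float(self.freqs[idx[np.argmax(props["prominences"])]])


# ---------------------------------------------------------------------------
# Tapers and weights


def slepian_tapers(window_length: int, NW: float, R: int) -> np.ndarray:
    """Discrete prolate spheroidal sequences, unit norm, mutually orthogonal.

    Returns an ``(R, window_length)`` array.
    """
    if R > 2 * NW - 1:
        raise ValueError(f"R={R} exceeds 2*NW-1={2 * NW - 1:g}")
    if R < 1:
        raise ValueError("need at least one taper")
    tapers = scipy.signal.windows.dpss(window_length, NW, Kmax=R, norm=2)
    return np.atleast_2d(tapers)


def state_weights(gamma_k: np.ndarray) -> np.ndarray:
    """Per-sample spectral weights for one state.

    Weights are proportional to the responsibilities and rescaled so that
    ``sum(rho**2) == T``, preserving total power: a state occupying the whole
    series gets unit weights everywhere.
    """
    gamma_k = np.asarray(gamma_k, float)
    T = gamma_k.size
    ss = float(np.sum(gamma_k**2))
    if ss == 0:
        raise EmptyStateError("state has zero total responsibility")
    return gamma_k * np.sqrt(T / ss)


# ---------------------------------------------------------------------------
# Multitaper cross-spectra


def _windowed_csd(
    data: TimeSeriesData,
    sample_weights: np.ndarray,
    window_weights_source: np.ndarray,
    taper_cfg: TaperConfig,
    freq_range: Optional[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Core weighted multitaper estimator.

    Splits every segment into windows, multiplies samples by
    ``sample_weights`` and each taper, Fourier transforms, and averages
    outer products over tapers and windows; windows are weighted by the mean
    of ``window_weights_source`` (the state responsibilities) inside them.
    """
    taper_cfg.validate()
    wl, step = taper_cfg.resolve(data.fs)
    tapers = slepian_tapers(wl, taper_cfg.NW, taper_cfg.R)
    freqs = np.fft.rfftfreq(wl, d=1.0 / data.fs)
    if freq_range is not None:
        sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    else:
        sel = np.ones(freqs.size, bool)
    freqs_out = freqs[sel]
    N = data.n_channels
    acc = np.zeros((freqs_out.size, N, N), dtype=complex)
    total_w = 0.0
    for a, b in data.segments:
        for start in range(a, b - wl + 1, step):
            sl = slice(start, start + wl)
            w_win = float(np.mean(window_weights_source[sl]))
            if w_win <= 0:
                continue
            seg = data.values[sl] * sample_weights[sl, None]  # (wl, N)
            # (R, F, N): FFT of each tapered, weighted window
            spec = np.fft.rfft(tapers[:, :, None] * seg[None], axis=1)[:, sel]
            acc += w_win * np.einsum("rfi,rfj->fij", spec, spec.conj()) / tapers.shape[0]
            total_w += w_win
    if total_w == 0:
        raise EmptyStateError("no window carries state mass")
    return freqs_out, acc / total_w


def multitaper_csd(
    data: TimeSeriesData,
    taper_cfg: Optional[TaperConfig] = None,
    freq_range: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard (unweighted) multitaper cross-spectral density.

    Returns ``(freqs, csd)`` with ``csd`` of shape ``(F, N, N)``.
    """
    taper_cfg = taper_cfg or TaperConfig()
    T = data.n_samples
    ones = np.ones(T)
    return _windowed_csd(data, ones, ones, taper_cfg, freq_range)


def statewise_multitaper(
    data: TimeSeriesData,
    stc,
    taper_cfg: Optional[TaperConfig] = None,
    freq_range: Optional[tuple[float, float]] = None,
    compute_pdc: bool = False,
    harden: bool = False,
) -> SpectralEstimate:
    """State-weighted multitaper spectra for every state.

    ``stc`` is a state time course (or a plain ``(T, K)`` responsibility
    matrix).  Samples are weighted by the power-preserving weights of
    :func:`state_weights` before tapering, giving more weight to the samples
    best represented by each state.  With uniform unit responsibilities the
    result equals :func:`multitaper_csd` exactly.

    With ``harden=True`` the responsibilities are binarised (argmax) before
    weighting.  Set ``compute_pdc`` to derive PDC via Wilson factorization
    (appreciably more expensive).
    """
    gamma = np.asarray(getattr(stc, "gamma", stc), float)
    if gamma.ndim == 1:
        gamma = gamma[:, None]
    if harden:
        hard = np.argmax(gamma, axis=1)
        gamma = np.eye(gamma.shape[1])[hard]
    taper_cfg = taper_cfg or TaperConfig()
    wl, _ = taper_cfg.resolve(data.fs)
    if freq_range is not None and freq_range[0] > 0:
        if wl < 2 * data.fs / max(freq_range[0], 1e-12):
            warnings.warn(
                "window shorter than 2 cycles of the lowest requested "
                "frequency; low-frequency estimates will be unreliable",
                stacklevel=2,
            )
    K = gamma.shape[1]
    csd_states = []
    freqs = None
    # CSD on the full [0, fs/2] grid: Wilson factorization (for PDC) needs it
    for k in range(K):
        rho = state_weights(gamma[:, k])
        freqs, csd_k = _windowed_csd(data, rho, gamma[:, k], taper_cfg, None)
        csd_states.append(csd_k)
    csd = np.stack(csd_states)
    pdc = None
    if compute_pdc:
        pdc = np.stack(
            [pdc_from_csd(csd[k], data.fs, residual_tol=1e-2)[0] for k in range(K)]
        )
    if freq_range is not None:
        sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
        freqs = freqs[sel]
        csd = csd[:, sel]
        if pdc is not None:
            pdc = pdc[:, sel]
    psd = np.real(np.einsum("kfii->kfi", csd))
    coh = coherence_from_csd(csd)
    return SpectralEstimate(
        freqs=freqs,
        csd=csd,
        psd=psd,
        coherence=coh,
        pdc=pdc,
        provenance="multitaper",
        taper=taper_cfg,
    )


def coherence_from_csd(csd: np.ndarray) -> np.ndarray:
    """Coherence ``|S_ij| / sqrt(S_ii S_jj)`` from cross-spectral matrices.

    Accepts ``(..., N, N)`` Hermitian matrices; diagonal of the result is 1.
    """
    diag = np.real(np.einsum("...ii->...i", csd))
    if np.any(diag <= 0):
        raise DegenerateSpectrumError("zero or negative diagonal spectral power")
    denom = np.sqrt(diag[..., :, None] * diag[..., None, :])
    coh = np.abs(csd) / denom
    # clip tiny numerical overshoot
    return np.clip(coh, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Wilson spectral-matrix factorization and non-parametric PDC


def wilson_factorize(
    csd: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
    residual_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Factorise a cross-spectral density into a minimum-phase transfer
    function and innovation covariance (Wilson's algorithm).

    ``csd`` is ``(F, N, N)`` Hermitian positive definite on a uniform
    frequency grid covering ``[0, fs/2]`` inclusive.  Returns ``(H, Z)``
    such that ``S(f) = H(f) Z H(f)*`` with ``H`` minimum phase and zeroth
    impulse-response coefficient equal to the identity.

    The reconstruction residual ``max_f ||H Z H* - S||_F / ||S||_F`` is
    checked on every call; failure to reach ``residual_tol`` raises
    :class:`FactorizationError` reporting the residual.
    """
    S = np.asarray(csd, complex)
    if S.ndim != 3 or S.shape[1] != S.shape[2]:
        raise ValueError("csd must have shape (F, N, N)")
    F, N, _ = S.shape
    if F < 2:
        raise ValueError("need at least 2 frequency points")
    # regularise: make strictly positive definite if needed
    tr = np.real(np.einsum("fii->f", S)).mean()
    eigmin = np.min(np.linalg.eigvalsh(0.5 * (S + S.conj().transpose(0, 2, 1))).real)
    if eigmin <= 0:
        S = S + (1e-10 * tr - eigmin) * np.eye(N)[None]
    M = 2 * (F - 1)
    Sf = np.empty((M, N, N), complex)
    Sf[:F] = S
    # negative frequencies: S(-f) = S(f)* (elementwise conjugate; equals the
    # transpose for Hermitian cross-spectra)
    Sf[F:] = S[F - 2 : 0 : -1].conj()

    Savg = Sf.mean(axis=0)
    Savg = 0.5 * (Savg + Savg.conj().T).real
    psi = np.tile(scipy.linalg.cholesky(Savg, lower=False), (M, 1, 1)).astype(complex)

    I = np.eye(N)
    keep = M // 2  # retain causal coefficients 0 .. keep-1 (+ half of m=0 term)
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sf @ psi_inv.conj().transpose(0, 2, 1) + I[None]
        gam = np.fft.ifft(g, axis=0)
        beta0 = 0.5 * gam[0]
        gam[0] = np.triu(beta0)
        # halve nothing else; zero the anticausal part
        gam[keep + 1 :] = 0.0
        gp = np.fft.fft(gam, axis=0)
        psi_new = psi @ gp
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        psi = psi_new
        if delta < tol:
            break
    # innovation covariance and transfer function
    A0 = np.fft.ifft(psi, axis=0)[0].real
    Z = A0 @ A0.T
    H = psi[:F] @ np.linalg.inv(A0)
    # self-check: reconstruction of the one-sided input spectrum
    recon = H @ Z @ H.conj().transpose(0, 2, 1)
    num = np.linalg.norm(recon - np.asarray(csd, complex), axis=(1, 2))
    den = np.linalg.norm(np.asarray(csd, complex), axis=(1, 2))
    residual = float(np.max(num / np.maximum(den, 1e-300)))
    if residual > residual_tol:
        raise FactorizationError(
            f"Wilson factorization residual {residual:.3e} exceeds "
            f"{residual_tol:.1e} after {max_iter} iterations"
        )
    return H, Z


def pdc_from_csd(
    csd: np.ndarray,
    fs: float,
    max_iter: int = 100,
    tol: float = 1e-9,
    residual_tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-parametric partial directed coherence from a cross-spectral density.

    The CSD is factorised into a minimum-phase transfer function ``H`` whose
    inverse plays the role of the autoregressive frequency response
    ``Abar(f)``; PDC is then the column-normalised magnitude
    ``|Abar_ij| / sqrt(sum_m |Abar_mj|^2)``, exactly as in the parametric
    definition.  Returns ``(pdc, H, Z)``.
    """
    H, Z = wilson_factorize(csd, max_iter=max_iter, tol=tol, residual_tol=residual_tol)
    Abar = np.linalg.inv(H)
    denom = np.sqrt(np.sum(np.abs(Abar) ** 2, axis=1, keepdims=True))
    pdc = np.abs(Abar) / denom
    return pdc, H, Z


# ---------------------------------------------------------------------------
# Envelopes and diagnostics


def hilbert_envelope(data: TimeSeriesData) -> TimeSeriesData:
    """Per-channel amplitude envelope (magnitude of the analytic signal).

    Computed independently within each segment so that trial edges do not
    bleed into one another.
    """
    out = np.empty_like(data.values)
    for a, b in data.segments:
        out[a:b] = np.abs(scipy.signal.hilbert(data.values[a:b], axis=0))
    return data.copy_with(out)


def gamma_spectrum_diagnostic(
    stc,
    fs: float,
    band: tuple[float, float] = (1.0, 48.0),
    threshold: float = 0.2,
    taper_cfg: Optional[TaperConfig] = None,
    segments: Optional[list[tuple[int, int]]] = None,
) -> dict:
    """Spectrum of each state time course and its overlap with a band.

    The statewise multitaper weights the data by the state time courses, so
    spectral structure in the responsibilities themselves can leak into the
    statewise spectra (a convolution in frequency).  This diagnostic reports
    the multitaper PSD of each ``gamma`` column and the fraction of its
    non-DC power falling inside ``band``; when that fraction exceeds
    ``threshold`` a warning recommends the parametric spectra instead.
    """
    gamma = np.asarray(getattr(stc, "gamma", stc), float)
    if gamma.ndim == 1:
        gamma = gamma[:, None]
    gamma = gamma - gamma.mean(axis=0, keepdims=True)  # remove DC
    ts = TimeSeriesData(values=gamma, fs=fs, segments=segments or [])
    taper_cfg = taper_cfg or TaperConfig()
    freqs, csd = multitaper_csd(ts, taper_cfg)
    psd = np.real(np.einsum("fii->if", csd))  # (K, F)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    total = psd.sum(axis=1)
    frac = np.where(total > 0, psd[:, in_band].sum(axis=1) / np.maximum(total, 1e-300), 0.0)
    flagged = frac > threshold
    if np.any(flagged):
        warnings.warn(
            f"state time course spectra have {frac.max():.0%} of power inside "
            f"the analysis band {band}; statewise multitaper estimates may be "
            "distorted — consider the parametric spectra",
            stacklevel=2,
        )
    return {
        "freqs": freqs,
        "psd": psd,
        "band": band,
        "band_fraction": frac,
        "flagged": flagged,
    }
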