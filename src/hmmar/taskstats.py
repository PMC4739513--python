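"""Task-locked summaries and statistics for fitted state time courses.

Even though the state model is trained with no knowledge of task timings,
epoching the state time courses around known events reveals task-dependent
state occupancy.  Combining the state time courses with the per-state
spectra yields regularised time-frequency (T-F) maps — the outer product of
occupancy and spectral content summed over states — and cluster-extent
permutation tests assess which T-F regions or frequency ranges differ
reliably from baseline or between states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import scipy.ndimage

from .spectral import SpectralEstimate


class EmptyEpochError(ValueError):
    pass


@dataclass
class OccupancyProfile:
    """Peri-event fractional occupancy per state.

    ``per_trial`` is ``(n_events, n_times, K)``; ``mean`` averages over
    events.  At every peri-event time the occupancies sum to one (soft
    responsibilities are conserved by averaging).
    """

    times: np.ndarray  # seconds relative to event
    per_trial: np.ndarray
    mean: np.ndarray
    window_s: tuple[float, float]


@dataclass
class TFMap:
    """Time-frequency map of one spectral measure around an event.

    ``values`` has shape ``(n_times, F)`` plus trailing channel axes
    (``(N,)`` for PSD, ``(N, N)`` for coherence/PDC).  ``mask`` marks
    significant elements when a cluster test has been run.
    """

    measure: Literal["psd", "coherence", "pdc"]
    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    baseline_window_s: Optional[tuple[float, float]] = None
    per_trial: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None


def _epoch_indices(
    events: np.ndarray,
    segments: list[tuple[int, int]],
    window: tuple[int, int],
    event_segments: Optional[np.ndarray] = None,
) -> list[int]:
    """Events whose full peri-event window fits inside their segment."""
    usable = []
    for i, e in enumerate(events):
        lo, hi = e + window[0], e + window[1]
        ok = False
        for a, b in segments:
            if a <= e < b and lo >= a and hi <= b:
                ok = True
                break
        if ok:
            usable.append(i)
    if len(usable) < len(events):
        warnings.warn(
            f"dropped {len(events) - len(usable)} events with partial windows",
            stacklevel=3,
        )
    return usable


def epoch_fractional_occupancy(
    stc,
    events: np.ndarray,
    window_s: tuple[float, float],
    fs: float,
    segments: Optional[list[tuple[int, int]]] = None,
) -> OccupancyProfile:
    """Epoch and average the state time courses around events.

    ``events`` are absolute sample indices; ``window_s = (pre, post)`` in
    seconds relative to the event (pre negative).  Events whose window does
    not fit inside a segment are dropped with a warning.
    """
    gamma = np.asarray(getattr(stc, "gamma", stc), float)
    events = np.asarray(events, int)
    w0, w1 = int(round(window_s[0] * fs)), int(round(window_s[1] * fs))
    segments = segments or [(0, gamma.shape[0])]
    usable = _epoch_indices(events, segments, (w0, w1))
    if not usable:
        raise EmptyEpochError("no event window fits inside a segment")
    slices = np.stack([gamma[events[i] + w0 : events[i] + w1] for i in usable])
    times = (np.arange(w0, w1)) / fs
    return OccupancyProfile(
        times=times,
        per_trial=slices,
        mean=slices.mean(axis=0),
        window_s=window_s,
    )


def state_lifetimes(
    stc,
    segments: Optional[list[tuple[int, int]]] = None,
    fs: Optional[float] = None,
    hard_path: Optional[np.ndarray] = None,
) -> dict:
    """Lifetime samples, mean lifetimes and percent occupancy per state.

    The hard path defaults to the per-sample argmax of gamma (ties resolved
    to the lower state index); pass ``hard_path`` (e.g. a Viterbi path) to
    override.  Run lengths are collected within segments only.
    """
    gamma = np.asarray(getattr(stc, "gamma", stc), float)
    hard = hard_path if hard_path is not None else np.argmax(gamma, axis=1)
    K = gamma.shape[1] if gamma.ndim == 2 else int(hard.max()) + 1
    segments = segments or [(0, hard.shape[0])]
    lifetimes: list[list[int]] = [[] for _ in range(K)]
    for a, b in segments:
        h = hard[a:b]
        edges = np.flatnonzero(np.diff(h)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [b - a]))
        for s, e in zip(starts, ends):
            lifetimes[h[s]].append(int(e - s))
    total = hard.shape[0]
    out = {
        "lifetimes": [np.asarray(lt) for lt in lifetimes],
        "mean_lifetime": np.array(
            [np.mean(lt) if lt else np.nan for lt in lifetimes]
        ),
        "percent_occupancy": np.array(
            [100.0 * np.sum(hard == k) / total for k in range(K)]
        ),
    }
    if fs:
        out["mean_lifetime_s"] = out["mean_lifetime"] / fs
    return out


def tf_reconstruct(
    stc,
    spectra: SpectralEstimate,
    events: np.ndarray,
    window_s: tuple[float, float],
    fs: float,
    baseline_s: Optional[tuple[float, float]] = None,
    measures: tuple[str, ...] = ("psd",),
    segments: Optional[list[tuple[int, int]]] = None,
) -> dict[str, TFMap]:
    """HMM-regularised time-frequency maps around events.

    For each measure the T-F value at time ``t`` and frequency ``f`` is the
    occupancy-weighted sum over states, ``sum_k measure_f^(k) gamma_tk`` —
    the outer product of state time course and state spectrum.  Maps are
    epoched around events and, when ``baseline_s`` is given (seconds
    relative to the event), corrected by subtracting the per-frequency mean
    over the baseline window.  The uncorrected per-state spectra remain
    available in ``spectra``.
    """
    gamma = np.asarray(getattr(stc, "gamma", stc), float)
    w0, w1 = int(round(window_s[0] * fs)), int(round(window_s[1] * fs))
    if baseline_s is not None:
        if baseline_s[0] < window_s[0] or baseline_s[1] > window_s[1]:
            raise ValueError(
                f"baseline window {baseline_s} outside epoch window {window_s}"
            )
    segments = segments or [(0, gamma.shape[0])]
    events = np.asarray(events, int)
    usable = _epoch_indices(events, segments, (w0, w1))
    if not usable:
        raise EmptyEpochError("no event window fits inside a segment")
    times = np.arange(w0, w1) / fs
    out: dict[str, TFMap] = {}
    for measure in measures:
        vals = getattr(spectra, measure)  # (K, F, ...) arrays
        if vals is None:
            raise ValueError(f"spectra do not include measure {measure!r}")
        per_trial = []
        for i in usable:
            g = gamma[events[i] + w0 : events[i] + w1]  # (n_times, K)
            per_trial.append(np.tensordot(g, vals, axes=(1, 0)))
        per_trial = np.stack(per_trial)  # (n_ev, n_times, F, ...)
        if baseline_s is not None:
            b0 = int(round((baseline_s[0] - window_s[0]) * fs))
            b1 = int(round((baseline_s[1] - window_s[0]) * fs))
            base = per_trial[:, b0:b1].mean(axis=1, keepdims=True)
            per_trial = per_trial - base
        out[measure] = TFMap(
            measure=measure,  # type: ignore[arg-type]
            times=times,
            freqs=spectra.freqs,
            values=per_trial.mean(axis=0),
            baseline_window_s=baseline_s,
            per_trial=per_trial,
        )
    return out


# ---------------------------------------------------------------------------
# Cluster-extent permutation testing


def _max_cluster_extent(mask: np.ndarray, structure: Optional[np.ndarray]) -> int:
    lab, n = scipy.ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    return int(np.max(np.bincount(lab.ravel())[1:]))


def cluster_permutation_test(
    observations: np.ndarray,
    mode: Literal["1d", "2d"] = "2d",
    cluster_threshold: float = 3.0,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Cluster-extent permutation test of maps against zero.

    ``observations`` is ``(n_obs, ...)`` — per-trial or per-subject contrast
    maps (1-D curves or 2-D T-F maps).  Element-wise t-statistics are
    thresholded at ``|t| > cluster_threshold``; contiguous supra-threshold
    clusters (4-connectivity in 2-D) are scored by extent, and the null
    distribution of the maximal extent is built from random sign flips of
    the observations.  Each tail is tested separately at level ``alpha``.

    Returns a dict with ``t``, boolean masks ``mask_pos``/``mask_neg``/
    ``mask`` and the per-tail extent thresholds.
    """
    obs = np.asarray(observations, float)
    n = obs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if n_perm < 1.0 / alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve alpha={alpha}", stacklevel=2
        )
    map_shape = obs.shape[1:]
    if mode == "1d" and len(map_shape) != 1:
        raise ValueError("1d mode expects (n_obs, n_points) observations")
    if mode == "2d" and len(map_shape) != 2:
        raise ValueError("2d mode expects (n_obs, n_t, n_f) observations")
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]) if mode == "2d" else None
    )
    flat = obs.reshape(n, -1)
    msq = np.mean(flat**2, axis=0)

    def tstat(mean):
        var = (msq - mean**2) * n / (n - 1)
        return mean / np.sqrt(np.maximum(var, 1e-300) / n)

    t_obs = tstat(flat.mean(axis=0)).reshape(map_shape)
    rng = np.random.default_rng(seed)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for p in range(n_perm):
        s = rng.choice([-1.0, 1.0], size=n)
        t_p = tstat(s @ flat / n).reshape(map_shape)
        null_pos[p] = _max_cluster_extent(t_p > cluster_threshold, structure)
        null_neg[p] = _max_cluster_extent(t_p < -cluster_threshold, structure)
    thr_pos = np.quantile(null_pos, 1 - alpha)
    thr_neg = np.quantile(null_neg, 1 - alpha)

    def significant(mask, thr):
        lab, nclus = scipy.ndimage.label(mask, structure=structure)
        out = np.zeros(map_shape, bool)
        for c in range(1, nclus + 1):
            m = lab == c
            if m.sum() > thr:
                out |= m
        return out

    mask_pos = significant(t_obs > cluster_threshold, thr_pos)
    mask_neg = significant(t_obs < -cluster_threshold, thr_neg)
    return {
        "t": t_obs,
        "mask_pos": mask_pos,
        "mask_neg": mask_neg,
        "mask": mask_pos | mask_neg,
        "extent_threshold_pos": float(thr_pos),
        "extent_threshold_neg": float(thr_neg),
        "null_pos": null_pos,
        "null_neg": null_neg,
    }


def compare_states_spectra(
    spectra_obs: np.ndarray,
    cluster_threshold: float = 3.0,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
) -> list[dict]:
    """Per-state spectral contrasts against the mean of the other states.

    ``spectra_obs`` is ``(n_obs, K, F)`` — one spectral curve per state per
    observation (trial or subject).  For each state the contrast
    ``state - mean(others)`` is tested with a 1-D cluster permutation test,
    higher and lower tails separately.  With ``K = 2`` the two contrasts are
    exact mirror images.
    """
    obs = np.asarray(spectra_obs, float)
    if obs.ndim != 3:
        raise ValueError("expected (n_obs, K, F) spectra")
    K = obs.shape[1]
    if K < 2:
        raise ValueError("need at least 2 states to contrast")
    results = []
    for k in range(K):
        others = [j for j in range(K) if j != k]
        contrast = obs[:, k] - obs[:, others].mean(axis=1)
        res = cluster_permutation_test(
            contrast,
            mode="1d",
            cluster_threshold=cluster_threshold,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
        )
        res["state"] = k
        res["contrast_mean"] = contrast.mean(axis=0)
        results.append(res)
    return results


def sliding_window_spectra(
    data,
    window_s: float,
    step_s: float,
    taper_cfg=None,
    freq_range: Optional[tuple[float, float]] = None,
):
    """Conventional sliding-window multitaper T-F estimate (comparison utility).

    Calls the standard multitaper with uniform weights on successive
    windows.  Returns ``(times, freqs, psd)`` with ``psd`` of shape
    ``(n_windows, F, N)``.  Provided for comparison with the regularised
    T-F maps; expect noisier estimates for short windows.
    """
    from .datatypes import TimeSeriesData
    from .spectral import TaperConfig, multitaper_csd

    wl = int(round(window_s * data.fs))
    step = int(round(step_s * data.fs))
    taper_cfg = taper_cfg or TaperConfig()
    times, psds = [], []
    for a, b in data.segments:
        for s in range(a, b - wl + 1, step):
            chunk = TimeSeriesData(values=data.values[s : s + wl], fs=data.fs)
            cfg = TaperConfig(
                R=taper_cfg.R, NW=taper_cfg.NW, window_length=wl, window_step=wl
            )
            freqs, csd = multitaper_csd(chunk, cfg, freq_range)
            psds.append(np.real(np.einsum("fii->fi", csd)))
            times.append((s + wl / 2) / data.fs)
    return np.asarray(times), freqs, np.stack(psds)
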