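"""Core containers for multichannel electrophysiological time series.

A recording is a ``T x N`` matrix of samples by channels at a fixed sampling
rate.  Recordings are frequently built from concatenated trials or sessions;
``segments`` records those boundaries so that downstream autoregressions never
regress across a trial edge.  Optional event markers (e.g. button presses,
stimulus onsets) are attached per segment for task-locked analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeriesData:
    """Multichannel time series with segment structure and event markers.

    Parameters
    ----------
    values : ndarray, shape (T, N)
        One row per sample, one column per channel.  Must be finite.
    fs : float
        Sampling rate in Hz.
    segments : list of (int, int), optional
        Half-open ``[start, stop)`` sample ranges partitioning ``[0, T)``.
        Defaults to the single segment ``[(0, T)]``.
    events : list of (int, int), optional
        ``(segment_index, absolute_sample_index)`` markers; every event must
        lie inside its segment.
    """

    values: np.ndarray
    fs: float
    segments: list[tuple[int, int]] = field(default_factory=list)
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x channels) array")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {bad[0]}, channel {bad[1]}"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate fs must be positive")
        T = self.values.shape[0]
        if not self.segments:
            self.segments = [(0, T)]
        self.segments = [(int(a), int(b)) for a, b in self.segments]
        cursor = 0
        for a, b in self.segments:
            if a != cursor or b <= a:
                raise ValueError(
                    "segments must be disjoint, ordered half-open ranges "
                    f"covering [0, {T}); got {self.segments}"
                )
            cursor = b
        if cursor != T:
            raise ValueError(f"segments do not cover [0, {T})")
        for seg, s in self.events:
            a, b = self.segments[seg]
            if not (a <= s < b):
                raise ValueError(
                    f"event sample {s} outside segment {seg} = [{a}, {b})"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_lengths(self) -> np.ndarray:
        return np.array([b - a for a, b in self.segments])

    def copy_with(self, values: np.ndarray) -> "TimeSeriesData":
        """Return a new container with the same metadata but new values."""
        return TimeSeriesData(
            values=np.array(values, dtype=float),
            fs=self.fs,
            segments=list(self.segments),
            events=list(self.events),
        )
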