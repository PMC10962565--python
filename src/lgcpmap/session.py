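"""Behavioral session container.

A session is a uniformly sampled time series of 2D positions and per-sample
spike counts, optionally with head direction.  Positions live in arena
coordinates (the same units as ``GridSpec.bin_size``; the built-in simulator
uses 1 m bins so positions are numerically equal to bin units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Session:
    """Trajectory + spikes (+ optional heading) at a fixed sample interval.

    Attributes
    ----------
    times : (T,) float array, seconds, strictly increasing, uniform spacing.
    positions : (T, 2) float array, columns (x, y).
    spikes : (T,) nonnegative integer counts per sample.
    heading : (T,) float array of head direction in radians, or None.
    dt : sample interval in seconds.
    """

    times: np.ndarray
    positions: np.ndarray
    spikes: np.ndarray
    heading: np.ndarray | None = None
    dt: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        self.spikes = np.asarray(self.spikes)
        if self.heading is not None:
            self.heading = np.asarray(self.heading, float)
        T = self.times.shape[0]
        if self.positions.shape != (T, 2):
            raise ValueError(f"positions must be (T, 2) with T={T}, got {self.positions.shape}")
        if self.spikes.shape != (T,):
            raise ValueError("spikes length must match times")
        if self.heading is not None and self.heading.shape != (T,):
            raise ValueError("heading length must match times")
        dts = np.diff(self.times)
        if T > 1:
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
            if self.dt == 0.0:
                self.dt = float(dts[0])
        if np.any(np.asarray(self.spikes) < 0):
            raise ValueError("spike counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(self.times.shape[0])

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def total_spikes(self) -> int:
        return int(np.sum(self.spikes))
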