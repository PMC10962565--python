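"""Spatial binning of sessions into per-bin visit and spike masses.

Coordinate convention, used everywhere in this package: a position ``p``
maps to fractional bin coordinates ``u = (p - origin)/bin_size``; bin
centers sit at ``u = i + 0.5``; arrays are indexed ``[row, col]`` with row
<-> y and col <-> x.  Each sample's unit visit mass (and its spike count)
is distributed over the 2x2 neighborhood of surrounding bin centers by
bilinear weights ("square-pyramidal" basis functions), which amounts to a
trapezoid-rule integration of the likelihood over space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .session import Session

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular analysis grid: interior ``rows x cols`` bins plus padding.

    ``pad`` is the number of zero-mass margin bins added per side before
    spectral operations; it must be at least the prior kernel's cutoff
    radius so the circulant wrap-around cannot leak correlations across
    opposite walls.
    """

    rows: int
    cols: int
    bin_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    pad: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.pad < 0:
            raise ValueError("pad must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def padded_shape(self) -> tuple[int, int]:
        return (self.rows + 2 * self.pad, self.cols + 2 * self.pad)

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the interior arena in position units."""
        x0, y0 = self.origin
        return (x0, x0 + self.cols * self.bin_size, y0, y0 + self.rows * self.bin_size)


@dataclass
class BinnedCounts:
    """Visit mass ``n`` and spike mass ``k`` per interior bin.

    Invariants: ``n, k >= 0`` elementwise, ``k = 0`` wherever ``n = 0``,
    ``sum(n)`` equals the (weighted) number of samples and ``sum(k)`` the
    (weighted) number of spikes.
    """

    n: np.ndarray
    k: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.n.shape != self.grid.shape or self.k.shape != self.grid.shape:
            raise ValueError("n and k must have the grid's interior shape")

    @property
    def rate_histogram(self) -> np.ndarray:
        """Raw per-bin rate k/n, NaN where unvisited."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.k / np.where(self.n > 0, self.n, 1.0), np.nan)


def pad(arr: np.ndarray, p: int) -> np.ndarray:
    """Zero-pad a 2D map by ``p`` bins on every side."""
    if p < 0:
        raise ValueError("pad must be nonnegative")
    if p == 0:
        return arr.copy()
    if 2 * p >= 8 * max(arr.shape):
        raise ValueError("pad is unreasonably large for this array")
    return np.pad(arr, p, mode="constant")


def unpad(arr: np.ndarray, p: int) -> np.ndarray:
    """Remove ``p`` margin bins from every side (inverse of :func:`pad`)."""
    if p < 0:
        raise ValueError("pad must be nonnegative")
    if p == 0:
        return arr.copy()
    if 2 * p >= min(arr.shape):
        raise ValueError("pad exceeds array size")
    return arr[p:-p, p:-p].copy()


def bin_session(
    session: Session,
    grid: GridSpec,
    weights: np.ndarray | None = None,
) -> BinnedCounts:
    """Accumulate bilinear visit/spike masses onto the interior grid.

    ``weights`` optionally scales each sample's visit mass (and its spike
    mass ``w_t * y_t``), as used for head-direction-conditioned maps.

    Samples with NaN positions are dropped (count logged); positions outside
    the arena extent raise with the index of the first offending sample.
    """
    pos = session.positions
    spikes = np.asarray(session.spikes, float)
    w = np.ones(session.n_samples) if weights is None else np.asarray(weights, float)
    if w.shape != (session.n_samples,):
        raise ValueError("weights must be one scalar per sample")

    valid = np.isfinite(pos).all(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.info("dropping %d samples with missing positions", n_dropped)
        pos, spikes, w = pos[valid], spikes[valid], w[valid]

    xmin, xmax, ymin, ymax = grid.extent()
    tol = 1e-9 * grid.bin_size
    bad = (pos[:, 0] < xmin - tol) | (pos[:, 0] > xmax + tol) | \
          (pos[:, 1] < ymin - tol) | (pos[:, 1] > ymax + tol)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"position outside arena extent at sample {idx}: {pos[idx]}")

    # fractional coordinates relative to bin centers
    ux = (pos[:, 0] - xmin) / grid.bin_size - 0.5
    uy = (pos[:, 1] - ymin) / grid.bin_size - 0.5
    ix0 = np.floor(ux).astype(int)
    iy0 = np.floor(uy).astype(int)
    fx = ux - ix0
    fy = uy - iy0

    n = np.zeros(grid.shape)
    k = np.zeros(grid.shape)
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        wt = (fy if dy else 1.0 - fy) * (fx if dx else 1.0 - fx)
        # clip the 2x2 neighborhood into the interior; boundary samples keep
        # full mass on the nearest existing bins (padding must stay massless)
        rr = np.clip(iy0 + dy, 0, grid.rows - 1)
        cc = np.clip(ix0 + dx, 0, grid.cols - 1)
        np.add.at(n, (rr, cc), w * wt)
        np.add.at(k, (rr, cc), w * spikes * wt)

    return BinnedCounts(n=n, k=k, grid=grid)
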