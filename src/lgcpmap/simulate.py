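"""Synthetic grid-cell foraging sessions with known ground truth.

The generator emulates the standard benchmark for grid-cell rate-map
estimators: a Brownian-motion forager in a square arena, smoothed twice with
a first-order exponential filter to mimic behavioral inertia, sampling
conditionally Poisson spikes from an ideal hexagonal log-rate map whose
trajectory-averaged expected rate is calibrated exactly to a stated mean
rate.

Defaults reproduce the benchmark conditions: a 90x90-bin arena, grid period
13 bins, 30 min at 50 Hz, mean rate 1.2 Hz, double exponential smoothing
with tau = 190 ms.  The diffusion constant defaults to 1.0 bins^2/s, i.e. a
per-step displacement variance of 0.02 bins^2 at 50 Hz sampling, which
produces arena-scale coverage over a 30-minute session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .session import Session


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic foraging session.

    grid_side : arena side length in bins.
    period_bins : grid spatial period P, bins.
    orientation : grid orientation theta0, radians.
    mean_rate : trajectory-averaged expected firing rate, Hz.
    duration : session length, seconds.
    sample_rate : behavioral sampling rate, Hz.
    diffusion : Brownian diffusion of the forager, bins^2/s per axis.
    smooth_tau : time constant of the (doubly applied) exponential smoother, s.
    log_amplitude : contrast of the log-rate modulation (the hexagonal
        wave-sum is multiplied by this before mean-rate calibration).
    seed : master seed; independent substreams drive trajectory and spikes.
    """

    grid_side: int = 90
    period_bins: float = 13.0
    orientation: float = 0.0
    mean_rate: float = 1.2
    duration: float = 1800.0
    sample_rate: float = 50.0
    diffusion: float = 1.0
    smooth_tau: float = 0.190
    log_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_side", "period_bins", "duration", "sample_rate",
                     "smooth_tau", "log_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_rate < 0 or self.diffusion < 0:
            raise ValueError("mean_rate and diffusion must be nonnegative")
        if self.period_bins >= self.grid_side:
            raise ValueError("period_bins must be smaller than grid_side")
        n = self.sample_rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_rate * duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.duration))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


def grid_log_rate_at(points: np.ndarray, period: float, orientation: float = 0.0,
                     amplitude: float = 1.0) -> np.ndarray:
    """Ideal hexagonal log-rate at continuous positions ``points`` (N, 2).

    Sum of three cosine plane waves of period ``period`` rotated pi/3 from
    each other; equals ``3*amplitude`` at the lattice origin and averages to
    zero over many periods.
    """
    if period < 2:
        raise ValueError("period must be at least 2 bins (Nyquist)")
    pts = np.atleast_2d(np.asarray(points, float))
    z = np.zeros(pts.shape[0])
    for ell in range(3):
        ang = np.pi / 3 * ell - orientation
        z += np.cos(2 * np.pi / period * (pts[:, 0] * np.cos(ang) - pts[:, 1] * np.sin(ang)))
    return amplitude * z


def ideal_grid_log_rate(grid_side: int, period: float, orientation: float = 0.0,
                        amplitude: float = 1.0, centers: bool = True) -> np.ndarray:
    """Ideal hexagonal log-rate map on a ``grid_side x grid_side`` grid.

    With ``centers=True`` (default) the map is evaluated at bin centers
    (i + 0.5), matching the binning convention; with ``centers=False`` it is
    evaluated on the integer lattice so ``map[0, 0] = 3*amplitude``.
    The map is un-normalized: mean-rate calibration happens in
    :func:`simulate_session`.
    """
    off = 0.5 if centers else 0.0
    yy, xx = np.mgrid[0:grid_side, 0:grid_side].astype(float) + off
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return grid_log_rate_at(pts, period, orientation, amplitude).reshape(grid_side, grid_side)


def _exp_smooth(x: np.ndarray, alpha: float) -> np.ndarray:
    # y_t = y_{t-1} + alpha (x_t - y_{t-1}), initialized at the first sample
    b = 1.0 - alpha
    zi = b * x[:1]  # makes y_0 = x_0
    y, _ = lfilter([alpha], [1.0, -b], x, axis=0, zi=zi)
    return y


def simulate_trajectory(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Brownian-motion foraging path, clipped to the arena, smoothed twice.

    Increments have per-step variance ``diffusion/sample_rate`` per axis; the
    cumulative path starts at the arena center and is clipped to
    ``[0, grid_side]``, then passed twice through a first-order exponential
    smoother with time constant ``smooth_tau``.
    Returns positions in bins, shape (T, 2), columns (x, y).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    T = cfg.n_samples
    step_sd = np.sqrt(cfg.diffusion / cfg.sample_rate)
    steps = rng.normal(0.0, step_sd, size=(T, 2)) if step_sd > 0 else np.zeros((T, 2))
    pos = np.cumsum(steps, axis=0) + cfg.grid_side / 2.0
    pos = np.clip(pos, 0.0, cfg.grid_side)
    alpha = 1.0 - np.exp(-cfg.dt / cfg.smooth_tau)
    for _ in range(2):
        pos = _exp_smooth(pos, alpha)
    # smoothing is a convex average of clipped positions, so bounds still hold
    return np.clip(pos, 0.0, cfg.grid_side)


def _bilinear_sample(vmap: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Sample a bin-centers map at continuous positions by bilinear interpolation."""
    rows, cols = vmap.shape
    ux = np.clip(pos[:, 0] - 0.5, 0.0, cols - 1.0)
    uy = np.clip(pos[:, 1] - 0.5, 0.0, rows - 1.0)
    ix0 = np.clip(np.floor(ux).astype(int), 0, cols - 2)
    iy0 = np.clip(np.floor(uy).astype(int), 0, rows - 2)
    fx = ux - ix0
    fy = uy - iy0
    return (vmap[iy0, ix0] * (1 - fy) * (1 - fx)
            + vmap[iy0, ix0 + 1] * (1 - fy) * fx
            + vmap[iy0 + 1, ix0] * fy * (1 - fx)
            + vmap[iy0 + 1, ix0 + 1] * fy * fx)


def simulate_session(cfg: SimConfig) -> tuple[Session, np.ndarray]:
    """Simulate a full session; returns (session, calibrated true log-rate map).

    The ideal log-rate is evaluated along the trajectory by bilinear
    interpolation and offset so the trajectory-averaged expected rate equals
    ``cfg.mean_rate`` exactly; spike counts are Poisson(rate * dt) per sample.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_traj, rng_spk = (np.random.default_rng(s) for s in ss.spawn(2))
    pos = simulate_trajectory(cfg, rng_traj)
    zmap = ideal_grid_log_rate(cfg.grid_side, cfg.period_bins, cfg.orientation,
                               cfg.log_amplitude)
    z_traj = _bilinear_sample(zmap, pos)
    if cfg.mean_rate > 0:
        offset = np.log(cfg.mean_rate) - np.log(np.mean(np.exp(z_traj)))
        rate = np.exp(z_traj + offset)
        spikes = rng_spk.poisson(rate * cfg.dt)
        truth = zmap + offset
    else:
        spikes = np.zeros(cfg.n_samples, dtype=np.int64)
        truth = np.full_like(zmap, -np.inf)
    times = np.arange(cfg.n_samples) * cfg.dt
    return Session(times=times, positions=pos, spikes=spikes, dt=cfg.dt), truth
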