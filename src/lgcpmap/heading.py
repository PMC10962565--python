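"""Head-direction preprocessing, direction-conditioned rate maps, and joint
2D + direction inference.

Two routes expose directional structure in a grid cell:

* weighted subsets — reweight every sample by the squared-cosine similarity
  w = max(0, cos(phi - phi0))^2 between its (smoothed) head direction and a
  reference direction phi0; binning the weighted masses reduces the problem
  to ordinary 2D inference, and opposing directions land in disjoint
  subsets;
* joint inference — treat head direction as a third, circular, unpadded
  axis: the prior kernel is the separable product of a PSD-clipped
  squared-cosine direction kernel and the optimized spatial kernel, and the
  same low-rank spectral machinery fits the 3D posterior (rank capped so
  the basis stays manageable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .binning import BinnedCounts, GridSpec, bin_session
from .inference import PriorSpec, VariationalState, fit
from .kernels import Hyperparams, direction_kernel, joint_kernel, kernel_pad, make_kernel
from .posterior import find_peaks, _disc
from .session import Session
from .spectral import build_spectral_prior, expand_batch
from scipy.ndimage import binary_dilation


@dataclass
class HeadingSeries:
    """Smoothed head direction, radians in [0, 2 pi), with validity mask."""

    phi: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.mod(np.asarray(self.phi, float), 2 * np.pi)
        self.valid_mask = np.asarray(self.valid_mask, bool)
        if np.any(~np.isfinite(self.phi[self.valid_mask])):
            raise ValueError("heading must be finite where valid")


def smooth_heading(phi_raw: np.ndarray, valid_mask: np.ndarray | None,
                   sample_rate: float, polyorder: int = 3,
                   window_seconds: float = 1.0) -> HeadingSeries:
    """Low-pass the head direction in (cos, sin) component space.

    Gaps are linearly interpolated per component; a Savitzky-Golay filter of
    order ``polyorder`` with an ~``window_seconds`` window (nearest odd
    sample count) is applied to each component, placing the -3 dB point
    near 2 Hz at 50 Hz sampling; the angle of the complex sum recombines
    them, so wrap-around at 0/2 pi never produces jumps.
    """
    phi_raw = np.asarray(phi_raw, float)
    valid = np.isfinite(phi_raw) if valid_mask is None else \
        (np.asarray(valid_mask, bool) & np.isfinite(phi_raw))
    if valid.sum() < 2:
        raise ValueError("need at least two valid heading samples")
    t = np.arange(phi_raw.size)
    cx = np.interp(t, t[valid], np.cos(phi_raw[valid]))
    sx = np.interp(t, t[valid], np.sin(phi_raw[valid]))
    window = int(round(sample_rate))
    window += 1 - window % 2  # nearest odd
    window = max(window, polyorder + 2 - (polyorder % 2))
    if window <= phi_raw.size:
        cx = savgol_filter(cx, window, polyorder)
        sx = savgol_filter(sx, window, polyorder)
    return HeadingSeries(phi=np.arctan2(sx, cx), valid_mask=valid)


def direction_weights(phi: np.ndarray, phi0: float) -> np.ndarray:
    """Squared-cosine similarity weights w = max(0, cos(phi - phi0))^2.

    Opposing reference directions phi0 and phi0 + pi produce disjointly
    supported weights; invariant under phi0 -> phi0 + 2 pi.
    """
    return np.maximum(0.0, np.cos(np.asarray(phi, float) - phi0)) ** 2


def weighted_counts(session: Session, heading: HeadingSeries, phi0: float,
                    grid: GridSpec) -> BinnedCounts:
    """Direction-conditioned binned counts: visit mass w_t, spike mass w_t y_t."""
    if heading.phi.shape[0] != session.n_samples:
        raise ValueError("heading must align with session samples")
    w = direction_weights(heading.phi, phi0) * heading.valid_mask
    return bin_session(session, grid, weights=w)


def bin_session_3d(session: Session, heading: HeadingSeries, grid: GridSpec,
                   n_dir: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear binning onto (direction, row, col): circular linear
    interpolation between the two adjacent direction bins times bilinear
    spatial weights.  Returns (n, k) with shape (n_dir, rows, cols)."""
    ud = np.mod(heading.phi, 2 * np.pi) / (2 * np.pi) * n_dir
    d0 = np.floor(ud).astype(int) % n_dir
    fd = ud - np.floor(ud)
    n3 = np.zeros((n_dir,) + grid.shape)
    k3 = np.zeros((n_dir,) + grid.shape)
    base_w = np.asarray(heading.valid_mask, float)
    for dd in (0, 1):
        wd = base_w * ((1.0 - fd) if dd == 0 else fd)
        dbin = (d0 + dd) % n_dir
        for b in np.unique(dbin):
            w = np.where(dbin == b, wd, 0.0)
            if not w.any():
                continue
            c = bin_session(session, grid, weights=w)
            n3[b] += c.n
            k3[b] += c.k
    return n3, k3


@dataclass
class JointCounts:
    """3D (direction x space) masses wrapped for the shared inference code."""

    n: np.ndarray
    k: np.ndarray
    grid: GridSpec


def _pad_3d(arr: np.ndarray, p: int) -> np.ndarray:
    # pad the two spatial axes only; the direction axis is circular
    return np.pad(arr, ((0, 0), (p, p), (p, p)), mode="constant")


def fit_joint(session: Session, heading: HeadingSeries, hyper: Hyperparams,
              grid: GridSpec, n_dir: int = 24, rank_cap: int = 1000,
              keep_fraction: float = 0.0, prior_mean: float | np.ndarray | None = None,
              **fit_kwargs) -> tuple[VariationalState, PriorSpec]:
    """Joint 2D + head-direction variational fit.

    The prior is the separable product of the PSD-clipped squared-cosine
    direction kernel (circular, unpadded) and the finalized spatial kernel.
    Unlike the 2D case, retention is purely by rank: the ``rank_cap``
    largest-|xi| components are kept (a relative threshold would let the
    large mean-rate variance on the spatially constant ray swamp the
    spatially structured components).
    """
    p = kernel_pad(hyper.period)
    sshape = (grid.rows + 2 * p, grid.cols + 2 * p)
    kx = make_kernel(sshape, hyper, "grid" if hyper.orientation is not None else "radial")
    kphi = direction_kernel(n_dir)
    kj = joint_kernel(kphi, kx)
    spectral = build_spectral_prior(kj.values, keep_fraction, rank_cap=rank_cap)
    n3, k3 = bin_session_3d(session, heading, grid, n_dir)
    n3p, k3p = _pad_3d(n3, p), _pad_3d(k3, p)
    if prior_mean is None:
        tot_n, tot_k = n3.sum(), k3.sum()
        prior_mean = float(np.log(max(tot_k, 1e-12) / max(tot_n, 1e-12)))
    muz = np.broadcast_to(np.asarray(prior_mean, float), spectral.shape).copy() \
        if np.ndim(prior_mean) else np.full(spectral.shape, float(prior_mean))
    prior = PriorSpec(spectral=spectral, prior_mean=muz, pad=p, hyper=hyper)
    # masses already live on the padded 3D grid; fit accepts them as-is
    state = fit(JointCounts(n=n3p, k=k3p, grid=grid), prior, **fit_kwargs)
    return state, prior


def conditional_peak_density(state: VariationalState, prior: PriorSpec,
                             n_samples: int, seed: int | None = None,
                             radius_frac: float = 1 / 2.5,
                             period: float | None = None) -> np.ndarray:
    """Per-direction peak-density maps from the joint posterior.

    Samples the 3D posterior, slices each direction bin, finds local maxima
    of each 2D slice, and accumulates the per-bin fraction of samples with
    a peak within ``radius_frac * period``; shape (n_dir, rows, cols).
    """
    if period is None:
        if prior.hyper is None:
            raise ValueError("period required")
        period = prior.hyper.period
    rng = np.random.default_rng(seed)
    sp = prior.spectral
    from .posterior import _posterior_factor
    Q = _posterior_factor(state, prior)
    disc = _disc(radius_frac * period)
    n_dir = sp.shape[0]
    acc = np.zeros(sp.shape)
    mu = state.mean_map(prior)
    chunk = 16
    for s0 in range(0, n_samples, chunk):
        m = min(chunk, n_samples - s0)
        eta = rng.standard_normal((m, sp.rank))
        z = mu[None] + expand_batch(sp, eta @ Q.T)
        for zi in z:
            for d in range(n_dir):
                pk = find_peaks(zi[d], refine=False)
                hit = np.zeros(zi[d].shape, bool)
                if pk.size:
                    hit[np.round(pk[:, 1]).astype(int),
                        np.round(pk[:, 0]).astype(int)] = True
                    hit = binary_dilation(hit, structure=disc)
                acc[d] += hit
    return acc / n_samples
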