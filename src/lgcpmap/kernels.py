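"""Positive-semidefinite prior covariance kernels for grid cells.

A kernel is stored as its spatial-domain values on the (padded) circulant
grid, origin at index ``[0, 0]`` with wrap-around displacements, so that the
unnormalized FFT of the array gives the eigenvalues of the implied circulant
covariance matrix.  Every *finalized* kernel has all eigenvalues >= 0 (made
so by clipping), even symmetry, and its maximum at zero displacement.

The hexagonal kernel is the sum of three cosine plane waves rotated pi/3
from each other; its radially averaged relative is the Bessel kernel
J0(2 pi r / P), which carries the same period structure with no preferred
orientation.  Kernels are localized to nearest-neighbor field interactions
by a hard circular window at r_c = k3 P / (2 pi) (k3 = third positive root
of J0, ~8.6537), Gaussian-blurred with sigma = P/pi to remove the window's
high-frequency ringing, and spectrally clipped back to PSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fftn, ifftn
from scipy.special import j0, jn_zeros


@dataclass(frozen=True)
class Hyperparams:
    """Kernel hyperparameters Theta = (P, sigma0^2, c, theta0).

    period : grid period P in bins.
    variance_scale : sigma0^2, marginal-variance scale of the local kernel.
    dc_offset : c, variance assigned to the mean-log-rate (DC) component.
    orientation : theta0 in radians (grid kernel only; None for radial).
    """

    period: float
    variance_scale: float = 1.0
    dc_offset: float = 0.0
    orientation: float | None = None

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.variance_scale <= 0:
            raise ValueError("variance_scale must be positive")
        if self.dc_offset < 0:
            raise ValueError("dc_offset must be nonnegative")


@dataclass
class Kernel:
    """Spatial-domain kernel on the circulant grid, origin at index [0, 0]."""

    values: np.ndarray
    period: float | None = None
    finalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def spectrum(self) -> np.ndarray:
        """Eigenvalues of the implied circulant covariance (unnormalized FFT)."""
        return np.real(fftn(self.values))


def bessel_zero(order: int, which: int) -> float:
    """The ``which``-th positive root of J_order (1-based)."""
    return float(jn_zeros(order, which)[which - 1])


K3 = bessel_zero(0, 3)  # third positive root of J0, ~8.6537


def cutoff_radius(period: float) -> float:
    """Nearest-neighbor interaction radius r_c = k3 P / (2 pi)."""
    return K3 * period / (2 * np.pi)


def kernel_pad(period: float) -> int:
    """Default padding in bins: ceil of the kernel cutoff radius."""
    return int(np.ceil(cutoff_radius(period)))


def displacements(shape: tuple[int, ...], anisotropy: tuple[float, ...] | None = None):
    """Signed wrap-around displacement grids along each axis, origin at [0,...,0]."""
    axes = []
    for i, L in enumerate(shape):
        d = (np.arange(L) + L // 2) % L - L // 2
        if anisotropy is not None:
            d = d * anisotropy[i]
        axes.append(d.astype(float))
    return np.meshgrid(*axes, indexing="ij")


def symmetrize(vals: np.ndarray) -> np.ndarray:
    """Enforce exact point symmetry K(dx) = K(-dx) on the circulant grid.

    On even-sized axes the Nyquist displacement -L/2 has no +L/2 partner, so
    a non-separable kernel evaluated pointwise can be asymmetric there by a
    sign of the function argument; averaging with the point reflection
    restores exact evenness (and hence a real spectrum).
    """
    reflected = vals[tuple(slice(None, None, -1) for _ in vals.shape)]
    reflected = np.roll(reflected, shift=[1] * vals.ndim,
                        axis=tuple(range(vals.ndim)))
    return 0.5 * (vals + reflected)


def grid_kernel(shape: tuple[int, int], period: float, orientation: float = 0.0,
                anisotropy: tuple[float, float] | None = None) -> Kernel:
    """Hexagonal (three-plane-wave) kernel with period P and orientation theta0.

    K(dx) = sum_l cos((2 pi / P)(dx1 cos(pi l/3 - theta0) - dx2 sin(pi l/3 - theta0)))
    with dx1 the x (column) and dx2 the y (row) displacement.  Invariant
    under theta0 -> theta0 + pi/3.
    """
    if period < 2:
        raise ValueError("period must be at least 2 bins (sub-Nyquist)")
    dy, dx = displacements(shape, anisotropy)
    vals = np.zeros(shape)
    for ell in range(3):
        ang = np.pi / 3 * ell - orientation
        vals += np.cos(2 * np.pi / period * (dx * np.cos(ang) - dy * np.sin(ang)))
    return Kernel(values=symmetrize(vals), period=period)


def radial_kernel(shape: tuple[int, int], period: float) -> Kernel:
    """Orientation-agnostic Bessel kernel K(r) = J0(2 pi r / P)."""
    if period < 2:
        raise ValueError("period must be at least 2 bins (sub-Nyquist)")
    dy, dx = displacements(shape)
    r = np.hypot(dx, dy)
    return Kernel(values=j0(2 * np.pi * r / period), period=period)


def radial_kernel_3d(r: np.ndarray | float, period: float) -> np.ndarray:
    """3D radial kernel sin(2 pi r/P)/(2 pi r/P) as a pure function of radius.

    Provided for completeness; volumetric inference is out of scope.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    u = 2 * np.pi * np.asarray(r, float) / period
    return np.sinc(u / np.pi)


def _gaussian_blur_circular(vals: np.ndarray, sigma: float) -> np.ndarray:
    """Circular convolution with an isotropic Gaussian (unit mass) via FFT."""
    dy, dx = displacements(vals.shape)
    g = np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
    g /= g.sum()
    return np.real(ifftn(fftn(vals) * fftn(g)))


def clip_spectrum(vals: np.ndarray) -> np.ndarray:
    """Project a (real, even) kernel onto the PSD cone by zeroing negative
    Fourier coefficients."""
    spec = np.real(fftn(vals))
    return np.real(ifftn(np.maximum(spec, 0.0)))


def localize_kernel(base: Kernel, period: float | None = None) -> Kernel:
    """Finalize a kernel: window to r <= r_c, Gaussian-blur, clip to PSD.

    The hard window uses the closed disc (the boundary is included; this is
    immaterial after blurring but stated for determinism).
    """
    P = period if period is not None else base.period
    if P is None:
        raise ValueError("period required to localize a kernel")
    rc = cutoff_radius(P)
    if rc > min(base.shape) / 2:
        raise ValueError(
            f"cutoff radius {rc:.1f} exceeds half the grid "
            f"{min(base.shape)}; increase padding or grid size")
    dy, dx = displacements(base.shape)
    r = np.hypot(dx, dy)
    windowed = base.values * (r <= rc)
    blurred = _gaussian_blur_circular(windowed, P / np.pi)
    vals = clip_spectrum(blurred)
    return Kernel(values=vals, period=P, finalized=True)


def parameterize_kernel(local: Kernel, variance_scale: float, dc_offset: float) -> Kernel:
    """K_Theta = sigma0^2 * K_local + c.

    The constant c adds ``c * M`` (M = number of bins) to the DC eigenvalue
    under this package's eigenvalue convention (unnormalized FFT of the
    kernel array); all other eigenvalues scale linearly with sigma0^2.
    """
    if variance_scale < 0 or dc_offset < 0:
        raise ValueError("variance_scale and dc_offset must be nonnegative")
    k = Kernel(values=variance_scale * local.values + dc_offset,
               period=local.period, finalized=local.finalized)
    k.meta.update(local.meta)
    return k


def make_kernel(shape: tuple[int, int], hyper: Hyperparams,
                kind: str = "grid") -> Kernel:
    """Build a finalized, parameterized kernel of the given kind.

    ``kind`` is one of 'grid' (oriented hexagonal), 'radial' (Bessel), or
    'rbf' (Gaussian with variance sigma^2 = P^2/(2 pi^2), the KDE-matched
    bandwidth).
    """
    if kind == "grid":
        base = grid_kernel(shape, hyper.period, hyper.orientation or 0.0)
        local = localize_kernel(base)
    elif kind == "radial":
        local = localize_kernel(radial_kernel(shape, hyper.period))
    elif kind == "rbf":
        dy, dx = displacements(shape)
        s2 = hyper.period**2 / (2 * np.pi**2)
        vals = np.exp(-(dx**2 + dy**2) / (2 * s2))
        local = Kernel(values=clip_spectrum(vals), period=hyper.period, finalized=True)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return parameterize_kernel(local, hyper.variance_scale, hyper.dc_offset)


def direction_kernel(n_bins: int = 24) -> np.ndarray:
    """Circular head-direction kernel from the squared-cosine window.

    Evaluates w(dphi) = max(0, cos dphi)^2 on the circular grid and clips
    negative circular-spectrum coefficients so the result is PSD.  (The raw
    squared-cosine window is not PSD; clipping changes it.)
    """
    if n_bins < 4:
        raise ValueError("need at least 4 direction bins")
    dphi = 2 * np.pi * (((np.arange(n_bins) + n_bins // 2) % n_bins - n_bins // 2)) / n_bins
    w = np.maximum(0.0, np.cos(dphi)) ** 2
    spec = np.maximum(np.real(np.fft.fft(w)), 0.0)
    return np.real(np.fft.ifft(spec))


def joint_kernel(direction: np.ndarray, spatial: Kernel) -> Kernel:
    """Separable (direction x space) kernel: outer product of the two.

    The joint spectrum is the outer product of the marginal spectra, hence
    PSD when both factors are.  The circular direction axis is not padded
    (wrap-around is correct there).
    """
    vals = np.multiply.outer(direction, spatial.values)
    return Kernel(values=vals, period=spatial.period, finalized=spatial.finalized)
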