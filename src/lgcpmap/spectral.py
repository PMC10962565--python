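"""Real-valued frequency-domain machinery.

The Hartley transform R = Re(F) + Im(F), with F the unitary discrete Fourier
transform, is real, unitary, and self-inverse.  For a real even-symmetric
circulant covariance it diagonalizes the matrix with the same (real)
eigenvalues as the Fourier transform, which lets all the linear algebra of
inference run in real arithmetic.

A :class:`SpectralPrior` holds the circulant prior's eigenvalue array xi on
the padded grid together with the retained low-rank components: frequency
components whose |xi| exceeds ``keep_fraction`` of the largest magnitude
(the DC component is always retained so the mean log-rate stays
adjustable).  The retained rows of the Hartley matrix form a semi-orthogonal
basis R~ (map-space <- coefficient-space) with R~^T R~ = I_D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fftn


def hartley(a: np.ndarray) -> np.ndarray:
    """Unitary Hartley transform (any dimensionality); self-inverse."""
    F = fftn(np.asarray(a, float), norm="ortho")
    return np.real(F) + np.imag(F)


inverse_hartley = hartley  # R is self-inverse


@dataclass
class SpectralPrior:
    """Low-rank spectral representation of a circulant prior covariance.

    xi : full eigenvalue array on the padded grid (real, >= 0).
    keep : flat indices of retained frequency components.
    xi_kept : eigenvalues of the retained components (all > 0), length D.
    """

    xi: np.ndarray
    keep: np.ndarray
    xi_kept: np.ndarray
    _row_cache: dict = field(default_factory=dict, repr=False)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.xi.shape

    @property
    def n_bins(self) -> int:
        return int(self.xi.size)

    @property
    def rank(self) -> int:
        return int(self.keep.size)

    @property
    def prior_marginal_variance(self) -> float:
        """Per-bin marginal variance of the full prior, (1/M) sum(xi) = K(0)."""
        return float(np.mean(self.xi))


def build_spectral_prior(kernel_values: np.ndarray, keep_fraction: float = 0.1,
                         rank_cap: int | None = None) -> SpectralPrior:
    """Eigendecompose a finalized circulant kernel and retain the top components.

    Retains components with |xi_m| > keep_fraction * |xi_max| (strict), the
    DC component unconditionally, and at most ``rank_cap`` components (kept
    by decreasing |xi|) when a cap is given.
    """
    xi = np.real(fftn(np.asarray(kernel_values, float)))
    xi = np.maximum(xi, 0.0)  # finalized kernels are PSD up to roundoff
    if np.abs(xi).max() <= 0:
        raise ValueError("kernel has an all-zero spectrum")
    flat = xi.ravel()
    # The DC eigenvalue carries the mean-log-rate variance c, which can be
    # orders of magnitude above the structured spectrum; it is retained
    # unconditionally and excluded from the threshold reference so the
    # spatially structured components survive.
    ximax = np.abs(flat[1:]).max() if flat.size > 1 else np.abs(flat[0])
    if ximax <= 0:
        ximax = np.abs(flat[0])
    keep = np.flatnonzero(np.abs(flat) > keep_fraction * ximax)
    if 0 not in keep:
        keep = np.concatenate([[0], keep])
    if rank_cap is not None and keep.size > rank_cap:
        order = np.argsort(np.abs(flat[keep]))[::-1][:rank_cap]
        keep = keep[np.sort(order)]
        keep = np.unique(np.concatenate([[0], keep]))
    keep = np.sort(keep)
    xi_kept = flat[keep]
    if np.any(xi_kept <= 0):
        raise ValueError("retained eigenvalues must be strictly positive")
    return SpectralPrior(xi=xi, keep=keep, xi_kept=xi_kept)


def circulant_apply(prior: SpectralPrior, v: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Apply Sigma_z (or its inverse restricted to the retained subspace).

    Pointwise multiplication of Hartley coefficients by xi, or by 1/xi~ on
    the retained components and zero elsewhere when ``inverse`` is set.
    """
    c = hartley(v).ravel()
    if inverse:
        if np.any(prior.xi_kept <= 0):
            raise ZeroDivisionError("prior is singular on the retained subspace")
        out = np.zeros_like(c)
        out[prior.keep] = c[prior.keep] / prior.xi_kept
    else:
        out = c * prior.xi.ravel()
    return inverse_hartley(out.reshape(prior.shape))


def project(prior: SpectralPrior, v: np.ndarray) -> np.ndarray:
    """R~^T v: map-space -> retained coefficient space (length D)."""
    return hartley(v).ravel()[prior.keep]


def expand(prior: SpectralPrior, c: np.ndarray) -> np.ndarray:
    """R~ c: retained coefficients -> map space.  expand(project(.)) is the
    orthogonal projector onto the retained subspace."""
    full = np.zeros(prior.n_bins)
    full[prior.keep] = c
    return inverse_hartley(full.reshape(prior.shape))


def expand_batch(prior: SpectralPrior, C: np.ndarray) -> np.ndarray:
    """Expand many coefficient vectors at once: (S, D) -> (S, *shape)."""
    S = C.shape[0]
    full = np.zeros((S, prior.n_bins))
    full[:, prior.keep] = C
    F = fftn(full.reshape((S,) + prior.shape), axes=tuple(range(1, 1 + len(prior.shape))),
             norm="ortho")
    return np.real(F) + np.imag(F)


def basis_rows(prior: SpectralPrior, flat_bins: np.ndarray) -> np.ndarray:
    """Rows of the retained Hartley basis R~ at the given (flat) map bins.

    Entry [t, d] = (cos phi - sin phi)/sqrt(M) with
    phi = 2 pi sum_axis(freq_d,axis * bin_t,axis / L_axis); computed directly
    rather than by FFT so arbitrary subsets of bins are cheap.  Results are
    cached per (id of bin set) since inference reuses the occupied-bin rows.
    """
    flat_bins = np.asarray(flat_bins)
    key = (flat_bins.tobytes(),)
    if key in prior._row_cache:
        return prior._row_cache[key]
    shape = prior.shape
    bin_idx = np.unravel_index(flat_bins, shape)
    freq_idx = np.unravel_index(prior.keep, shape)
    phi = np.zeros((flat_bins.size, prior.rank))
    for b, f, L in zip(bin_idx, freq_idx, shape):
        phi += np.outer(b.astype(float), f.astype(float)) * (2 * np.pi / L)
    rows = (np.cos(phi) - np.sin(phi)) / np.sqrt(prior.n_bins)
    prior._row_cache[key] = rows
    return rows
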