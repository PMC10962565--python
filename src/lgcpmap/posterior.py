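"""Posterior uncertainty analysis: sampling, grid-field segmentation, and
peak-location confidence ellipses.

Two complementary routes quantify where a grid field's peak is:

* sampling — draw log-rate maps from the low-rank posterior, find each
  sample's local maxima, and summarize the per-field scatter;
* locally quadratic — Taylor-expand the posterior mean around a peak; a
  perturbation with gradient J at the peak shifts it by
  dx = -H^{-1} J, so the peak-location covariance is
  Sigma_dx = H^{-1} grad(R~ Q) (grad(R~ Q))^T H^{-1}
  with H the mean's Hessian and Q a Cholesky factor of the low-rank
  posterior covariance.

The two agree for well-localized peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.ndimage import binary_dilation
from scipy.stats import chi2

from .inference import PriorSpec, VariationalState
from .spectral import basis_rows, expand_batch


@dataclass
class FieldPeak:
    """A grid-field peak with its local curvature and location uncertainty.

    location : (x, y) in bins on the padded grid, sub-bin refined.
    hessian : 2x2 curvature of the posterior mean log-rate at the peak
        (negative definite for a genuine maximum).
    peak_cov : 2x2 covariance Sigma_dx of the peak location.
    ellipse : (semi_major, semi_minor, angle) at ``level`` confidence.
    level : confidence level of the ellipse.
    """

    location: np.ndarray
    hessian: np.ndarray
    peak_cov: np.ndarray
    ellipse: tuple[float, float, float]
    level: float = 0.95


def _posterior_factor(state: VariationalState, prior: PriorSpec) -> np.ndarray:
    """Q = L^{-T} with Lambda = L L^T, so Sigma~ = Q Q^T in coefficient space."""
    sp = prior.spectral
    if state.chol is None:
        return np.diag(np.sqrt(sp.xi_kept))
    Linv = solve_triangular(state.chol, np.eye(sp.rank), lower=True)
    return Linv.T


def sample_posterior(state: VariationalState, prior: PriorSpec, n_samples: int,
                     seed: int | None = None) -> np.ndarray:
    """Draw log-rate maps z = mu + R~ (L^{-T} eta) from the variational
    posterior; shape (n_samples, *padded grid).  With q = 0 these are draws
    from the (low-rank) prior."""
    rng = np.random.default_rng(seed)
    sp = prior.spectral
    Q = _posterior_factor(state, prior)
    eta = rng.standard_normal((n_samples, sp.rank))
    dev = expand_batch(sp, eta @ Q.T)
    return state.mean_map(prior)[None] + dev


def find_peaks(vmap: np.ndarray, exclude_border: int = 0,
               refine: bool = True) -> np.ndarray:
    """Strict 8-neighbor local maxima, optionally sub-bin refined by 2D
    quadratic interpolation.  Returns (n_peaks, 2) array of (x, y)."""
    v = np.asarray(vmap, float)
    strict = np.zeros(v.shape, bool)
    core = v[1:-1, 1:-1]
    ok = np.ones(core.shape, bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == dx == 0:
                continue
            ok &= core > v[1 + dy:v.shape[0] - 1 + dy, 1 + dx:v.shape[1] - 1 + dx]
    strict[1:-1, 1:-1] = ok
    if exclude_border > 0:
        b = exclude_border
        keepmask = np.zeros_like(strict)
        keepmask[b:v.shape[0] - b, b:v.shape[1] - b] = True
        strict &= keepmask
    ys, xs = np.nonzero(strict)
    peaks = []
    for y, x in zip(ys, xs):
        px, py = float(x), float(y)
        if refine:
            dx_num = 0.5 * (v[y, x - 1] - v[y, x + 1])
            dx_den = v[y, x - 1] - 2 * v[y, x] + v[y, x + 1]
            dy_num = 0.5 * (v[y - 1, x] - v[y + 1, x])
            dy_den = v[y - 1, x] - 2 * v[y, x] + v[y + 1, x]
            if dx_den < 0:
                px += float(np.clip(dx_num / dx_den, -0.5, 0.5))
            if dy_den < 0:
                py += float(np.clip(dy_num / dy_den, -0.5, 0.5))
        peaks.append((px, py))
    return np.array(peaks).reshape(-1, 2)


def _disc(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy**2 + xx**2) <= radius**2


def peak_density(samples: np.ndarray, period: float,
                 radius_frac: float = 0.5, exclude_border: int = 0) -> np.ndarray:
    """Per-bin fraction of posterior samples with a local maximum within
    ``radius_frac * period`` of that bin; values in [0, 1]."""
    if samples.ndim != 3 or samples.shape[0] < 1:
        raise ValueError("need a (n_samples, rows, cols) stack")
    disc = _disc(radius_frac * period)
    acc = np.zeros(samples.shape[1:])
    for s in samples:
        pk = find_peaks(s, exclude_border=exclude_border, refine=False)
        hit = np.zeros(s.shape, bool)
        if pk.size:
            hit[np.round(pk[:, 1]).astype(int), np.round(pk[:, 0]).astype(int)] = True
            hit = binary_dilation(hit, structure=disc)
        acc += hit
    return acc / samples.shape[0]


def segment_fields(mean_map: np.ndarray, period: float,
                   max_radius_frac: float = 0.7, exclude_border: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Voronoi segmentation of the arena by grid-field peak.

    Peaks are the strict local maxima of the posterior mean; each bin is
    labeled with the index of its nearest peak if that peak lies within
    ``max_radius_frac * period``, else -1.  Returns (labels, peaks).
    """
    peaks = find_peaks(mean_map, exclude_border=exclude_border)
    labels = np.full(mean_map.shape, -1, dtype=int)
    if peaks.shape[0] == 0:
        warnings.warn("no local maxima found; empty segmentation", RuntimeWarning)
        return labels, peaks
    yy, xx = np.indices(mean_map.shape)
    d2 = (xx[..., None] - peaks[:, 0]) ** 2 + (yy[..., None] - peaks[:, 1]) ** 2
    nearest = np.argmin(d2, axis=-1)
    dist = np.sqrt(np.take_along_axis(d2, nearest[..., None], axis=-1)[..., 0])
    labels = np.where(dist <= max_radius_frac * period, nearest, -1)
    return labels, peaks


def confidence_ellipse(cov: np.ndarray, level: float = 0.95
                       ) -> tuple[float, float, float]:
    """(semi-major, semi-minor, angle) of the ``level`` confidence ellipse of
    a 2x2 covariance: eigen-axes scaled by sqrt(chi2_2 quantile)."""
    cov = np.asarray(cov, float)
    if cov.shape != (2, 2):
        raise ValueError("cov must be 2x2")
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    if w.min() < -1e-10 * max(w.max(), 1.0):
        raise ValueError("covariance must be positive semidefinite")
    w = np.maximum(w, 0.0)
    scale = np.sqrt(chi2.ppf(level, df=2))
    order = np.argsort(w)[::-1]
    axes = scale * np.sqrt(w[order])
    angle = float(np.arctan2(V[1, order[0]], V[0, order[0]]))
    return float(axes[0]), float(axes[1]), angle


def peak_covariance_quadratic(state: VariationalState, prior: PriorSpec,
                              x0: np.ndarray, level: float = 0.95) -> FieldPeak:
    """Locally quadratic peak-location confidence region at peak ``x0``.

    The Hessian of the posterior mean comes from central finite differences
    at 1-bin spacing; the gradient rows of R~ Q at the peak come from
    central differences of the retained basis rows.  Sigma_dx = B B^T with
    B = H^{-1} grad(R~ Q).
    """
    sp = prior.spectral
    mu = state.mean_map(prior)
    x, y = int(round(x0[0])), int(round(x0[1]))
    rows, cols = mu.shape
    if not (1 <= x < cols - 1 and 1 <= y < rows - 1):
        raise ValueError("peak too close to the grid edge for finite differences")
    H = np.empty((2, 2))
    H[0, 0] = mu[y, x - 1] - 2 * mu[y, x] + mu[y, x + 1]
    H[1, 1] = mu[y - 1, x] - 2 * mu[y, x] + mu[y + 1, x]
    H[0, 1] = H[1, 0] = 0.25 * (mu[y + 1, x + 1] - mu[y + 1, x - 1]
                                - mu[y - 1, x + 1] + mu[y - 1, x - 1])
    if np.any(np.linalg.eigvalsh(H) >= 0):
        raise ValueError("Hessian not negative definite: not a genuine peak")
    # gradient rows of R~ at the peak, central differences along x and y
    def row(yy, xx):
        return basis_rows(sp, np.array([np.ravel_multi_index((yy, xx), mu.shape)]))[0]
    grad = np.vstack([0.5 * (row(y, x + 1) - row(y, x - 1)),
                      0.5 * (row(y + 1, x) - row(y - 1, x))])
    Q = _posterior_factor(state, prior)
    B = np.linalg.solve(H, grad @ Q)
    cov = B @ B.T
    return FieldPeak(location=np.asarray(x0, float), hessian=H, peak_cov=cov,
                     ellipse=confidence_ellipse(cov, level), level=level)
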