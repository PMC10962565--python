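"""Core estimators: MAP via preconditioned Newton-Krylov, and the
variational posterior via alternating mean / variance updates.

Model
-----
Per-bin log-rate z ~ N(mu_z, Sigma_z) with a circulant prior, spike counts
conditionally Poisson with per-visit rate exp(z).  After binning (visit mass
n, spike mass k) the log posterior is

    ln Pr(z | n, k) = -1/2 (z - mu_z)^T Sigma_z^{-1} (z - mu_z)
                      + z^T k - n^T e^z + const.

The variational family is Gaussian with precision Sigma^{-1} =
Sigma_z^{-1} + diag(q): a diagonal information update to the prior, which is
the exact stationary family of the evidence lower bound (ELBO).  The ELBO is
maximized by alternating Newton-Krylov steps on the mean with a fixed-point
sweep on the marginal variances v = diag(Sigma), whose self-consistency
condition is q = lambda_bar = n o exp(mu + v/2).

All computations run in the retained low-rank Hartley subspace of the
prior: the mean is stored as deviation-from-mu_z coefficients, Hessian
products use the occupied-bin basis rows, and the posterior covariance is
represented by the Cholesky factor of Lambda = diag(1/xi~) + X X^T.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.sparse.linalg import LinearOperator, minres

from .binning import BinnedCounts, pad as pad_map
from .kernels import Hyperparams
from .spectral import SpectralPrior, basis_rows, expand, expand_batch, project

log = logging.getLogger(__name__)

RATE_CEILING = 700.0  # nats; overflow guard for exp on degenerate fits


@dataclass
class PriorSpec:
    """Prior for inference: spectral covariance + mean log-rate map.

    ``prior_mean`` lives on the padded grid (same shape as the spectral
    prior); ``pad`` records the margin so results can be cropped back.
    """

    spectral: SpectralPrior
    prior_mean: np.ndarray
    pad: int = 0
    hyper: Hyperparams | None = None

    def __post_init__(self) -> None:
        self.prior_mean = np.asarray(self.prior_mean, float)
        if self.prior_mean.shape != self.spectral.shape:
            raise ValueError("prior_mean must match the spectral prior's padded shape")
        if not np.all(np.isfinite(self.prior_mean)):
            raise ValueError("prior_mean must be finite")


@dataclass
class VariationalState:
    """Low-rank variational posterior.

    mean_coeff : coefficients of (mu - mu_z) in the retained basis, length D.
    marginal_var : v = diag(Sigma) per padded bin.
    q : diagonal precision update per padded bin (q = lambda_bar at the optimum).
    expected_rate : lambda_bar = n o exp(mu + v/2) per padded bin.
    elbo : evidence lower bound in nats (additive constants omitted; the
        rank-D correction is applied so values compare across ranks).
    chol : Cholesky factor L of Lambda = diag(1/xi~) + X X^T (None while q=0).
    """

    mean_coeff: np.ndarray
    marginal_var: np.ndarray
    q: np.ndarray
    expected_rate: np.ndarray
    elbo: float = -np.inf
    chol: np.ndarray | None = None
    converged: bool = False
    n_outer: int = 0
    elbo_trace: list = field(default_factory=list)

    def mean_map(self, prior: PriorSpec) -> np.ndarray:
        """Posterior mean log-rate on the padded grid."""
        return prior.prior_mean + expand(prior.spectral, self.mean_coeff)

    def rate_map(self, prior: PriorSpec) -> np.ndarray:
        """Posterior expected per-visit rate exp(mu + v/2) on the padded grid."""
        return np.exp(np.minimum(self.mean_map(prior) + 0.5 * self.marginal_var,
                                 RATE_CEILING))


def expected_rate(mu: np.ndarray, v: np.ndarray, n: np.ndarray) -> np.ndarray:
    """lambda_bar = n o exp(mu + v/2), the visit-weighted log-normal mean.

    The exponent is clipped at a ceiling (with a warning) to survive
    degenerate hyperparameters during grid search.
    """
    if np.any(np.asarray(v) < 0):
        raise ValueError("marginal variances must be nonnegative")
    expo = mu + 0.5 * v
    if np.any(expo > RATE_CEILING):
        warnings.warn("log-rate exceeded overflow ceiling; clipping", RuntimeWarning)
        expo = np.minimum(expo, RATE_CEILING)
    return n * np.exp(expo)


def _padded_counts(counts, prior: PriorSpec) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(counts.n, float)
    k = np.asarray(counts.k, float)
    if n.shape == prior.spectral.shape:  # already on the padded grid (3D joint)
        return n, k
    n = pad_map(n, prior.pad)
    k = pad_map(k, prior.pad)
    if n.shape != prior.spectral.shape:
        raise ValueError(
            f"padded counts {n.shape} do not match prior grid {prior.spectral.shape}")
    return n, k


def marginal_variance(prior: SpectralPrior, q: np.ndarray,
                      chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Marginal posterior variances v = diag[(Sigma_z^{-1} + diag q)^{-1}]
    in the retained subspace, plus the Cholesky factor of Lambda.

    Forms X = R~^T o q^{1/2} over occupied bins, Lambda = diag(xi~^{-1}) +
    X X^T, factorizes Lambda = L L^T (with jitter escalation on numerical
    indefiniteness), and returns the per-bin row sums of squares of
    R~ L^{-T} computed by batched inverse transforms.
    """
    qf = np.asarray(q, float).ravel()
    if np.any(qf < 0):
        raise ValueError("q must be nonnegative")
    D = prior.rank
    Lam = np.diag(1.0 / prior.xi_kept)
    occ = np.flatnonzero(qf > 0)
    if occ.size:
        B = basis_rows(prior, occ)
        Xw = B * np.sqrt(qf[occ])[:, None]
        Lam = Lam + Xw.T @ Xw
    jitter = 0.0
    for attempt in range(4):
        try:
            L = np.linalg.cholesky(Lam + jitter * np.eye(D))
            break
        except np.linalg.LinAlgError:
            jitter = max(10 * jitter, 1e-10 * np.trace(Lam) / D)
    else:
        raise np.linalg.LinAlgError("posterior precision not positive definite")
    Linv = solve_triangular(L, np.eye(D), lower=True)
    # columns of R~ L^{-T} are expansions of the rows of L^{-1}
    v = np.zeros(prior.n_bins)
    for s in range(0, D, chunk):
        S = expand_batch(prior, Linv[s:s + chunk])
        v += np.sum(S.reshape(S.shape[0], -1) ** 2, axis=0)
    return v.reshape(prior.shape), L


def _newton_optimize(prior: PriorSpec, n: np.ndarray, k: np.ndarray,
                     mu_t: np.ndarray, v: np.ndarray, tol: float,
                     max_iter: int, krylov_rtol: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Newton-Krylov ascent of the ELBO in the mean coefficients.

    ``v`` is held fixed (zero for the MAP problem).  Each step solves
    (diag(1/xi~) + R~^T diag(lambda_bar) R~) delta = grad with MINRES,
    preconditioned spectrally by the prior covariance, then backtracks on
    the objective.
    """
    sp = prior.spectral
    xi = sp.xi_kept
    nf, kf, vf = n.ravel(), k.ravel(), np.asarray(v, float).ravel()
    occ = np.flatnonzero(nf > 0)
    B = basis_rows(sp, occ)
    n_occ, k_occ, v_occ = nf[occ], kf[occ], vf[occ]
    muz_occ = prior.prior_mean.ravel()[occ]
    ktot = float(kf.sum())
    gtol = tol * (1.0 + ktot)

    def f_and_grad(mt):
        mu_occ = muz_occ + B @ mt
        lam = n_occ * np.exp(np.minimum(mu_occ + 0.5 * v_occ, RATE_CEILING))
        f = -0.5 * np.sum(mt**2 / xi) + k_occ @ mu_occ - lam.sum()
        g = -mt / xi + B.T @ (k_occ - lam)
        return f, g, lam

    converged = False
    f0, g, lam = f_and_grad(mu_t)
    for it in range(max_iter):
        if np.max(np.abs(g), initial=0.0) <= gtol:
            converged = True
            break
        A = LinearOperator((sp.rank, sp.rank),
                           matvec=lambda u: u / xi + B.T @ (lam * (B @ u)))
        M = LinearOperator((sp.rank, sp.rank), matvec=lambda u: u * xi)
        delta, info = minres(A, g, rtol=krylov_rtol, maxiter=10 * sp.rank, M=M)
        if info != 0:
            log.debug("MINRES returned info=%d at Newton iteration %d", info, it)
        step = 1.0
        accepted = False
        for _ in range(25):
            cand = mu_t + step * delta
            f1, g1, lam1 = f_and_grad(cand)
            if f1 >= f0 - 1e-12 * max(1.0, abs(f0)):
                gain = f1 - f0
                mu_t, f0, g, lam = cand, f1, g1, lam1
                accepted = True
                break
            step *= 0.5
        if not accepted:
            log.debug("Newton backtracking stalled at iteration %d", it)
            break
        if gain < 1e-10 * max(1.0, abs(f0)):
            # objective has plateaued at solver precision; the remaining
            # gradient is below what MINRES tolerance can reduce
            converged = np.max(np.abs(g), initial=0.0) <= 1e3 * gtol
            break
    else:
        warnings.warn("Newton-Krylov did not converge; returning best iterate",
                      RuntimeWarning)
    return mu_t, converged


def map_estimate(counts: BinnedCounts, prior: PriorSpec, tol: float = 1e-8,
                 max_iter: int = 50) -> np.ndarray:
    """MAP log-rate map z-hat on the padded grid.

    Maximizes the log posterior with Newton-Krylov in the retained subspace;
    with no data the optimum is the prior mean.
    """
    n, k = _padded_counts(counts, prior)
    mu_t = np.zeros(prior.spectral.rank)
    mu_t, _ = _newton_optimize(prior, n, k, mu_t, np.zeros_like(n), tol, max_iter)
    return prior.prior_mean + expand(prior.spectral, mu_t)


def update_mean(state: VariationalState, counts: BinnedCounts, prior: PriorSpec,
                tol: float = 1e-8, max_iter: int = 50) -> VariationalState:
    """Re-optimize the posterior mean at the current marginal variances."""
    n, k = _padded_counts(counts, prior)
    mu_t, conv = _newton_optimize(prior, n, k, state.mean_coeff.copy(),
                                  state.marginal_var, tol, max_iter)
    state.mean_coeff = mu_t
    mu = state.mean_map(prior)
    state.expected_rate = expected_rate(mu, state.marginal_var, n)
    if not conv:
        log.debug("mean update hit iteration cap")
    return state


def update_variance(state: VariationalState, counts: BinnedCounts,
                    prior: PriorSpec) -> VariationalState:
    """One fixed-point sweep v <- diag[(Sigma_z^{-1} + diag lambda_bar(v))^{-1}].

    Sets q to the current lambda_bar and recomputes marginal variances; if
    the sweep leaves the admissible band [0, prior marginal variance] the
    step is halved toward the previous iterate.
    """
    n, _ = _padded_counts(counts, prior)
    mu = state.mean_map(prior)
    lam = expected_rate(mu, state.marginal_var, n)
    q = lam.copy()
    v_new, L = marginal_variance(prior.spectral, q)
    pv = prior.spectral.prior_marginal_variance
    slack = 1e-9 * max(1.0, pv)
    if np.any(v_new < -slack) or np.any(v_new > pv + max(1e-6 * pv, slack)):
        log.debug("variance sweep left admissible band; halving step")
        v_new = 0.5 * (state.marginal_var + np.clip(v_new, 0.0, pv))
    state.q = q
    state.marginal_var = np.clip(v_new, 0.0, None)
    state.chol = L
    state.expected_rate = expected_rate(mu, state.marginal_var, n)
    return state


def elbo(state: VariationalState, counts: BinnedCounts, prior: PriorSpec) -> float:
    """Evidence lower bound in nats, evaluated in the rank-D subspace.

    L = -KL[Q || prior] + mu^T k - n^T <lambda>, with the data-independent
    ln y! terms omitted and the dimension constant taken as D (not the full
    bin count) so values are comparable across ranks.
    """
    sp = prior.spectral
    xi = sp.xi_kept
    n, k = _padded_counts(counts, prior)
    mu_t = state.mean_coeff
    quad = float(np.sum(mu_t**2 / xi))
    if state.chol is None:
        tr = float(sp.rank)
        logdet_lam = float(-np.sum(np.log(xi)))
    else:
        L = state.chol
        Linv = solve_triangular(L, np.eye(sp.rank), lower=True)
        tr = float(np.sum(Linv**2 / xi[None, :]))
        logdet_lam = float(2.0 * np.sum(np.log(np.diag(L))))
    kl = 0.5 * (quad + tr + logdet_lam + float(np.sum(np.log(xi))) - sp.rank)
    mu = state.mean_map(prior)
    lam = expected_rate(mu, state.marginal_var, n)
    occ = n.ravel() > 0
    like = float(k.ravel()[occ] @ mu.ravel()[occ] - lam.ravel()[occ].sum())
    return like - kl


def fit(counts: BinnedCounts, prior: PriorSpec, tol: float = 1e-6,
        max_outer: int = 20, init_mu: np.ndarray | None = None,
        newton_tol: float = 1e-8) -> VariationalState:
    """Full variational fit: alternate mean and variance updates to ELBO
    convergence (|delta L| < tol |L|, or ``max_outer`` sweeps).

    ``init_mu`` optionally warm-starts the posterior mean from a padded
    log-rate map (e.g. the previous hyperparameter's solution); variances
    always restart from v = 0, where the fixed-point sweep is convergent.
    """
    n, _ = _padded_counts(counts, prior)
    sp = prior.spectral
    mu_t = np.zeros(sp.rank)
    if init_mu is not None:
        mu_t = project(sp, np.asarray(init_mu, float) - prior.prior_mean)
    state = VariationalState(
        mean_coeff=mu_t,
        marginal_var=np.zeros(sp.shape),
        q=np.zeros(sp.shape),
        expected_rate=np.zeros(sp.shape),
    )
    prev = -np.inf
    for outer in range(max_outer):
        update_mean(state, counts, prior, tol=newton_tol)
        update_variance(state, counts, prior)
        state.elbo = elbo(state, counts, prior)
        state.elbo_trace.append(state.elbo)
        state.n_outer = outer + 1
        if not np.isfinite(state.elbo):
            raise FloatingPointError("ELBO became non-finite during fitting")
        if np.isfinite(prev) and abs(state.elbo - prev) <= tol * abs(state.elbo):
            state.converged = True
            break
        prev = state.elbo
    # leave the mean consistent with the final variances
    update_mean(state, counts, prior, tol=newton_tol)
    state.elbo = elbo(state, counts, prior)
    return state
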