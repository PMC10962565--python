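import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq, minimize

from lgcpmap import kernels as kn
from lgcpmap import spectral as sp
from lgcpmap.binning import BinnedCounts, GridSpec, unpad
from lgcpmap.inference import (PriorSpec, elbo, expected_rate, fit,
                               map_estimate, marginal_variance, update_mean,
                               update_variance)
from lgcpmap.posterior import find_peaks
from tests.conftest import dense_circulant


def _pd_kernel(shape, period=2.5, var=1.0, dc=0.3, floor=0.05):
    base = kn.localize_kernel(kn.radial_kernel(shape, period))
    vals = kn.parameterize_kernel(base, var, dc).values
    vals[0, 0] += floor
    return vals


def _problem(shape=(12, 12), seed=0, keep_fraction=0.0):
    rng = np.random.default_rng(seed)
    vals = _pd_kernel(shape)
    prior_s = sp.build_spectral_prior(vals, keep_fraction=keep_fraction)
    muz = np.full(shape, -1.0)
    prior = PriorSpec(spectral=prior_s, prior_mean=muz, pad=0)
    n = rng.integers(0, 5, shape).astype(float)
    k = rng.poisson(n * 0.5).astype(float)
    k[n == 0] = 0
    counts = BinnedCounts(n=n, k=k, grid=GridSpec(*shape))
    return vals, prior, counts


class _ScalarCounts:
    def __init__(self, n, k):
        self.n = np.array([[float(n)]])
        self.k = np.array([[float(k)]])


def _scalar_problem(s=1.0, muz=0.0):
    prior_s = sp.build_spectral_prior(np.array([[s]]), keep_fraction=0.0)
    return PriorSpec(spectral=prior_s, prior_mean=np.array([[muz]]), pad=0)


class TestExpectedRate:
    def test_zero_variance_is_point_estimate(self):
        mu = np.array([0.0, 1.0])
        assert np.allclose(expected_rate(mu, np.zeros(2), np.ones(2)), np.exp(mu))

    def test_lognormal_mean_closed_form(self):
        assert expected_rate(np.array([0.0]), np.array([2 * np.log(2)]),
                             np.array([1.0]))[0] == pytest.approx(2.0)

    def test_matches_monte_carlo(self, rng):
        mu, v = 0.3, 0.8
        draws = np.exp(rng.normal(mu, np.sqrt(v), 100_000))
        se = draws.std() / np.sqrt(draws.size)
        lam = expected_rate(np.array([mu]), np.array([v]), np.array([1.0]))[0]
        assert abs(lam - draws.mean()) < 3 * se

    def test_overflow_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = expected_rate(np.array([900.0]), np.zeros(1), np.ones(1))
        assert np.isfinite(out).all()


class TestMarginalVariance:
    def test_no_data_gives_prior_marginal_variance(self):
        vals = _pd_kernel((8, 8))
        prior = sp.build_spectral_prior(vals, keep_fraction=0.0)
        v, _ = marginal_variance(prior, np.zeros((8, 8)))
        dense = dense_circulant(vals)
        assert np.allclose(v.ravel(), np.diag(dense), atol=1e-10)
        assert np.allclose(v, np.mean(prior.xi))

    def test_matches_dense_inverse(self, rng):
        vals = _pd_kernel((8, 8))
        prior = sp.build_spectral_prior(vals, keep_fraction=0.0)
        q = rng.uniform(0, 3, (8, 8)) * rng.integers(0, 2, (8, 8))
        v, _ = marginal_variance(prior, q)
        dense = np.linalg.inv(np.linalg.inv(dense_circulant(vals)) + np.diag(q.ravel()))
        assert np.allclose(v.ravel(), np.diag(dense), atol=1e-9)

    def test_monotone_decreasing_in_q(self, rng):
        vals = _pd_kernel((8, 8))
        prior = sp.build_spectral_prior(vals, keep_fraction=0.0)
        q = rng.uniform(0, 1, (8, 8))
        v0, _ = marginal_variance(prior, q)
        q2 = q.copy()
        q2[3, 4] += 1.0
        v1, _ = marginal_variance(prior, q2)
        assert np.all(v1 <= v0 + 1e-12)
        assert v1[3, 4] < v0[3, 4]

    def test_negative_q_rejected(self):
        prior = sp.build_spectral_prior(_pd_kernel((8, 8)))
        with pytest.raises(ValueError):
            marginal_variance(prior, np.full((8, 8), -1.0))


class TestMapEstimate:
    def test_no_data_returns_prior_mean(self):
        _, prior, counts = _problem()
        empty = BinnedCounts(n=np.zeros((12, 12)), k=np.zeros((12, 12)),
                             grid=GridSpec(12, 12))
        zhat = map_estimate(empty, prior)
        assert np.allclose(zhat, prior.prior_mean, atol=1e-10)

    @pytest.mark.parametrize("s,muz,n,k", [(1.0, 0.0, 1.0, 1.0),
                                           (0.5, -1.0, 3.0, 2.0),
                                           (2.0, 0.5, 1.0, 0.0)])
    def test_single_bin_matches_root_finder(self, s, muz, n, k):
        # optimality condition: (z - muz)/s = k - n e^z
        prior = _scalar_problem(s, muz)
        zhat = map_estimate(_ScalarCounts(n, k), prior)[0, 0]
        root = brentq(lambda z: (z - muz) / s - (k - n * np.exp(z)), -20, 20)
        assert zhat == pytest.approx(root, abs=1e-8)

    def test_matches_dense_newton(self):
        vals, prior, counts = _problem()
        zhat = map_estimate(counts, prior)
        Sinv = np.linalg.inv(dense_circulant(vals))
        z = prior.prior_mean.ravel().copy()
        for _ in range(100):
            lam = counts.n.ravel() * np.exp(z)
            g = -Sinv @ (z - prior.prior_mean.ravel()) + counts.k.ravel() - lam
            z = z - np.linalg.solve(-Sinv - np.diag(lam), g)
        assert np.abs(zhat.ravel() - z).max() < 1e-6


class TestVariationalUpdates:
    def test_mean_update_with_zero_variance_equals_map(self):
        _, prior, counts = _problem()
        zhat = map_estimate(counts, prior)
        state = fit(counts, prior, max_outer=1)
        # rebuild a fresh state with v frozen at zero
        from lgcpmap.inference import VariationalState
        st = VariationalState(mean_coeff=np.zeros(prior.spectral.rank),
                              marginal_var=np.zeros((12, 12)),
                              q=np.zeros((12, 12)),
                              expected_rate=np.zeros((12, 12)))
        update_mean(st, counts, prior)
        assert np.allclose(st.mean_map(prior), zhat, atol=1e-7)

    def test_larger_variance_pulls_mean_down(self):
        # scalar problem: bigger v means bigger lambda_bar, smaller converged mu
        prior = _scalar_problem(1.0, 0.0)
        counts = _ScalarCounts(2.0, 3.0)
        from lgcpmap.inference import VariationalState
        mus = []
        for v in (0.0, 0.5, 1.0):
            st = VariationalState(mean_coeff=np.zeros(1),
                                  marginal_var=np.full((1, 1), v),
                                  q=np.zeros((1, 1)), expected_rate=np.zeros((1, 1)))
            update_mean(st, counts, prior)
            mus.append(st.mean_map(prior)[0, 0])
        assert mus[0] > mus[1] > mus[2]

    def test_no_data_variance_is_prior_variance(self):
        _, prior, _ = _problem()
        empty = BinnedCounts(n=np.zeros((12, 12)), k=np.zeros((12, 12)),
                             grid=GridSpec(12, 12))
        st = fit(empty, prior)
        assert np.allclose(st.marginal_var, prior.spectral.prior_marginal_variance,
                           atol=1e-9)
        assert np.allclose(st.q, 0.0)

    def test_scalar_fixed_point_matches_direct_elbo_maximization(self):
        s, muz, n, k = 1.0, 0.0, 1.0, 1.0
        prior = _scalar_problem(s, muz)
        st = fit(_ScalarCounts(n, k), prior, tol=1e-12, max_outer=200)
        mu_fit = st.mean_map(prior)[0, 0]
        v_fit = st.marginal_var[0, 0]

        def neg_elbo(p):
            mu, lv = p
            v = np.exp(lv)
            kl = 0.5 * ((mu - muz) ** 2 / s + v / s + np.log(s / v) - 1)
            return kl - (k * mu - n * np.exp(mu + v / 2))

        res = minimize(neg_elbo, [0.0, -1.0], method="Nelder-Mead",
                       options=dict(xatol=1e-12, fatol=1e-14))
        assert mu_fit == pytest.approx(res.x[0], abs=1e-4)
        assert v_fit == pytest.approx(np.exp(res.x[1]), abs=1e-4)
        assert st.elbo == pytest.approx(-res.fun, abs=1e-6)

    def test_elbo_below_quadrature_evidence_with_small_gap(self):
        s, muz, n, k = 1.0, 0.0, 1.0, 1.0
        prior = _scalar_problem(s, muz)
        st = fit(_ScalarCounts(n, k), prior, tol=1e-12, max_outer=200)
        ev, _ = quad(lambda z: np.exp(-0.5 * (z - muz) ** 2 / s)
                     / np.sqrt(2 * np.pi * s) * np.exp(k * z - n * np.exp(z)),
                     -25, 10)
        gap = np.log(ev) - st.elbo
        assert 0 < gap < 0.02

    def test_variance_iterates_stay_in_loewner_band(self):
        _, prior, counts = _problem()
        st = fit(counts, prior)
        pv = prior.spectral.prior_marginal_variance
        assert np.all(st.marginal_var >= -1e-12)
        assert np.all(st.marginal_var <= pv + 1e-9)


class TestFullFit:
    def test_matches_dense_variational_oracle(self):
        vals, prior, counts = _problem()
        st = fit(counts, prior, tol=1e-10, max_outer=100)
        Sinv = np.linalg.inv(dense_circulant(vals))
        muz = prior.prior_mean.ravel()
        z = muz.copy()
        v = np.zeros(z.size)
        for _ in range(100):
            for _ in range(50):
                lam = counts.n.ravel() * np.exp(z + v / 2)
                g = -Sinv @ (z - muz) + counts.k.ravel() - lam
                z = z - np.linalg.solve(-Sinv - np.diag(lam), g)
            lam = counts.n.ravel() * np.exp(z + v / 2)
            v = np.diag(np.linalg.inv(Sinv + np.diag(lam)))
        assert np.abs(st.mean_map(prior).ravel() - z).max() < 1e-4
        assert np.abs(st.marginal_var.ravel() - v).max() < 1e-4

    def test_elbo_monotone_over_outer_iterations(self):
        _, prior, counts = _problem(seed=3)
        st = fit(counts, prior, tol=0.0, max_outer=12)
        tr = np.array(st.elbo_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))

    def test_laplace_consistency(self, rng):
        # q built from the MAP point-rate reproduces the Laplace covariance
        vals, prior, counts = _problem(seed=5)
        zhat = map_estimate(counts, prior)
        lam_tilde = counts.n * np.exp(zhat)
        v, _ = marginal_variance(prior.spectral, lam_tilde)
        dense = np.linalg.inv(np.linalg.inv(dense_circulant(vals))
                              + np.diag(lam_tilde.ravel()))
        assert np.allclose(v.ravel(), np.diag(dense), atol=1e-8)

    def test_posterior_variance_contracts_only_near_data(self):
        # with a DC-free (purely local) kernel, bins beyond the kernel
        # support revert to the prior variance; observed bins contract
        shape = (24, 24)
        vals = _pd_kernel(shape, period=2.5, dc=0.0)
        prior_s = sp.build_spectral_prior(vals, keep_fraction=0.0)
        prior = PriorSpec(spectral=prior_s, prior_mean=np.zeros(shape), pad=0)
        n = np.zeros(shape)
        k = np.zeros(shape)
        n[2:5, 2:5] = 5.0
        k[2:5, 2:5] = 3.0
        st = fit(BinnedCounts(n=n, k=k, grid=GridSpec(*shape)), prior)
        pv = prior_s.prior_marginal_variance
        assert st.marginal_var[3, 3] < 0.5 * pv
        assert st.marginal_var[14, 14] == pytest.approx(pv, rel=5e-2)

    def test_recovers_synthetic_rate_map(self, bench_session, bench_counts, bench_fit):
        cfg, _, truth = bench_session
        state, prior, _ = bench_fit
        mu = unpad(state.mean_map(prior), prior.pad)
        mask = bench_counts.n > 0
        r = np.corrcoef(np.exp(mu[mask]), np.exp(truth[mask]))[0, 1]
        assert r > 0.8

    def test_recovers_field_locations(self, bench_session, bench_counts, bench_fit):
        # >= 90% of the *sampled* true peaks matched within P/4; fields the
        # forager never visited carry no information and are excluded
        cfg, _, truth = bench_session
        state, prior, _ = bench_fit
        mu = unpad(state.mean_map(prior), prior.pad)
        true_peaks = find_peaks(truth, exclude_border=2)
        est_peaks = find_peaks(mu, exclude_border=2)
        n = bench_counts.n
        yy, xx = np.indices(n.shape)
        tol = cfg.period_bins / 4
        matched = total = 0
        for tp in true_peaks:
            near = np.hypot(xx - tp[0], yy - tp[1]) <= cfg.period_bins / 2
            if n[near].sum() < 50:  # under a second of data near this field
                continue
            total += 1
            d = np.hypot(est_peaks[:, 0] - tp[0], est_peaks[:, 1] - tp[1]).min()
            matched += d <= tol
        assert total >= 10
        assert matched / total >= 0.9
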