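import numpy as np
import pytest

from lgcpmap import kernels as kn
from lgcpmap import spectral as sp
from lgcpmap.binning import BinnedCounts, GridSpec
from lgcpmap.inference import PriorSpec, VariationalState, fit
from lgcpmap.posterior import (confidence_ellipse, find_peaks,
                               peak_covariance_quadratic, peak_density,
                               sample_posterior, segment_fields)


@pytest.fixture(scope="module")
def fitted():
    """Small fitted posterior with localized structure."""
    rng = np.random.default_rng(42)
    shape = (32, 32)
    base = kn.localize_kernel(kn.radial_kernel(shape, 3.0))
    vals = kn.parameterize_kernel(base, 0.8, 0.2).values
    vals[0, 0] += 0.02
    prior_s = sp.build_spectral_prior(vals, keep_fraction=0.0)
    prior = PriorSpec(spectral=prior_s, prior_mean=np.full(shape, -0.5), pad=0)
    n = np.full(shape, 8.0)
    truth = 0.8 * np.cos(2 * np.pi * np.hypot(*np.indices(shape) - 16) / 6.0)
    k = rng.poisson(n * np.exp(truth - 0.5)).astype(float)
    counts = BinnedCounts(n=n, k=k, grid=GridSpec(*shape))
    state = fit(counts, prior)
    return state, prior


class TestSampling:
    def test_sample_mean_approaches_posterior_mean(self, fitted):
        state, prior = fitted
        S = 2000
        draws = sample_posterior(state, prior, S, seed=1)
        bound = 4 * np.sqrt(state.marginal_var.max() / S)
        assert np.abs(draws.mean(0) - state.mean_map(prior)).max() < bound

    def test_sample_variance_matches_marginals(self, fitted):
        state, prior = fitted
        draws = sample_posterior(state, prior, 2000, seed=2)
        sv = draws.var(0)
        # sampling error of a variance estimate ~ v * sqrt(2/S)
        tol = 5 * state.marginal_var.max() * np.sqrt(2 / 2000)
        assert np.abs(sv - state.marginal_var).max() < tol

    def test_seed_reproducibility(self, fitted):
        state, prior = fitted
        a = sample_posterior(state, prior, 3, seed=7)
        b = sample_posterior(state, prior, 3, seed=7)
        assert np.array_equal(a, b)

    def test_prior_draws_match_kernel_autocovariance(self):
        shape = (48, 48)
        base = kn.localize_kernel(kn.radial_kernel(shape, 4.0))
        vals = base.values + np.eye(1)[0, 0] * 0.0
        vals = vals.copy()
        vals[0, 0] += 0.05
        prior_s = sp.build_spectral_prior(vals, keep_fraction=0.0)
        prior = PriorSpec(spectral=prior_s, prior_mean=np.zeros(shape), pad=0)
        state = VariationalState(mean_coeff=np.zeros(prior_s.rank),
                                 marginal_var=np.zeros(shape),
                                 q=np.zeros(shape), expected_rate=np.zeros(shape))
        draws = sample_posterior(state, prior, 400, seed=3)
        # empirical autocovariance via FFT, averaged over draws
        from scipy.fft import fftn, ifftn
        acc = np.zeros(shape)
        for d in draws:
            F = fftn(d - d.mean())
            acc += np.real(ifftn(F * np.conj(F))) / d.size
        acc /= draws.shape[0]
        assert np.allclose(acc, vals, atol=0.1 * vals[0, 0])


class TestPeaks:
    def test_single_bump_density(self):
        yy, xx = np.indices((30, 30))
        bump = np.exp(-((xx - 14) ** 2 + (yy - 17) ** 2) / 20.0)
        dens = peak_density(bump[None], period=8.0, radius_frac=0.5)
        assert dens[17, 14] == 1.0
        assert dens[0, 0] == 0.0
        assert dens.min() >= 0.0 and dens.max() <= 1.0
        # density disc area ~ pi (P/2)^2 around the single interior peak
        assert dens.sum() == pytest.approx(np.pi * 16, rel=0.15)

    def test_strict_maxima_exclude_plateaus(self):
        m = np.zeros((10, 10))
        m[4:6, 4:6] = 1.0  # 2x2 plateau: no strictly greater bin
        assert find_peaks(m).shape[0] == 0

    def test_quadratic_refinement_finds_subbin_peak(self):
        yy, xx = np.indices((21, 21))
        m = -((xx - 10.3) ** 2 + (yy - 9.6) ** 2)
        pk = find_peaks(m)
        assert pk.shape[0] == 1
        assert pk[0, 0] == pytest.approx(10.3, abs=0.05)
        assert pk[0, 1] == pytest.approx(9.6, abs=0.05)


class TestSegmentation:
    def test_symmetric_two_bump_map_splits_evenly(self):
        yy, xx = np.indices((20, 40))
        m = np.exp(-((xx - 10) ** 2 + (yy - 10) ** 2) / 8.0) \
            + np.exp(-((xx - 30) ** 2 + (yy - 10) ** 2) / 8.0)
        labels, peaks = segment_fields(m, period=10.0)
        assert peaks.shape[0] == 2
        counts = [(labels == i).sum() for i in range(2)]
        assert counts[0] == counts[1]

    def test_labels_within_max_radius(self):
        yy, xx = np.indices((25, 25))
        m = np.exp(-((xx - 12) ** 2 + (yy - 12) ** 2) / 10.0)
        labels, peaks = segment_fields(m, period=6.0, max_radius_frac=0.7)
        lab = np.argwhere(labels == 0)
        d = np.hypot(lab[:, 1] - peaks[0, 0], lab[:, 0] - peaks[0, 1])
        assert d.max() <= 0.7 * 6.0 + 1e-9

    def test_fields_are_connected_on_ideal_map(self):
        from scipy.ndimage import label as cc_label
        from lgcpmap.simulate import ideal_grid_log_rate
        m = ideal_grid_log_rate(60, 12.0)
        labels, peaks = segment_fields(m, period=12.0)
        for i in range(peaks.shape[0]):
            _, ncomp = cc_label(labels == i)
            assert ncomp == 1

    def test_flat_map_warns_and_returns_empty(self):
        with pytest.warns(RuntimeWarning):
            labels, peaks = segment_fields(np.zeros((10, 10)), period=5.0)
        assert peaks.shape[0] == 0
        assert (labels == -1).all()


class TestConfidenceEllipse:
    def test_isotropic_radius_is_chi2_scaled(self):
        sigma = 0.7
        # closed-form chi-square(2) quantile: -2 ln(1 - level)
        expected = sigma * np.sqrt(-2 * np.log(0.05))
        a, b, _ = confidence_ellipse(sigma**2 * np.eye(2), 0.95)
        assert a == pytest.approx(expected, rel=1e-9)
        assert b == pytest.approx(expected, rel=1e-9)

    def test_level_zero_collapses(self):
        a, b, _ = confidence_ellipse(np.eye(2), 1e-12)
        assert a < 1e-5 and b < 1e-5

    def test_rotation_equivariance(self):
        base = np.diag([2.0, 0.5])
        for t in (0.3, 1.1):
            R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            a, b, ang = confidence_ellipse(R @ base @ R.T)
            assert a == pytest.approx(np.sqrt(2.0 * 5.991), rel=1e-2)
            assert (abs((ang - t + np.pi / 2) % np.pi - np.pi / 2) < 1e-6
                    or abs((ang - t) % np.pi) < 1e-6
                    or abs((ang - t) % np.pi - np.pi) < 1e-6)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestQuadraticPeakCovariance:
    def test_analytic_white_posterior(self):
        # posterior ~ white noise with pointwise sd c on a full-rank basis;
        # mean = -1/2 x^T A x  =>  Sigma_dx = (c^2/2) A^{-2} (central-diff
        # gradient of white noise has variance c^2/2 per axis)
        shape = (33, 33)
        delta = np.zeros(shape)
        delta[0, 0] = 1.0
        prior_s = sp.build_spectral_prior(delta, keep_fraction=0.0)
        A = np.diag([0.08, 0.02])
        yy, xx = np.indices(shape)
        quad_map = -0.5 * (A[0, 0] * (xx - 16.0) ** 2 + A[1, 1] * (yy - 16.0) ** 2)
        prior = PriorSpec(spectral=prior_s, prior_mean=quad_map, pad=0)
        c = 0.3
        L = np.eye(prior_s.rank) / c  # Lambda = I/c^2 -> Sigma = c^2 I
        state = VariationalState(mean_coeff=np.zeros(prior_s.rank),
                                 marginal_var=np.full(shape, c**2),
                                 q=np.zeros(shape), expected_rate=np.zeros(shape),
                                 chol=L)
        fp = peak_covariance_quadratic(state, prior, np.array([16.0, 16.0]))
        expected = 0.5 * c**2 * np.linalg.inv(A) @ np.linalg.inv(A)
        assert np.allclose(fp.peak_cov, expected, rtol=1e-6)
        assert np.allclose(fp.peak_cov, fp.peak_cov.T)
        assert np.all(np.linalg.eigvalsh(fp.peak_cov) >= 0)

    def test_non_peak_rejected(self, fitted):
        state, prior = fitted
        mu = state.mean_map(prior)
        trough = np.unravel_index(np.argmin(mu), mu.shape)
        with pytest.raises(ValueError):
            peak_covariance_quadratic(state, prior,
                                      np.array([trough[1], trough[0]], float))
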