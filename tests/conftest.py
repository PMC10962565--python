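import numpy as np
import pytest

from lgcpmap.binning import GridSpec, bin_session
from lgcpmap.inference import fit
from lgcpmap.kernels import Hyperparams
from lgcpmap.hyperparams import build_prior, heuristic_init
from lgcpmap.simulate import SimConfig, simulate_session


@pytest.fixture(scope="session")
def bench_session():
    """Full benchmark session: 90x90 arena, P=13 bins, 30 min at 50 Hz."""
    cfg = SimConfig(seed=101)
    session, truth = simulate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def bench_counts(bench_session):
    cfg, session, _ = bench_session
    return bin_session(session, GridSpec(cfg.grid_side, cfg.grid_side))


@pytest.fixture(scope="session")
def bench_fit(bench_session, bench_counts):
    """Variational fit on the benchmark session at heuristic hyperparameters."""
    init = heuristic_init(bench_counts)
    hyper = Hyperparams(period=init.period0, variance_scale=init.variance0,
                        dc_offset=init.dc0, orientation=init.orientation0)
    prior = build_prior(bench_counts, hyper, "grid", init.prior_mean_map)
    state = fit(bench_counts, prior)
    return state, prior, init


@pytest.fixture(scope="session")
def small_session():
    """Light session for fast functional tests: 40x40 arena, P=10, 5 min."""
    cfg = SimConfig(grid_side=40, period_bins=10.0, duration=300.0, seed=7)
    session, truth = simulate_session(cfg)
    return cfg, session, truth


def dense_circulant(kernel_values: np.ndarray) -> np.ndarray:
    """Materialize the full circulant covariance from a 2D kernel array."""
    rows, cols = kernel_values.shape
    M = rows * cols
    dense = np.empty((M, M))
    for i in range(rows):
        for j in range(cols):
            dense[i * cols + j] = np.roll(np.roll(kernel_values, i, 0), j, 1).ravel()
    return dense


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
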