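"""Simulate a grid-cell foraging session and infer its rate map.

Generates the standard synthetic benchmark (90x90-bin arena, 13-bin grid
period, 30 min of Brownian foraging at 50 Hz, 1.2 Hz mean rate), estimates
hyperparameters heuristically from the rate histogram, fits the variational
LGCP posterior, and reports how well the inferred map matches the ground
truth.
"""

import numpy as np

from lgcpmap import (GridSpec, Hyperparams, SimConfig, bin_session,
                     build_prior, fit, heuristic_init, simulate_session, unpad)

cfg = SimConfig(seed=0)
session, truth = simulate_session(cfg)
print(f"simulated {session.n_samples} samples, {session.total_spikes} spikes "
      f"({session.total_spikes / cfg.duration:.3f} Hz realized vs "
      f"{cfg.mean_rate} Hz target)")

counts = bin_session(session, GridSpec(cfg.grid_side, cfg.grid_side))
init = heuristic_init(counts)
print(f"heuristic period {init.period0:.2f} bins (true {cfg.period_bins}), "
      f"orientation {np.rad2deg(init.orientation0):.1f} deg, "
      f"sigma0^2 {init.variance0:.3f}")

hyper = Hyperparams(period=init.period0, variance_scale=init.variance0,
                    dc_offset=init.dc0, orientation=init.orientation0)
prior = build_prior(counts, hyper, "grid", init.prior_mean_map)
state = fit(counts, prior)
print(f"fit converged={state.converged} after {state.n_outer} sweeps, "
      f"ELBO {state.elbo:.1f} nats, subspace rank {prior.spectral.rank} "
      f"of {prior.spectral.n_bins} bins")

mu = unpad(state.mean_map(prior), prior.pad)
mask = counts.n > 0
r = np.corrcoef(np.exp(mu[mask]), np.exp(truth[mask]))[0, 1]
print(f"correlation of inferred vs true rate over visited bins: r = {r:.3f}")
# r above ~0.9 means the posterior mean has recovered the hexagonal map from
# half an hour of spikes; the ELBO is the evidence bound used to compare
# kernels and hyperparameters on this same data.
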