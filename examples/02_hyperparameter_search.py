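"""Select kernel hyperparameters by ELBO hill climbing.

Runs the two-stage search — (period, variance) with the orientation-agnostic
Bessel kernel, then an orientation sweep and re-climb with the hexagonal
kernel — on a shorter synthetic session, and shows that the selected period
and orientation recover the simulation's ground truth.
"""

import numpy as np

from lgcpmap import (GridSpec, SimConfig, bin_session, grid_search,
                     heuristic_init, simulate_session)

cfg = SimConfig(grid_side=48, period_bins=12.0, duration=900.0,
                mean_rate=3.0, orientation=np.deg2rad(10.0), seed=4)
session, _ = simulate_session(cfg)
counts = bin_session(session, GridSpec(cfg.grid_side, cfg.grid_side))

init = heuristic_init(counts)
print(f"heuristic start: P={init.period0:.2f} bins, "
      f"theta0={np.rad2deg(init.orientation0):.1f} deg, "
      f"sigma0^2={init.variance0:.3f}, c={init.dc0:g}")

hyper, state, trace = grid_search(counts, init, "grid", n_angles=8)
print(f"{len(trace)} posterior fits evaluated")
theta = "n/a (radial)" if hyper.orientation is None else \
    f"{np.rad2deg(hyper.orientation):.1f} deg"
print(f"best ELBO {state.elbo:.1f} nats at P={hyper.period:.2f} bins "
      f"(true {cfg.period_bins}), theta0={theta} "
      f"(true {np.rad2deg(cfg.orientation):.0f} deg), "
      f"sigma0^2={hyper.variance_scale:.3f}")
# The ELBO lower-bounds the log evidence for each kernel choice, so the
# argmax is a principled (approximate) empirical-Bayes selection of the
# grid period, orientation, and prior variance.  Period and variance are
# sharply identified; orientation has a flatter likelihood surface on short
# sessions (it tightens to a few degrees with 30 min of data).
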