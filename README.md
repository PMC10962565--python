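# lgcpmap

Variational-Bayes **log-Gaussian Cox process (LGCP) regression for grid-cell
firing-rate maps**: periodic covariance priors, a low-rank real-spectral
(Hartley) solver, ELBO-based kernel hyperparameter selection, and posterior
uncertainty for grid-field locations — with a built-in synthetic grid-cell
simulator so the whole pipeline is testable end to end without any data
download.

## Who this is for

Systems neuroscientists analyzing spatial tuning of entorhinal grid cells
(or other spatially periodic cells) from foraging sessions: time series of
2D positions and spike counts. Standard occupancy-normalized kernel
smoothers (KDEs) are noisy with limited data, carry no uncertainty, and
ignore the hexagonal periodicity that is the defining feature of these
cells. An LGCP with a periodicity-aware prior uses every field to constrain
every other field, and returns a full posterior.

## The model

Bin the session into per-bin visit mass `n` and spike mass `k` (bilinear
binning). The per-bin log rate `z` gets a Gaussian-process prior with a
stationary (circulant) covariance kernel, and spikes are conditionally
Poisson:

```
z ~ N(mu_z, Sigma_z),      ln Pr(n,k|z) = k^T z - n^T exp(z) + const.
```

Grid-cell kernels: the hexagonal kernel (sum of three plane waves rotated
60° apart, period `P`, orientation `theta0`) and its orientation-agnostic
radial average `K(r) = J0(2 pi r / P)`. Kernels are localized to
nearest-neighbor field interactions (hard window at `r_c = k3 P / 2 pi`,
`k3 ≈ 8.65` the third root of `J0`, then Gaussian blur `sigma = P/pi`) and
clipped to positive semidefinite. Scale `sigma0^2` and a DC variance `c`
complete the hyperparameters `Theta = (P, sigma0^2, c, theta0)`.

Inference is variational with a Gaussian family whose precision is a
diagonal update to the prior precision, `Sigma^{-1} = Sigma_z^{-1} +
diag(q)` — the exact stationary family of the evidence lower bound (ELBO).
The posterior mean is found by preconditioned Newton–Krylov (MINRES with
circulant matrix–vector products), the variances by the fixed-point sweep
`q <- lambda_bar = n ∘ exp(mu + v/2)`. Everything runs in the low-rank
subspace of Hartley components where the prior has non-negligible variance,
so a 90×90 arena fits in a fraction of a second. The ELBO ranks kernels and
drives a hill-climbing search over `Theta`. The posterior yields samples,
grid-field Voronoi segmentation, and per-field 95% confidence ellipses (by
sampling, or by a locally quadratic approximation
`Sigma_dx = H^{-1} ∇(R~Q) (∇(R~Q))^T H^{-1}`).

## Worked example

`python examples/01_simulate_and_fit.py` simulates the benchmark session —
a 90×90-bin arena, 13-bin grid period, 30 minutes of smoothed Brownian
foraging at 50 Hz, 1.2 Hz mean rate — and fits the grid-kernel LGCP at
heuristically initialized hyperparameters:

```
simulated 90000 samples, 2126 spikes (1.181 Hz realized vs 1.2 Hz target)
heuristic period 13.28 bins (true 13.0), orientation 1.1 deg, sigma0^2 0.216
fit converged=True after 3 sweeps, ELBO -8644.7 nats, subspace rank 203 of 16384 bins
correlation of inferred vs true rate over visited bins: r = 0.979
```

The period comes from the first secondary peak of the radial
autocorrelogram (`P = 2 pi Δp / k12`, `k12 ≈ 7.016` the second positive
root of `J1`); rank 203 of 16384 is the low-rank spectral subspace actually
used; r = 0.979 is the agreement between the posterior-mean rate map and the
simulator's ground truth. Other example scripts cover hyperparameter search
(`02`), peak confidence ellipses by both constructions (`03`), and
cross-validated comparison against matched-bandwidth KDE baselines (`04`).

A thin CLI wraps the same library calls:

```bash
lgcp simulate --seed 0 --out session.csv
lgcp fit --session session.csv --out posterior.npz
lgcp search --session session.csv --kernel grid --out theta.yaml
lgcp peaks --posterior posterior.npz --samples 1000 --seed 0 --out peaks.json
```

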