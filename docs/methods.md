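# Methods

## Model and estimators

A session is a uniformly sampled trajectory `x_t` with spike counts `y_t`.
Samples are aggregated onto a rectangular grid by bilinear ("square
pyramid") weights, giving visit mass `n` and spike mass `k` per bin; this
amounts to trapezoid-rule integration of the Poisson likelihood over space
and is the only place the binning choice enters. With an exponential rate
nonlinearity the log posterior over the per-bin log rate `z` is

    ln Pr(z|n,k) = -1/2 (z-mu_z)' Sigma_z^{-1} (z-mu_z) + k'z - n' e^z + const,

concave in `z`. The MAP estimator maximizes it by damped Newton steps; each
step solves `(Sigma_z^{-1} + diag(lambda)) delta = grad` with MINRES using
only matrix-vector products (the prior is circulant, so `Sigma_z v` is a
pointwise multiply in the spectral domain), preconditioned by `Sigma_z`.

The variational posterior is Gaussian with `Sigma^{-1} = Sigma_z^{-1} +
diag(q)`. This one-vector parameterization is exact: the stationary point
of the ELBO in a full covariance has precisely this form, with `q =
lambda_bar = n o exp(mu + v/2)` and `v = diag(Sigma)`. Fitting alternates
(1) Newton–Krylov on the mean (identical to MAP with `lambda_bar` in place
of the point rate) and (2) one fixed-point sweep `v <- diag[(Sigma_z^{-1} +
diag(lambda_bar(v)))^{-1}]`. Starting from `v = 0` and re-optimizing the
mean before each sweep, the iterates stay inside `0 <= v <= diag(Sigma_z)`
(Loewner bound on the parameterized covariance), and the ELBO is monotone
over outer iterations to float tolerance — both are asserted in the test
suite. The Laplace approximation is the same algebra with the point rate;
freezing `v = 0` reproduces MAP exactly, and the marginal-variance routine
applied to the MAP point rate reproduces the Laplace covariance diagonal.

## Spectral representation

All heavy linear algebra runs in a real spectral basis. We use the Hartley
transform `R = Re F + Im F` (`F` unitary): real, unitary, self-inverse, and
it diagonalizes real even-symmetric circulants with the same eigenvalues
`xi` as the Fourier transform. Eigenvalues are the unnormalized FFT of the
kernel array (origin at index [0,0]); under this convention the DC offset
`c` adds `c·M` to the DC eigenvalue and the prior marginal variance is
`mean(xi) = K(0)`.

The retained subspace keeps components with `|xi_m| > 0.1 |xi_ref|`. The
reference `xi_ref` is the largest **non-DC** eigenvalue and the DC
component is always retained: the DC eigenvalue carries the mean-log-rate
variance `c = 1e3`, orders of magnitude above the structured spectrum, and
a threshold referenced to it would otherwise retain nothing but the mean.
Retained basis rows are evaluated in closed form (`cas` functions), so
occupied-bin sub-blocks of `R~` are cheap; marginal variances come from a
Cholesky factor of `Lambda = diag(1/xi~) + X X'`, `X = R~' o q^{1/2}`, with
batched inverse transforms of `L^{-T}` columns (complexity `O(D^2 N + D^3)`
plus `D` FFTs). Degenerate factorizations get escalating jitter before
failing. The ELBO replaces the Gaussian dimension constant by the retained
rank `D`, so values are comparable across ranks; `ln y!` terms are dropped
throughout (they cancel in every comparison made on fixed data).

## Kernels

The hexagonal kernel is the sum of three cosine plane waves rotated pi/3
apart; the radial kernel `J0(2 pi r/P)` is its orientation average. A 3D
radial form `sinc(2r/P)` is provided as a pure function only. Localization:
hard circular window at `r_c = k3 P/(2 pi)` (closed disc; the boundary
choice is immaterial after blurring), circular Gaussian blur with
sigma = `P/pi` interpreted as a standard deviation in bins, then clipping of
negative Fourier coefficients. Clipping is a projection onto the PSD cone
and reintroduces ripples of a few percent of `K(0)` outside the window —
the support bound is exact only pre-clip (tested both ways). Kernels
evaluated pointwise on even-sized wrap grids are explicitly symmetrized:
the Nyquist displacement `-L/2` has no `+L/2` partner, and without
averaging against the point reflection a non-separable kernel is slightly
asymmetric there, making the spectrum complex. Optional per-axis scaling of
the displacement before kernel evaluation provides anisotropy control;
default isotropic.

Padding is `ceil(r_c)` bins per side, recomputed whenever `P` changes, so
circulant wrap-around cannot couple opposite walls. The head-direction
kernel is the squared-cosine window `max(0, cos Δphi)^2` clipped to PSD on
the circle (the raw window is not PSD); the joint position×direction kernel
is the separable outer product, with the circular direction axis unpadded.
For the joint prior, retention is by rank cap (default 1000 largest
components) rather than relative threshold: the spatially constant ray
inherits the large DC variance `c` and would monopolize a relative
threshold.

## Synthetic sessions

The generator emulates the standard benchmark: Brownian foraging in a
square arena (default 90×90 bins, 30 min at 50 Hz), clipped to the walls,
smoothed twice by a first-order exponential filter (tau = 190 ms,
discretized as `y_t = y_{t-1} + (1-exp(-dt/tau))(x_t - y_{t-1})`,
initialized at the first sample); an ideal hexagonal log-rate map (period
13 bins, contrast `log_amplitude = 1`, a package choice since only the mean
rate is externally constrained); an additive offset calibrating the
**trajectory-averaged** expected rate to exactly 1.2 Hz (so the expected
spike count is fixed regardless of occupancy inhomogeneity); and Poisson
counts per 20 ms sample. The walk starts at the arena center; one master
seed feeds independent substreams for trajectory and spikes. The default
diffusion is 1.0 bins²/s — i.e. a per-step displacement variance of 0.02
bins² at 50 Hz — which produces arena-scale coverage in 30 minutes; an
order-of-magnitude smaller diffusion confines the walk to a patch smaller
than one grid period and makes period recovery impossible for any
estimator.

What the generator does *not* emulate: wall-following and thigmotaxis,
theta-band rate modulation, conduction of head direction with movement
direction, spike-sorting noise, and non-Poisson dispersion. Passing tests
therefore certify the estimator under ideal Poisson sampling of a stationary
map, not robustness to these real-data features.

## Hyperparameters

Initialization: the radial autocorrelogram of the rate histogram is
computed as a masked Pearson correlation per lag (only overlapping visited
bins contribute; lags with under 20 overlaps are dropped), angle-averaged
in 1-bin rings. The first positive secondary peak at `Δp` gives `P = 2 pi
Δp / k12` with `k12 = 7.0156` — the second positive root of `J1`, which is
where `J0` has its first positive secondary peak (the first root, 3.83,
marks the negative lobe). Orientation comes from a least-squares 6-fold
sinusoid on the ring at `Δp`; the ring maxima lie along real-space lattice
directions, 30° away from the plane-wave orientation that parameterizes the
kernel, so 30° is subtracted before reducing mod 60°. A fitted 6-fold
amplitude under 0.02 (correlation units) is flagged as degenerate.
Foreground/background maps are occupancy-normalized Gaussian smoothings
(`(smooth k)/(smooth n)` with a 1e-9 floor — well-defined where the raw
histogram `k/n` is not) at `sigma_f = P/pi` and `5 sigma_f`; `mu_z = ln
background`, initial mean `ln foreground`, `sigma0^2 = var(ln fg - ln bg)`,
`c = 1e3` fixed and never searched.

Search: hill climbing on `(P, sigma0^2)` over multiplicative steps
{0.9, 1, 1.1}, refining the step toward 1.02 at each local maximum, with the
radial kernel; then an orientation sweep (default 16 angles in [0, 60°))
with the grid kernel; then a re-climb at fixed orientation. Fits warm-start
the posterior *mean* from the best state so far (projected into the new
basis); variances restart at `v = 0`, where the fixed-point sweep is
guaranteed convergent. Bounds: `P` in [4, grid/2] bins, `sigma0^2` in
[1e-3, 1e2]. An optional evaluation budget (`max_evals`) truncates the
search and returns the best `Theta` found; the heuristic `sigma0^2`
systematically underestimates (smoothing attenuates contrast), so the climb
typically walks the variance up several-fold. On 30-minute benchmark
sessions the selected period lands within a bin of truth; orientation has a
flatter ELBO surface and tightens from ~±10° (10-minute sessions) to a few
degrees (30 minutes).

## Posterior analysis

Samples are `mu + R~ L^{-T} eta` in the subspace. Peaks are strict
8-neighbor maxima with 2D quadratic sub-bin refinement; peaks inside the
padding margin are discarded. Peak-density maps count, per bin, the
fraction of samples with a peak within `P/2` (`P/2.5` for head-direction
slices). Fields are Voronoi cells of the posterior-mean peaks out to
`0.7 P`. The quadratic confidence ellipse uses central finite differences
(1-bin spacing; spectral differentiation was rejected to keep locality near
boundaries) for both the mean's Hessian `H` and the gradient rows of
`R~ Q` (`Q = L^{-T}`), giving `Sigma_dx = B B'` with `B = H^{-1} ∇(R~ Q)`;
ellipse axes scale eigenvalues by the chi-square(2) quantile. The sampling
route uses the sample covariance of matched peak locations within a field's
Voronoi region. On the benchmark session the two agree within a few percent
in axis length for well-localized fields (tested at 25%).

## Evaluation harness

KDE baselines are occupancy-normalized Gaussian smoothers; the
scale-matched bandwidth `sigma0^2 = P^2/(2 pi^2)` equates curvature at zero
lag with `J0(2 pi r/P)`, and the fine variant uses one eighth of that.
Bias/variance/accuracy curves bootstrap contiguous session blocks (15
blocks, resampled with replacement) with estimator parameters held fixed
across replicates. Cross-validation uses contiguous time folds (contiguity
avoids leakage through trajectory autocorrelation); each estimator is
re-fit per fold, hyperparameters included; predicted rates are rescaled by
one scalar so predicted total spikes match the test fold, and folds are
scored by the expected Poisson log-likelihood under the posterior (LGCP) or
the point likelihood (KDE). Explained deviance normalizes against the test
fold's mean-rate null (`lambda = <y_test>`) and the saturated model
(`lambda = y_test`, with `0 ln 0 = 0`); it may be negative for models worse
than null.

## Numerical choices and problem sizes

Newton: gradient tolerance `1e-8 (1 + total spikes)`, MINRES relative
residual 1e-6 with iteration cap `10 D`, backtracking line search, and a
stagnation break when the objective improvement falls below solver
precision. Outer loop: relative ELBO change 1e-6, max 20 sweeps. The
`exp` argument is clipped at 700 nats (warning) so degenerate
hyperparameters encountered mid-search cannot overflow. Test problem sizes
were chosen to exercise every code path at comfortable margins: dense-matrix
oracles on 8×8–16×16 grids (where the full circulant is materialized),
functional tests on 5-minute 40×40 sessions, estimator comparisons on a
30-minute 90×90 session with 10 bootstrap replicates and an 8-minute 36×36
session with 10 CV folds.

## Known limitations

Stationary kernels only: a single `Theta` describes the whole arena, so
boundary-dependent grid distortions are absorbed, not modeled. The
Poisson observation model has no over-dispersion beyond the log-Gaussian
prior. The posterior covariance is meaningful only insofar as the kernel is
a reasonable model of the true correlation structure; formal hypothesis
testing should use shuffle controls, which are out of scope here. The
variational family underestimates evidence by a small gap (about 0.01 nats
on the scalar test problem); ELBO comparisons across hyperparameters share
this bias. Volumetric (3D spatial) inference is not implemented — only the
3D radial kernel formula is exposed.
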