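# Methods

## Model

All estimators assume a linear-Gaussian generative model on a dense time
grid of step `dt` (the stimulus update interval):

```
r(t_i) = sum_{tau} f(tau) * s(t_i - tau) + noise_i
```

The response is observed only at a sparse set of exactly known times `t_i`
(one brief voxel integration per imaging frame). Because `t_i` is known to
stimulus resolution, each observation constrains the filter at every lag of
its stimulus history, and the filter is estimated on the `dt` lag grid
regardless of the sampling interval. The estimate is unbiased at any
sampling rate; sparser sampling only raises its variance (empirically and
theoretically as `N^-1/2` in the number of samples for the
cross-correlation estimator).

Key assumptions:

- The stimulus is a uniform grid; a sample at time `t` is assigned to bin
  `floor((t - t0)/dt)` (ties at bin edges round down). The binning
  convention is ours; sub-bin timing error is at most `dt/2`.
- The voxel integration window is short relative to the filter's
  timescales. Pairing treats samples as point measurements of the bin
  containing the window centre by default; overlap-weighted window
  averaging of the stimulus history is available (`integrate=True`).
- Samples whose lag window extends outside the stimulus record are dropped,
  not zero-padded, to avoid edge bias in the cross-correlation.
- Stimulus columns and responses are centred over the retained rows
  (per-column means, stored in the `PairSet`). Per-column centring makes
  noiseless OLS recovery exact at finite N.

## Estimators and numerical choices

**Cross-correlation** `c_tau = (1/N) S' r`. For a white stimulus this is
the filter scaled by the stimulus variance.

**OLS / ridge** solves `(S'S + ridge*N*I) f = S'r` by Cholesky. With
`ridge=0` a singular Gram matrix raises a conditioning error naming the
rank deficiency — never a silent fallback to regularisation.

**Discrete Laguerre basis**: closed-form discrete Laguerre functions with
decay parameter `alpha` (default 0.7), QR re-orthonormalised over the
finite lag window, signs fixed so order 0 is positive. Order `j` has
exactly `j` sign changes. The fit is OLS on `S @ B` with `n_funcs`
(default 5) coefficients; causal lag grids only.

**ASD** (automatic smoothness determination): squared-exponential prior
`C[a,b] = exp(-rho) exp(-(a-b)^2 / (2 delta^2))` over lag steps, Gaussian
observation noise `sigma2`. The three hyperparameters maximise the log
marginal likelihood; we optimise over `(log sigma2, rho, log delta)` with
Nelder–Mead (bounded by box penalties: `delta` in [0.25, 10 L] lag steps,
`rho` in [-40, 40], `sigma2` within 25 nats of the response power). Each
evidence evaluation is O(L^3) via Cholesky in the L-dimensional dual form.
Initialisation: `sigma2` = residual variance of the OLS (or ridge 0.1)
fit, prior scale from that filter's variance, `delta` = 2 lag steps.
The squared-exponential kernel is numerically near-singular for smooth
optima, so a diagonal jitter of `1e-7 * exp(-rho)` is added both inside
the evidence and for the returned posterior mean — the two paths must use
the same matrix or the posterior can be garbage at the optimum. At frozen
hyperparameters (`optimize=False`) no jitter is applied unless Cholesky
fails, so the posterior mean matches the textbook generalized-ridge
formula to machine precision. Whether a separate DC offset term belongs in
the model is unstated in the literature we follow; we centre the data
instead and fit no offset.

**Response-weighted covariance.** For a cell whose receptive-field
amplitude flips sign, the mean filter is identically zero. The second-order
statistic is

```
C = (1/N) sum_i w_i * S_i S_i' - mean(w) * (1/N) sum_i S_i S_i'
```

with weights `w_i = r_i^2` by default. Linear weighting (`w_i = r_i`) is
available but cannot recover the field of a sign-modulated cell driven by
a symmetric stimulus: `E[r * s s']` is a third moment of the stimulus and
vanishes identically (verified numerically: top-eigenvector correlation
with the true field ~0.56, i.e. chance, versus ~0.98 under squared
weighting). Squared weighting targets "stimuli that produce large
responses" of either sign. Eigenvalues are sorted by magnitude;
eigenvector signs are fixed so the largest-magnitude element is positive.

**Interpolation baseline.** `interpolated_filter` upsamples the response to
the stimulus grid (linear, nearest, PCHIP or cubic spline) and fits OLS on
the dense series over the half-open span `[t_first, t_last)` of the
samples. Interpolating at sample *bin-centre* times makes on-grid samples
reproduce exactly.

**Triangle equivalence.** Smoothing the voxel-timing OLS filter with a
unit-sum triangle of base `2 * sample_interval` reproduces the
linear-interpolation filter. As a finite-sample identity this is exact
precisely when every stimulus phase relative to the sampling comb is
visited equally often; for a generic white-noise stimulus the two sides
agree only at `O(N^-1/2)` (about 1e-3 at feasible N). The equivalence test
therefore uses a phase-balanced world: a periodic stimulus of period `P`
bins with `gcd(P, k) = 1` (`k` = samples' bin stride), `P` greater than
the lag window, a compactly supported causal filter vanishing within `k`
bins of both lag-window edges, noiseless responses, whole super-periods of
samples, and one closing sample at the phase of the first so the
interpolant covers complete cycles. Under those conditions the identity
holds to ~1e-14, and the test asserts 1e-6. This phase-balance requirement
is the same commensurability consideration that motivates choosing
stimulus and acquisition rates with no common integer multiples.

**Smoothing edges** are zero-padded: estimated filters decay to ~0 at the
window edges by construction, so padding bias is negligible away from
pathological windows.

**Prediction** (`predict`) convolves the centred stimulus with the filter
at every bin (acausal lags draw on future stimulus; incomplete histories
zero-padded); residuals for autocorrelation analysis are formed directly
from the centred `PairSet`.

## Synthetic worlds

The generator defaults restate the three canonical simulated experiments:

1. **Damped oscillation** `f(t) = (1/Z) exp(-t/tau1) sin(2 pi t/tau2)`,
   `tau1` = 100 ms, `tau2` = 50 ms, `Z` setting the mean squared value to 1;
   Gaussian white stimulus at 1 ms; response sampled for 1 ms every 100 ms;
   noise SD set by peak response / 60.
2. **Exponential** `f(t) = exp(-t/tau1)/tau1`, `tau1` = 10 steps; white
   stimulus per step; sampled every 10 steps; noiseless.
3. **Bilobed**
   `f(t) = (1 - exp(-t/tau1)) ((1/tau2) exp(-t/tau2) - (t/tau3^2) exp(-t/tau3))`,
   `tau` = 20/100/200 ms; 100 Hz stimulus; sampled 10 ms every 500 ms;
   noise SD equal to the clean response SD (SNR 1).

Filters are causal (`f(t<0) = 0`) and evaluated at bin centres
`(k + 1/2) dt`, avoiding the `t = 0` ambiguity of the sine/exponential
products. All randomness in a simulation flows from one seeded generator.

**Sign-modulated cell.** `r(t) = a(t) (f*s)(t) + noise`, `a(t)` piecewise
constant, iid ±1 per epoch (Gaussian amplitudes optional). Defaults:
20-lag filter, epoch length = filter span = sampling stride (one sample
per epoch), SD/SD SNR 1.5, 4000 samples. One-sample-per-epoch matters for
calibration: with several samples per epoch the realised mean amplitude
(~`1/sqrt(n_epochs)`) puts a coherent, filter-shaped bias in the
first-order estimate that per-sample bootstrap SEs do not see, and the
"mean filter is statistically zero" check then fails for reasons that have
nothing to do with the estimator.

**Volumetric vs plane-by-plane.** A 20-minute dense record at a 30 Hz
plane rate; 15 planes per volume, so volumetric sampling measures each
cell at 2 Hz for the whole record while plane-by-plane takes a contiguous
30 Hz block with exactly the same sample count. The true kernel is a
calcium-indicator-like double exponential (50 ms rise, 300 ms decay).
Measurement noise is added on the dense grid: white, or AR(1) with
coefficient 0.8 per 30 Hz step scaled to the same marginal SD (SD/SD
SNR 1). AR(1) at the fast rate is our model of the empirical observation
that errors in neighbouring fast samples are more correlated than errors
in neighbouring slow samples; the coefficient 0.8 gives neighbouring
plane-by-plane samples correlation 0.8 while neighbouring volumetric
samples (15 steps apart) are nearly independent (0.8^15 ~ 0.035). With
200 synthetic cells the comparison reproduces the mechanism: smoothing
(7.5 Hz zero-phase windowed sinc) and ASD reduce volumetric errors much
more than plane-by-plane errors (Cohen's d ~ +0.9 and +1.1, signed-rank
p < 1e-20), raw OLS shows no reliable difference (d ~ -0.06), and with
white noise every |d| < 0.05. This demonstrates the mechanism on synthetic
cells, not the numbers of any particular recording; 200 cells keeps the
Cohen's-d sampling SD near 0.07 so the null bounds are ~3-sigma
statements.

What a green synthetic test does **not** establish: indicator
nonlinearity, photon shot noise, bleaching dynamics beyond a single
exponential, motion, or bleed-through — none are modelled; noise is
additive Gaussian throughout.

## Uncertainty

Bootstrap SEs resample pairing rows with replacement (the rows are first
put in a canonical order so the result is invariant to row permutations)
and report per-lag bias-corrected (BC, no acceleration) 68.27% intervals;
the SE is half the interval width. Replicates on which an estimator fails
are dropped and counted. Note per-sample resampling assumes exchangeable
rows; it understates uncertainty when responses are correlated across
samples (e.g. shared slow amplitude states), which is why the
sign-modulated default world uses one sample per epoch.

## Known limitations

- The triangle/interpolation equivalence is asserted only for regular
  sampling; the irregular-interval generalisation is not implemented.
- ASD cost is O(L^3) per evidence evaluation; lag windows of several
  hundred bins are slow to optimise.
- Laguerre fitting requires purely causal lag grids.
- `selection_index` sums raw Pearson correlations over offsets; with very
  few offsets the index scale depends on the offset count.
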