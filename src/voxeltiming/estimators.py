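"""Filter estimators for voxel-timing (temporal super-resolution) analysis.

The estimators are scikit-learn style: each takes the lagged stimulus design
matrix ``X`` (rows = samples, columns = lags) and the response vector ``y``,
and exposes the fitted kernel as ``coef_``. Module-level functions wrap them
to operate directly on a :class:`~voxeltiming.core.PairSet` and return a
:class:`~voxeltiming.core.FilterEstimate`.

Estimators
----------
``CrossCorrelationFilter``
    The voxel-timing cross-correlation ``c_tau = (1/N) sum_i S[i,tau] r[i]``.
    For a white stimulus this equals the true filter scaled by the stimulus
    variance.
``LeastSquaresFilter``
    Normal-equations OLS (optionally ridge-regularised): the cross-correlation
    deconvolved by the stimulus autocorrelation.
``LaguerreFilter``
    OLS in the low-order discrete Laguerre basis — few parameters, causal,
    decaying.
``ASDFilter``
    Automatic smoothness determination: empirical-Bayes posterior mean under a
    squared-exponential smoothness prior whose hyperparameters maximise the
    marginal likelihood.
``ResponseWeightedCovariance``
    Second-order analysis (continuous-response analog of spike-triggered
    covariance): eigenvectors of the response-weighted stimulus covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .core import FilterEstimate, LagGrid, PairSet, StimulusTrace

__all__ = [
    "CrossCorrelationFilter",
    "LeastSquaresFilter",
    "LaguerreFilter",
    "ASDFilter",
    "ResponseWeightedCovariance",
    "SmoothingKernel",
    "CovarianceResult",
    "cross_correlation",
    "ols_filter",
    "interpolated_filter",
    "smooth_filter",
    "triangle_kernel",
    "gaussian_kernel",
    "lowpass_sinc_kernel",
    "delta_kernel",
    "laguerre_basis",
    "laguerre_fit",
    "asd_fit",
    "response_weighted_covariance",
    "predict",
]

INTERP_METHODS = ("linear", "nearest", "pchip", "spline")


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x lags)")
    if y.shape != (X.shape[0],):
        raise ValueError("y must be 1-D with one entry per row of X")
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    return X, y


class _FilterRegressor(RegressorMixin, BaseEstimator):
    """Base for linear kernel estimators: predict is ``X @ coef_``."""

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_


class CrossCorrelationFilter(_FilterRegressor):
    """Voxel-timing cross-correlation estimator.

    ``coef_[tau] = (1/N) sum_i X[i, tau] y[i]``. Expects centred inputs
    (as produced by :func:`voxeltiming.core.build_pairs`).
    """

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        self.coef_ = X.T @ y / X.shape[0]
        return self


class LeastSquaresFilter(_FilterRegressor):
    """Normal-equations OLS / ridge filter.

    Solves ``(X'X + ridge * N * I) coef = X'y``. With ``ridge=0`` a singular
    Gram matrix raises an informative conditioning error rather than silently
    regularising.
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        n, L = X.shape
        G = X.T @ X
        if self.ridge > 0:
            G = G + self.ridge * n * np.eye(L)
        try:
            c, low = linalg.cho_factor(G)
            self.coef_ = linalg.cho_solve((c, low), X.T @ y)
        except linalg.LinAlgError as err:
            if self.ridge == 0:
                raise np.linalg.LinAlgError(
                    f"X'X is singular (N={n} rows for L={L} lags, "
                    f"rank {np.linalg.matrix_rank(X)}); pass ridge > 0"
                ) from err
            raise
        self.n_features_in_ = L
        return self


def laguerre_basis(n_funcs: int, alpha: float, length: int) -> np.ndarray:
    """Discrete Laguerre function basis, re-orthonormalised over the window.

    Columns are the ``n_funcs`` lowest-order discrete Laguerre functions with
    decay parameter ``alpha`` evaluated on ``0..length-1``, then QR
    re-orthonormalised so that ``B.T @ B = I`` holds exactly on the finite
    window. Column ``j`` has exactly ``j`` sign changes; column 0 is a
    strictly positive decaying geometric envelope.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_funcs > length:
        raise ValueError("n_funcs cannot exceed the window length")
    n = np.arange(length)
    B = np.empty((length, n_funcs))
    for j in range(n_funcs):
        acc = np.zeros(length)
        for i in range(j + 1):
            binom_n = np.array([comb(int(m), i) for m in n], dtype=float)
            acc += (-1) ** i * binom_n * comb(j, i) * alpha ** (j - i) * (1 - alpha) ** i
        B[:, j] = alpha ** ((n - j) / 2.0) * np.sqrt(1 - alpha) * acc
    Q, R = np.linalg.qr(B)
    Q *= np.sign(np.diag(R))  # keep each column aligned with its raw version
    return Q


class LaguerreFilter(_FilterRegressor):
    """OLS fit in the discrete Laguerre basis (causal lags only).

    Fits ``y ~ (X @ B) beta`` with ``B`` the ``n_funcs`` lowest-order discrete
    Laguerre functions; the kernel is ``coef_ = B @ beta``. Drastically fewer
    parameters than lags.
    """

    def __init__(self, n_funcs: int = 5, alpha: float = 0.7):
        self.n_funcs = n_funcs
        self.alpha = alpha

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        L = X.shape[1]
        B = laguerre_basis(self.n_funcs, self.alpha, L)
        Z = X @ B
        beta = LeastSquaresFilter().fit(Z, y).coef_
        self.basis_ = B
        self.basis_coef_ = beta
        self.coef_ = B @ beta
        self.n_features_in_ = L
        return self


class ASDFilter(_FilterRegressor):
    """Automatic smoothness determination (evidence-optimised smooth prior).

    Gaussian linear model ``y = X f + noise`` with prior
    ``f ~ N(0, C)``, ``C[a, b] = exp(-rho) exp(-(a - b)^2 / (2 delta^2))``
    where ``a, b`` index lag steps. The hyperparameters ``(sigma2, rho,
    delta)`` — observation noise variance, log inverse prior scale, and
    smoothness length in lag steps — maximise the evidence (marginal
    likelihood) by Nelder-Mead on their logs; ``coef_`` is the posterior
    mean at the optimum.

    Pass explicit ``sigma2``, ``rho`` and ``delta`` with ``optimize=False``
    to compute the posterior mean at frozen hyperparameters.
    """

    def __init__(self, optimize: bool = True, sigma2: float | None = None,
                 rho: float | None = None, delta: float | None = None,
                 max_iter: int = 200, tol: float = 1e-6):
        self.optimize = optimize
        self.sigma2 = sigma2
        self.rho = rho
        self.delta = delta
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _prior_cov(L: int, rho: float, delta: float) -> np.ndarray:
        a = np.arange(L, dtype=float)
        C = np.exp(-rho) * np.exp(-((a[:, None] - a[None, :]) ** 2) / (2 * delta**2))
        return C

    @staticmethod
    def _posterior_mean(StS, Sty, sigma2, C):
        L = StS.shape[0]
        try:
            cf = linalg.cho_factor(C)
            Cinv = linalg.cho_solve(cf, np.eye(L))
        except linalg.LinAlgError:
            Cj = C + 1e-7 * np.trace(C) / L * np.eye(L)
            Cinv = linalg.cho_solve(linalg.cho_factor(Cj), np.eye(L))
        A = StS / sigma2 + Cinv
        try:
            return linalg.solve(A, Sty / sigma2, assume_a="pos")
        except linalg.LinAlgError:
            return np.linalg.lstsq(A, Sty / sigma2, rcond=None)[0]

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        n, L = X.shape
        if n < 2:
            raise ValueError("ASD needs at least 2 samples")
        StS = X.T @ X
        Sty = X.T @ y
        yty = float(y @ y)

        if not self.optimize:
            if None in (self.sigma2, self.rho, self.delta):
                raise ValueError("optimize=False requires sigma2, rho and delta")
            s2, rho, d = self.sigma2, self.rho, self.delta
            self.coef_ = self._posterior_mean(StS, Sty, s2, self._prior_cov(L, rho, d))
            self.hyperparams_ = {"sigma2": s2, "rho": rho, "delta": d}
            self.converged_ = True
            self.n_iter_ = 0
            self.n_features_in_ = L
            return self

        y_scale = max(yty / n, 1e-300)
        lo = np.array([np.log(y_scale) - 25.0, -40.0, np.log(0.25)])
        hi = np.array([np.log(y_scale) + 25.0, 40.0, np.log(10.0 * L)])

        def neg_log_evidence(theta):
            if np.any(theta < lo) or np.any(theta > hi):
                return 1e12
            ls2, rho, ld = theta
            s2 = np.exp(ls2)
            d = np.exp(ld)
            C = self._prior_cov(L, rho, d)
            C[np.diag_indices(L)] += 1e-7 * np.exp(-rho)
            try:
                cfC = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                return 1e12
            logdetC = 2.0 * np.sum(np.log(np.diag(cfC)))
            Cinv = linalg.cho_solve((cfC, True), np.eye(L))
            A = StS / s2 + Cinv
            try:
                cfA = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                return 1e12
            logdetA = 2.0 * np.sum(np.log(np.diag(cfA)))
            mu = linalg.cho_solve((cfA, True), Sty / s2)
            quad = yty / s2 - (Sty / s2) @ mu
            return 0.5 * (n * np.log(2 * np.pi * s2) + logdetC + logdetA + quad)

        # init: noise variance from a ridge (or OLS) residual, prior scale
        # from that filter's variance, smoothness 2 lag steps
        try:
            f0 = LeastSquaresFilter().fit(X, y).coef_
        except np.linalg.LinAlgError:
            f0 = LeastSquaresFilter(ridge=0.1).fit(X, y).coef_
        resid_var = max(float(np.mean((y - X @ f0) ** 2)), 1e-12 * max(yty / n, 1e-300))
        rho0 = -np.log(max(float(np.var(f0)), 1e-12))
        x0 = np.clip(np.array([np.log(resid_var), rho0, np.log(2.0)]),
                     lo + 1e-6, hi - 1e-6)
        res = optimize.minimize(
            neg_log_evidence, x0, method="Nelder-Mead",
            options={"maxiter": self.max_iter * len(x0) * 2, "maxfev": self.max_iter * len(x0) * 2,
                     "xatol": 1e-4, "fatol": self.tol},
        )
        if not res.success:
            warnings.warn("ASD evidence optimisation did not converge; "
                          "returning the best iterate", RuntimeWarning)
        ls2, rho, ld = res.x
        s2, d = float(np.exp(ls2)), float(np.exp(ld))
        # same jitter as the evidence computation: the SE prior is
        # near-singular for smooth optima and the two paths must agree
        C = self._prior_cov(L, rho, d)
        C[np.diag_indices(L)] += 1e-7 * np.exp(-rho)
        self.coef_ = self._posterior_mean(StS, Sty, s2, C)
        self.hyperparams_ = {"sigma2": s2, "rho": float(rho), "delta": d}
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.neg_log_evidence_ = float(res.fun)
        self.n_features_in_ = L
        return self


class ResponseWeightedCovariance(TransformerMixin, BaseEstimator):
    """Response-weighted stimulus covariance (STC analog for graded signals).

    Computes ``C = (1/N) sum_i w_i x_i x_i' - mean(w) * C_stim`` where
    ``C_stim`` is the unweighted stimulus covariance of the same rows and the
    weights ``w_i`` are ``y_i**2`` (default), ``|y_i|`` or ``y_i``. Squared
    weighting is the default because for a symmetric stimulus the linearly
    weighted covariance is a third moment and vanishes even for cells whose
    receptive field drives large responses of either sign.

    Fitted attributes: ``covariance_``, ``eigenvalues_`` (descending by
    magnitude), ``eigenvectors_`` (columns, unit norm, largest-magnitude
    element positive).
    """

    def __init__(self, weighting: str = "squared", subtract_baseline: bool = True):
        self.weighting = weighting
        self.subtract_baseline = subtract_baseline

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if self.weighting == "squared":
            w = y**2
        elif self.weighting == "abs":
            w = np.abs(y)
        elif self.weighting == "response":
            w = y
        else:
            raise ValueError("weighting must be 'squared', 'abs' or 'response'")
        n = X.shape[0]
        C = (X * w[:, None]).T @ X / n
        if self.subtract_baseline:
            C = C - float(w.mean()) * (X.T @ X / n)
        C = 0.5 * (C + C.T)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(-np.abs(evals))
        evals = evals[order]
        evecs = evecs[:, order]
        # fix sign: element of maximum magnitude positive
        for j in range(evecs.shape[1]):
            k = np.argmax(np.abs(evecs[:, j]))
            if evecs[k, j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.covariance_ = C
        self.eigenvalues_ = evals
        self.eigenvectors_ = evecs
        self.components_ = evecs.T
        self.n_samples_ = n
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.eigenvectors_


# ---------------------------------------------------------------------------
# smoothing kernels
# ---------------------------------------------------------------------------

@dataclass
class SmoothingKernel:
    """Unit-sum, centre-symmetric smoothing taps on the lag grid."""

    kind: str
    width: float
    taps: np.ndarray

    def __post_init__(self):
        self.taps = np.asarray(self.taps, dtype=float)
        if abs(self.taps.sum() - 1.0) > 1e-12:
            raise ValueError("taps must sum to 1")
        if len(self.taps) % 2 != 1:
            raise ValueError("taps must have odd length (symmetric about centre)")


@dataclass
class CovarianceResult:
    """Symmetric response-weighted covariance with its eigendecomposition."""

    C: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_samples: int
    meta: dict = field(default_factory=dict)


def delta_kernel() -> SmoothingKernel:
    return SmoothingKernel("delta", 0.0, np.array([1.0]))


def gaussian_kernel(sd: float, dt: float, n_sd: float = 4.0) -> SmoothingKernel:
    """Discretised Gaussian taps with standard deviation ``sd`` seconds."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    half = max(1, int(np.ceil(n_sd * sd / dt)))
    x = np.arange(-half, half + 1) * dt
    taps = np.exp(-(x**2) / (2 * sd**2))
    return SmoothingKernel("gaussian", sd, taps / taps.sum())


def triangle_kernel(sample_interval: float, dt: float) -> SmoothingKernel:
    """Triangle taps of base ``2 * sample_interval`` on the ``dt`` grid.

    Smoothing the voxel-timing filter with this kernel reproduces the filter
    obtained from a linearly interpolated response (regular sampling at
    ``sample_interval``). ``sample_interval == dt`` degenerates to a delta.
    """
    if sample_interval < dt:
        raise ValueError("sample_interval must be at least dt")
    k = int(round(sample_interval / dt))
    j = np.arange(-(k - 1), k)
    taps = (1.0 - np.abs(j) / k)
    return SmoothingKernel("triangle", sample_interval, taps / taps.sum())


def lowpass_sinc_kernel(cutoff_hz: float, dt: float, half_width: int = 10) -> SmoothingKernel:
    """Zero-phase windowed-sinc low-pass taps (Hamming window)."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    frac = cutoff_hz * dt  # cutoff as a fraction of the sampling rate
    n = np.arange(-half_width, half_width + 1)
    taps = 2 * frac * np.sinc(2 * frac * n) * np.hamming(2 * half_width + 1)
    return SmoothingKernel("lowpass_sinc", cutoff_hz, taps / taps.sum())


def smooth_filter(f: FilterEstimate, kernel: SmoothingKernel) -> FilterEstimate:
    """Convolve a filter estimate with smoothing taps (zero-padded edges)."""
    L = len(f.values)
    if len(kernel.taps) > 10 * L:
        raise ValueError("kernel is more than 10x longer than the filter")
    out = np.convolve(f.values, kernel.taps, mode="full")
    half = (len(kernel.taps) - 1) // 2
    out = out[half:half + L]
    return FilterEstimate(
        lags=f.lags, values=out, method=f.method + f"+{kernel.kind}",
        meta={**f.meta, "smoothing": kernel.kind, "smoothing_width": kernel.width},
    )


# ---------------------------------------------------------------------------
# PairSet-level wrappers
# ---------------------------------------------------------------------------

def _require_nonempty(pairs: PairSet):
    if pairs.n_kept < 1:
        raise ValueError("empty PairSet")


def cross_correlation(pairs: PairSet) -> FilterEstimate:
    """Voxel-timing cross-correlation on the stimulus-resolution lag grid."""
    _require_nonempty(pairs)
    est = CrossCorrelationFilter().fit(pairs.S, pairs.r)
    return FilterEstimate(lags=pairs.lags, values=est.coef_, method="xcorr",
                          meta={"n_samples": pairs.n_kept})


def ols_filter(pairs: PairSet, ridge: float = 0.0) -> FilterEstimate:
    """OLS (or ridge) voxel-timing filter from the normal equations."""
    _require_nonempty(pairs)
    est = LeastSquaresFilter(ridge=ridge).fit(pairs.S, pairs.r)
    method = "ols" if ridge == 0 else "ridge"
    return FilterEstimate(lags=pairs.lags, values=est.coef_, method=method,
                          meta={"ridge": ridge, "n_samples": pairs.n_kept})


def laguerre_fit(pairs: PairSet, n_funcs: int = 5, alpha: float = 0.7) -> FilterEstimate:
    """Voxel-timing filter fit in the discrete Laguerre basis (causal lags)."""
    _require_nonempty(pairs)
    if pairs.lags.n_acausal > 0:
        raise ValueError("Laguerre basis is causal; use a lag grid with tau >= 0 only")
    est = LaguerreFilter(n_funcs=n_funcs, alpha=alpha).fit(pairs.S, pairs.r)
    return FilterEstimate(
        lags=pairs.lags, values=est.coef_, method="laguerre",
        meta={"n_funcs": n_funcs, "alpha": alpha, "coef": est.basis_coef_.tolist()},
    )


def asd_fit(pairs: PairSet, **kwargs) -> FilterEstimate:
    """ASD-regularised voxel-timing filter (evidence-optimised smooth prior)."""
    _require_nonempty(pairs)
    est = ASDFilter(**kwargs).fit(pairs.S, pairs.r)
    return FilterEstimate(
        lags=pairs.lags, values=est.coef_, method="asd",
        meta={**est.hyperparams_, "converged": est.converged_},
    )


def response_weighted_covariance(pairs: PairSet, weighting: str = "squared",
                                 subtract_baseline: bool = True) -> CovarianceResult:
    """Response-weighted stimulus covariance with eigendecomposition."""
    _require_nonempty(pairs)
    est = ResponseWeightedCovariance(weighting=weighting,
                                     subtract_baseline=subtract_baseline)
    est.fit(pairs.S, pairs.r)
    return CovarianceResult(
        C=est.covariance_, eigenvalues=est.eigenvalues_,
        eigenvectors=est.eigenvectors_, n_samples=est.n_samples_,
        meta={"weighting": weighting, "subtract_baseline": subtract_baseline},
    )


def interpolated_filter(stim: StimulusTrace, samples, method: str,
                        lags: LagGrid, ridge: float = 0.0) -> FilterEstimate:
    """Baseline (resolution-limited) filter from an interpolated response.

    The sparse response is upsampled to the stimulus grid with the named
    interpolant (``linear``, ``nearest``, ``pchip`` or ``spline``), then an
    OLS filter is fitted to the dense series. Dense bins are taken on the
    half-open span ``[t_first, t_last)`` of the samples.
    """
    from scipy.interpolate import CubicSpline, PchipInterpolator, interp1d

    if method not in INTERP_METHODS:
        raise ValueError(f"unknown interpolation method {method!r}; "
                         f"choose from {INTERP_METHODS}")
    if len(samples) < 2:
        raise ValueError("interpolation needs at least 2 samples")

    first_bin = int(stim.bin_of(samples.times[0]))
    last_bin = int(stim.bin_of(samples.times[-1]))
    dense_bins = np.arange(first_bin, last_bin)  # half-open
    dense_t = stim.t0 + (dense_bins + 0.5) * stim.dt

    # interpolate as a function of the sample *bin centre* times so that
    # on-grid samples are reproduced exactly
    t_knots = stim.t0 + (stim.bin_of(samples.times) + 0.5) * stim.dt
    if method == "linear":
        f = interp1d(t_knots, samples.values, kind="linear",
                     fill_value="extrapolate", assume_sorted=True)
    elif method == "nearest":
        f = interp1d(t_knots, samples.values, kind="nearest",
                     fill_value="extrapolate", assume_sorted=True)
    elif method == "pchip":
        f = PchipInterpolator(t_knots, samples.values, extrapolate=True)
    else:
        f = CubicSpline(t_knots, samples.values, extrapolate=True)
    dense_values = np.asarray(f(dense_t), dtype=float)

    from .core import TimedSamples, build_pairs
    dense_samples = TimedSamples(times=dense_t, values=dense_values,
                                 integration_time=stim.dt)
    pairs = build_pairs(stim, dense_samples, lags)
    est = ols_filter(pairs, ridge=ridge)
    est.method = f"ols_interp:{method}"
    est.meta["interpolation"] = method
    return est


def predict(f: FilterEstimate, stim: StimulusTrace) -> np.ndarray:
    """Convolve the (centred) stimulus with a filter at every stimulus bin.

    Positive lags draw on past stimulus, negative lags on future stimulus;
    bins without complete history are zero-padded.
    """
    if stim.values.ndim != 1:
        raise ValueError("predict requires a single-channel stimulus")
    if len(f.lags) > 1 and not np.isclose(f.lags.dt, stim.dt, rtol=1e-9):
        raise ValueError("filter lag spacing must equal the stimulus dt")
    s = stim.values - stim.values.mean()
    steps = np.rint(f.lags.taus / stim.dt).astype(int)
    a = -int(steps[0])  # number of acausal steps
    full = np.convolve(s, f.values)
    out = np.zeros(stim.n_bins)
    lo = max(0, -a)
    hi = min(stim.n_bins, len(full) - a)
    out[lo:hi] = full[lo + a:hi + a]
    return out
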