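"""Filter estimators against independent brute-force oracles and known limits."""

import numpy as np
import pytest

from voxeltiming import (ASDFilter, LagGrid, StimulusTrace, TimedSamples,
                         build_pairs, cross_correlation, delta_kernel,
                         gaussian_kernel, interpolated_filter, laguerre_basis,
                         laguerre_fit, ols_filter, predict,
                         response_weighted_covariance, smooth_filter,
                         triangle_kernel)
from voxeltiming.core import FilterEstimate, PairSet
from voxeltiming.estimators import asd_fit

from conftest import phase_balanced_setup


def _toy_pairs(rng, n=10, L=3):
    S = rng.standard_normal((n, L))
    S -= S.mean(axis=0)
    r = rng.standard_normal(n)
    r -= r.mean()
    return PairSet(S=S, r=r, lags=LagGrid.from_window(1.0, n_causal=L))


class TestCrossCorrelation:
    def test_zero_response(self, rng):
        pairs = _toy_pairs(rng)
        pairs.r[:] = 0.0
        assert np.all(cross_correlation(pairs).values == 0.0)

    def test_brute_force_summation_oracle(self, rng):
        pairs = _toy_pairs(rng, n=2, L=3)
        got = cross_correlation(pairs).values
        expected = np.zeros(3)
        for tau in range(3):
            for i in range(2):
                expected[tau] += pairs.S[i, tau] * pairs.r[i]
        expected /= 2
        np.testing.assert_allclose(got, expected, atol=1e-15)

    def test_empty_pairs_error(self):
        pairs = PairSet(S=np.empty((0, 3)), r=np.empty(0),
                        lags=LagGrid.from_window(1.0, n_causal=3))
        with pytest.raises(ValueError):
            cross_correlation(pairs)


class TestOLS:
    def test_linear_algebra_oracle(self, rng):
        pairs = _toy_pairs(rng, n=8, L=3)
        got = ols_filter(pairs).values
        expected = np.linalg.inv(pairs.S.T @ pairs.S) @ pairs.S.T @ pairs.r
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_noiseless_exact_recovery(self, small_pairs):
        pairs, f_true = small_pairs
        np.testing.assert_allclose(ols_filter(pairs).values, f_true, atol=1e-10)

    def test_singular_gram_raises_conditioning_error(self, rng):
        S = np.ones((5, 3))  # rank 1
        pairs = PairSet(S=S - S.mean(0), r=rng.standard_normal(5),
                        lags=LagGrid.from_window(1.0, n_causal=3))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            ols_filter(pairs)
        ols_filter(pairs, ridge=0.1)  # ridge rescues it

    def test_ridge_matches_dense_formula(self, rng):
        pairs = _toy_pairs(rng, n=12, L=4)
        lam = 0.3
        got = ols_filter(pairs, ridge=lam).values
        n = pairs.n_kept
        expected = np.linalg.solve(pairs.S.T @ pairs.S + lam * n * np.eye(4),
                                   pairs.S.T @ pairs.r)
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_estimator_consistency_white_noiseless(rng):
    # xcorr ~ stim_variance * truth, ols = truth on white noiseless data
    L, k, N, dt = 8, 3, 5000, 0.01
    f_true = np.exp(-np.arange(L) / 3.0)
    nbins = N * k + L + 4
    s = rng.standard_normal(nbins)
    y = np.convolve(s, f_true)[:nbins]
    bins = L + k * np.arange(N)
    stim = StimulusTrace(0.0, dt, s)
    samples = TimedSamples((bins + 0.5) * dt, y[bins], dt)
    pairs = build_pairs(stim, samples, LagGrid.from_window(dt, n_causal=L))

    c = cross_correlation(pairs).values
    o = ols_filter(pairs).values
    var = pairs.S.var()
    np.testing.assert_allclose(o, f_true, atol=1e-10)
    # cross-correlation approximates var * truth (statistical, not exact)
    assert np.corrcoef(c, f_true)[0, 1] > 0.99
    assert np.abs(c / var - f_true).max() < 0.2 * np.abs(f_true).max()


class TestInterpolatedFilter:
    def test_complete_data_any_method_is_ols(self, rng):
        L, n = 5, 400
        s = rng.standard_normal(n)
        f = np.exp(-np.arange(L) / 2.0)
        y = np.convolve(s, f)[:n]
        stim = StimulusTrace(0.0, 1.0, s)
        times = np.arange(L, n - 1) + 0.5
        samples = TimedSamples(times, y[L:n - 1], 0.0)
        lags = LagGrid.from_window(1.0, n_causal=L)
        # the interpolated route spans the half-open interval [t_first, t_last),
        # so the matching OLS baseline uses every sample but the last
        base_samples = TimedSamples(times[:-1], y[L:n - 2], 0.0)
        base = ols_filter(build_pairs(stim, base_samples, lags)).values
        for method in ("linear", "nearest", "pchip", "spline"):
            got = interpolated_filter(stim, samples, method, lags).values
            np.testing.assert_allclose(got, base, atol=1e-8, err_msg=method)

    def test_unknown_method(self, rng):
        stim = StimulusTrace(0.0, 1.0, rng.standard_normal(30))
        samples = TimedSamples(np.array([10.5, 20.5]), np.array([0.0, 1.0]), 0.0)
        with pytest.raises(ValueError, match="unknown interpolation"):
            interpolated_filter(stim, samples, "bogus",
                                LagGrid.from_window(1.0, n_causal=3))

    def test_interpolation_smears_fast_filter(self):
        # exponential filter sampled every 10 steps, noiseless: the
        # interpolated filter cannot match the true fast exponential
        from voxeltiming.synthetic import fig2_experiment
        rng = np.random.default_rng(3)
        L, stride, N = 50, 10, 300
        nbins = N * stride + 2 * L
        s = rng.standard_normal(nbins)
        f = np.exp(-np.arange(L) / 10.0) / 10.0
        y = np.convolve(s, f)[:nbins]
        stim = StimulusTrace(0.0, 1.0, s)
        bins = L + stride * np.arange(N)
        samples = TimedSamples(bins + 0.5, y[bins], 0.0)
        lags = LagGrid.from_window(1.0, n_causal=L)
        voxel = ols_filter(build_pairs(stim, samples, lags)).values
        interp = interpolated_filter(stim, samples, "linear", lags).values
        assert np.abs(voxel - f).max() < 1e-8          # voxel-timing is exact
        assert np.abs(interp - f).max() > 0.2 * f.max()  # interpolation is not


class TestSmoothing:
    def test_delta_kernel_is_identity(self, rng):
        f = FilterEstimate(LagGrid.from_window(1.0, n_causal=6),
                           rng.standard_normal(6))
        np.testing.assert_array_equal(smooth_filter(f, delta_kernel()).values,
                                      f.values)

    def test_gaussian_impulse_response(self):
        L = 21
        v = np.zeros(L)
        v[10] = 1.0
        f = FilterEstimate(LagGrid.from_window(1.0, n_causal=L), v)
        kern = gaussian_kernel(1.0, 1.0)
        sm = smooth_filter(f, kern).values
        assert sm.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(sm) == 10
        np.testing.assert_allclose(sm[10 - 4:10 + 5], kern.taps, atol=1e-12)

    def test_triangle_kernel_taps(self):
        k = triangle_kernel(2.0, 1.0)
        np.testing.assert_allclose(k.taps, [0.25, 0.5, 0.25])
        assert len(triangle_kernel(1.0, 1.0).taps) == 1  # degenerate delta

    @pytest.mark.parametrize("ratio", [2, 3, 7, 11])
    def test_triangle_taps_unit_sum(self, ratio):
        assert triangle_kernel(float(ratio), 1.0).taps.sum() == pytest.approx(1.0)

    def test_triangle_below_dt_raises(self):
        with pytest.raises(ValueError):
            triangle_kernel(0.5, 1.0)


def test_triangle_equivalence_identity():
    """Smoothing the voxel-timing OLS filter with the matched triangle kernel
    reproduces the linear-interpolation OLS filter exactly on noiseless,
    regularly sampled, phase-balanced data."""
    stim, voxel, closing, lags, _ = phase_balanced_setup(P=37, k=4, L=31)
    fv = ols_filter(build_pairs(stim, voxel, lags))
    fs = smooth_filter(fv, triangle_kernel(4 * stim.dt, stim.dt))
    fi = interpolated_filter(stim, closing, "linear", lags)
    rel = np.sqrt(np.mean((fi.values - fs.values) ** 2) /
                  np.mean(fs.values ** 2))
    assert rel < 1e-6


class TestLaguerre:
    def test_orthonormal(self):
        B = laguerre_basis(5, 0.7, 100)
        np.testing.assert_allclose(B.T @ B, np.eye(5), atol=1e-10)

    def test_order0_positive_decaying(self):
        B = laguerre_basis(3, 0.6, 50)
        assert np.all(B[:, 0] > 0)
        assert np.all(np.diff(B[:, 0]) < 0)

    def test_sign_changes(self):
        B = laguerre_basis(5, 0.7, 200)
        for j in range(5):
            col = B[np.abs(B[:, j]) > 1e-12, j]
            assert np.sum(np.diff(np.sign(col)) != 0) == j

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            laguerre_basis(3, 1.2, 50)

    def test_exact_recovery_of_basis_filter(self, rng):
        # true filter inside the basis span, noiseless -> exact recovery
        L, n = 40, 400
        B = laguerre_basis(4, 0.7, L)
        f = B @ np.array([1.0, -0.5, 0.3, 0.1])
        S = rng.standard_normal((n, L))
        r = S @ f
        pairs = PairSet(S=S, r=r, lags=LagGrid.from_window(1.0, n_causal=L))
        got = laguerre_fit(pairs, n_funcs=4, alpha=0.7)
        np.testing.assert_allclose(got.values, f, atol=1e-10)

    def test_projection_oracle_near_white(self, rng):
        # with an exactly white design (S'S = n I) coefficients equal the
        # basis projection of the OLS filter
        L, n = 20, 2000
        S = rng.standard_normal((n, L))
        # exactly whiten the columns
        U, _, Vt = np.linalg.svd(S, full_matrices=False)
        S = U @ Vt * np.sqrt(n)
        r = S @ np.exp(-np.arange(L) / 5.0) + 0.1 * rng.standard_normal(n)
        pairs = PairSet(S=S, r=r, lags=LagGrid.from_window(1.0, n_causal=L))
        f_ols = ols_filter(pairs).values
        B = laguerre_basis(5, 0.7, L)
        got = laguerre_fit(pairs, n_funcs=5, alpha=0.7)
        np.testing.assert_allclose(np.asarray(got.meta["coef"]), B.T @ f_ols,
                                   atol=1e-8)

    def test_acausal_lags_rejected(self, rng):
        pairs = _toy_pairs(rng, n=10, L=4)
        pairs.lags = LagGrid.from_window(1.0, n_causal=2, n_acausal=2)
        with pytest.raises(ValueError, match="causal"):
            laguerre_fit(pairs)


class TestASD:
    def test_zero_response_gives_prior_mean(self, rng):
        pairs = _toy_pairs(rng, n=30, L=5)
        pairs.r[:] = 0.0
        got = asd_fit(pairs, optimize=False, sigma2=1.0, rho=0.0, delta=2.0)
        np.testing.assert_allclose(got.values, 0.0, atol=1e-12)

    def test_frozen_hyperparameters_generalized_ridge_oracle(self, rng):
        pairs = _toy_pairs(rng, n=50, L=12)
        s2, rho, delta = 0.5, 1.0, 2.0
        got = asd_fit(pairs, optimize=False, sigma2=s2, rho=rho, delta=delta)
        a = np.arange(12.0)
        C = np.exp(-rho) * np.exp(-((a[:, None] - a[None, :]) ** 2) / (2 * delta**2))
        expected = np.linalg.solve(pairs.S.T @ pairs.S / s2 + np.linalg.inv(C),
                                   pairs.S.T @ pairs.r / s2)
        np.testing.assert_allclose(got.values, expected, atol=1e-10)

    def test_optimized_asd_denoises(self):
        from voxeltiming.synthetic import fig3_experiment
        pairs, f_true = fig3_experiment(n_samples=400, seed=7)
        f_ols = ols_filter(pairs)
        f_asd = asd_fit(pairs)
        rms = lambda v: np.sqrt(np.mean((v - f_true.values) ** 2))
        assert rms(f_asd.values) < rms(f_ols.values)
        assert f_asd.meta["converged"]


class TestResponseWeightedCovariance:
    def test_zero_response(self, rng):
        pairs = _toy_pairs(rng, n=20, L=4)
        pairs.r[:] = 0.0
        cov = response_weighted_covariance(pairs)
        np.testing.assert_allclose(cov.C, 0.0, atol=1e-14)

    def test_brute_force_oracle(self, rng):
        pairs = _toy_pairs(rng, n=6, L=3)
        for weighting in ("squared", "abs", "response"):
            cov = response_weighted_covariance(pairs, weighting=weighting)
            w = {"squared": pairs.r**2, "abs": np.abs(pairs.r),
                 "response": pairs.r}[weighting]
            C = np.zeros((3, 3))
            C0 = np.zeros((3, 3))
            for i in range(6):
                C += w[i] * np.outer(pairs.S[i], pairs.S[i])
                C0 += np.outer(pairs.S[i], pairs.S[i])
            expected = C / 6 - w.mean() * C0 / 6
            np.testing.assert_allclose(cov.C, expected, atol=1e-12)

    def test_symmetry_and_eigen_order(self, rng):
        pairs = _toy_pairs(rng, n=50, L=6)
        cov = response_weighted_covariance(pairs)
        assert np.linalg.norm(cov.C - cov.C.T) <= 1e-10 * np.linalg.norm(cov.C)
        mags = np.abs(cov.eigenvalues)
        assert np.all(np.diff(mags) <= 1e-12)
        for j in range(6):
            assert np.linalg.norm(cov.eigenvectors[:, j]) == pytest.approx(1.0)
            k = np.argmax(np.abs(cov.eigenvectors[:, j]))
            assert cov.eigenvectors[k, j] > 0


class TestPredict:
    def test_zero_filter(self, rng):
        stim = StimulusTrace(0.0, 1.0, rng.standard_normal(20))
        f = FilterEstimate(LagGrid.from_window(1.0, n_causal=4), np.zeros(4))
        np.testing.assert_array_equal(predict(f, stim), np.zeros(20))

    def test_delta_filter_returns_centered_stimulus(self, rng):
        s = rng.standard_normal(20)
        stim = StimulusTrace(0.0, 1.0, s)
        f = FilterEstimate(LagGrid(np.array([0.0])), np.array([1.0]))
        np.testing.assert_allclose(predict(f, stim), s - s.mean(), atol=1e-14)

    def test_direct_summation_oracle(self, rng):
        s = rng.standard_normal(20)
        stim = StimulusTrace(0.0, 1.0, s)
        lags = LagGrid.from_window(1.0, n_causal=3, n_acausal=2)
        v = rng.standard_normal(5)
        f = FilterEstimate(lags, v)
        got = predict(f, stim)
        sc = s - s.mean()
        steps = [-2, -1, 0, 1, 2]
        expected = np.zeros(20)
        for m in range(20):
            for vj, st_ in zip(v, steps):
                idx = m - st_
                if 0 <= idx < 20:
                    expected[m] += vj * sc[idx]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_grid_mismatch(self, rng):
        stim = StimulusTrace(0.0, 0.5, rng.standard_normal(10))
        f = FilterEstimate(LagGrid.from_window(1.0, n_causal=3),
                           np.zeros(3))
        with pytest.raises(ValueError):
            predict(f, stim)


def test_resolution_independence(small_pairs):
    # the lag grid of a voxel-timing estimate has stimulus resolution,
    # independent of the (coarser) sampling interval
    pairs, _ = small_pairs
    for est in (cross_correlation(pairs), ols_filter(pairs)):
        assert est.lags.dt == pytest.approx(0.01)  # stimulus dt, not 0.03
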