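import numpy as np
import pytest

from voxeltiming import (LagGrid, StimulusTrace, TimedSamples, build_pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pairs(rng):
    """Small white-stimulus PairSet with a known generating filter."""
    L, k, N = 8, 3, 300
    dt = 0.01
    f = np.exp(-np.arange(L) / 3.0)
    nbins = N * k + L + 4
    s = rng.standard_normal(nbins)
    y = np.convolve(s, f)[:nbins]
    bins = L + k * np.arange(N)
    times = (bins + 0.5) * dt
    stim = StimulusTrace(0.0, dt, s)
    samples = TimedSamples(times, y[bins], dt)
    lags = LagGrid.from_window(dt, n_causal=L)
    return build_pairs(stim, samples, lags), f


def phase_balanced_setup(P=37, k=4, L=31, n_super=4, seed=0, dt=0.01):
    """Noiseless, regularly sampled data on a periodic stimulus in which every
    stimulus phase is visited equally often (gcd(P, k) = 1, whole number of
    super-periods). Returns (stim, voxel_samples, closing_samples, lags, k).

    ``closing_samples`` has one extra sample at the phase of the first so the
    linear interpolant covers whole cycles; the true filter is compactly
    supported away from the lag-window edges.
    """
    assert np.gcd(P, k) == 1
    rng = np.random.default_rng(seed)
    period = rng.standard_normal(P)
    N = n_super * P
    b0 = L
    nbins = b0 + N * k + L + 5
    s = np.tile(period, nbins // P + 1)[:nbins]
    f = np.zeros(L)
    tt = np.arange(L - 2 * k, dtype=float)
    f[k:L - k] = np.exp(-tt / 6.0) * np.sin(2 * np.pi * tt / 10.0)
    y = np.convolve(s, f)[:nbins]
    stim = StimulusTrace(0.0, dt, s)
    bins = b0 + k * np.arange(N + 1)
    times = (bins + 0.5) * dt
    voxel = TimedSamples(times[:-1], y[bins[:-1]], dt)
    closing = TimedSamples(times, y[bins], dt)
    lags = LagGrid.from_window(dt, n_causal=L)
    return stim, voxel, closing, lags, f
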