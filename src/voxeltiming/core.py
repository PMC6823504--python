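"""Domain containers and stimulus-response pairing.

The central objects are a densely and uniformly sampled stimulus
(:class:`StimulusTrace`), a set of sparse response measurements with exact
acquisition times (:class:`TimedSamples`), and the pairing of the two into a
lagged design matrix (:class:`PairSet`) on which every filter estimator
operates.

Conventions
-----------
* Stimulus bin ``b`` covers the half-open interval
  ``[t0 + b*dt, t0 + (b+1)*dt)``; a sample at time ``t`` falls in bin
  ``floor((t - t0) / dt)``, ties at bin edges rounding down.
* Positive lag ``tau`` means the stimulus *preceding* the response, so causal
  filters live at ``tau >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "StimulusTrace",
    "TimedSamples",
    "LagGrid",
    "PairSet",
    "FilterEstimate",
    "build_pairs",
    "integrate_sample_window",
]


class PairingError(ValueError):
    """Raised when no sample can be paired with a complete stimulus history."""


def _as_float_array(x, name: str, ndim=None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if ndim is not None and arr.ndim not in np.atleast_1d(ndim):
        raise ValueError(f"{name} must have ndim in {ndim}, got {arr.ndim}")
    return arr


@dataclass
class StimulusTrace:
    """Uniform-grid high-resolution signal (the "fast" variable).

    Parameters
    ----------
    t0 : float
        Time (s) of the left edge of the first bin.
    dt : float
        Bin width (s); must be positive.
    values : array, shape (n_bins,) or (n_bins, n_channels)
        Signal values, one per bin (contrast or a.u.).
    """

    t0: float
    dt: float
    values: np.ndarray
    units: str = "a.u."
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.values = _as_float_array(self.values, "values", ndim=(1, 2))
        if self.values.shape[0] < 1:
            raise ValueError("stimulus must contain at least one bin")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Bin-center times."""
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + self.n_bins * self.dt

    def bin_of(self, t) -> np.ndarray:
        """Map time(s) to bin index by flooring; no range check."""
        return np.floor((np.asarray(t, dtype=float) - self.t0) / self.dt).astype(int)

    def channel(self, c: int) -> "StimulusTrace":
        if self.values.ndim == 1:
            if c != 0:
                raise IndexError("scalar stimulus has a single channel")
            return self
        return StimulusTrace(self.t0, self.dt, self.values[:, c], self.units, dict(self.meta))


@dataclass
class TimedSamples:
    """Sparse response measurements with exact acquisition times.

    ``times`` must be strictly increasing; ``integration_time`` is the
    duration (s) each value was averaged over (0 means an instantaneous
    point sample).
    """

    times: np.ndarray
    values: np.ndarray
    integration_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times", ndim=1)
        self.values = _as_float_array(self.values, "values", ndim=1)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.integration_time < 0:
            raise ValueError("integration_time must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class LagGrid:
    """Uniformly spaced lag axis; spacing must equal the stimulus ``dt``."""

    taus: np.ndarray

    def __post_init__(self):
        self.taus = _as_float_array(self.taus, "taus", ndim=1)
        if len(self.taus) > 1:
            d = np.diff(self.taus)
            if np.any(d <= 0):
                raise ValueError("taus must be sorted ascending")
            if not np.allclose(d, d[0], rtol=1e-9, atol=0):
                raise ValueError("taus must be uniformly spaced")

    @classmethod
    def from_window(cls, dt: float, n_causal: int, n_acausal: int = 0) -> "LagGrid":
        """Build a grid of ``n_acausal`` lags with tau < 0 followed by
        ``n_causal`` lags with tau >= 0 at spacing ``dt``."""
        if n_causal < 1:
            raise ValueError("need at least one causal lag")
        return cls(np.arange(-n_acausal, n_causal) * float(dt))

    @property
    def dt(self) -> float:
        return float(self.taus[1] - self.taus[0]) if len(self.taus) > 1 else np.nan

    @property
    def n_causal(self) -> int:
        return int(np.sum(self.taus >= 0))

    @property
    def n_acausal(self) -> int:
        return int(np.sum(self.taus < 0))

    @property
    def steps(self) -> np.ndarray:
        """Lags expressed as integer bin offsets."""
        dt = self.dt if len(self.taus) > 1 else 1.0
        return np.rint(self.taus / dt).astype(int) if len(self.taus) > 1 else np.array([int(round(self.taus[0]))])

    def __len__(self) -> int:
        return len(self.taus)


@dataclass
class PairSet:
    """Aligned (stimulus-history, response) pairs: the design matrix and
    target of every estimator.

    ``S[i, j]`` holds the (mean-subtracted) stimulus in the bin containing
    ``t_i - tau_j``; ``r`` is the mean-subtracted response. The means removed
    from the retained rows are stored so predictions can be un-centered.
    """

    S: np.ndarray
    r: np.ndarray
    lags: LagGrid
    n_dropped: int = 0
    stim_mean: Union[float, np.ndarray] = 0.0  # per-lag column means
    resp_mean: float = 0.0
    sample_times: Optional[np.ndarray] = None

    @property
    def n_kept(self) -> int:
        return self.S.shape[0]

    @property
    def n_lags(self) -> int:
        return self.S.shape[1]


@dataclass
class FilterEstimate:
    """Lag-indexed kernel estimate with optional bootstrap SE band."""

    lags: LagGrid
    values: np.ndarray
    se: Optional[np.ndarray] = None
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = _as_float_array(self.values, "values", ndim=1)
        if len(self.values) != len(self.lags):
            raise ValueError("values and lag grid must have equal length")
        if self.se is not None:
            self.se = _as_float_array(self.se, "se", ndim=1)
            if self.se.shape != self.values.shape:
                raise ValueError("se must match values shape")
            if np.any(self.se < 0):
                raise ValueError("se must be non-negative")

    @property
    def dt(self) -> float:
        return self.lags.dt


def build_pairs(
    stim: StimulusTrace,
    samples: TimedSamples,
    lags: LagGrid,
    integrate: bool = False,
) -> PairSet:
    """Pair each response sample with its lagged stimulus history.

    For each retained sample ``i`` and lag ``tau``, ``S[i, tau]`` is the
    stimulus value in the bin containing ``t_i - tau``. Samples whose history
    window falls outside the stimulus record are dropped (never zero-padded)
    and counted in ``n_dropped``. Both ``S`` and ``r`` are mean-subtracted
    over the retained rows, with the removed means recorded.

    Parameters
    ----------
    integrate : bool
        If True, each design entry is the stimulus averaged over the voxel
        integration window (``samples.integration_time`` wide, centred on
        ``t_i - tau``) instead of a point sample at the window centre.
    """
    if stim.values.ndim != 1:
        raise ValueError(
            "build_pairs requires a single-channel stimulus; use "
            "StimulusTrace.channel() to select one"
        )
    if not np.isclose(lags.dt, stim.dt, rtol=1e-9) and len(lags) > 1:
        raise ValueError("lag-grid spacing must equal the stimulus dt")

    bins = stim.bin_of(samples.times)
    steps = np.rint(lags.taus / stim.dt).astype(int)
    idx = bins[:, None] - steps[None, :]
    valid = np.all((idx >= 0) & (idx < stim.n_bins), axis=1)
    n_dropped = int(np.sum(~valid))
    if not np.any(valid):
        raise PairingError("no pairable samples: every history window falls "
                           "outside the stimulus record")

    if integrate and samples.integration_time > 0:
        w = samples.integration_time
        t_hist = samples.times[valid, None] - lags.taus[None, :]
        S = _window_means(stim, t_hist, w)
    else:
        S = stim.values[idx[valid]]
    r = samples.values[valid]

    stim_mean = S.mean(axis=0)  # per-column, so every lag column is centred
    resp_mean = float(r.mean())
    return PairSet(
        S=S - stim_mean,
        r=r - resp_mean,
        lags=lags,
        n_dropped=n_dropped,
        stim_mean=stim_mean,
        resp_mean=resp_mean,
        sample_times=samples.times[valid].copy(),
    )


def _window_means(stim: StimulusTrace, t: np.ndarray, width: float) -> np.ndarray:
    """Overlap-weighted window means of the stimulus, vectorised over ``t``."""
    lo = (np.asarray(t) - width / 2.0 - stim.t0) / stim.dt
    hi = lo + width / stim.dt
    if np.any(lo < 0) or np.any(hi > stim.n_bins):
        raise ValueError("integration window extends outside the stimulus record")
    csum = np.concatenate([[0.0], np.cumsum(stim.values)])
    lo_bin = np.clip(np.floor(lo).astype(int), 0, stim.n_bins - 1)
    hi_bin = np.clip(np.ceil(hi).astype(int) - 1, 0, stim.n_bins - 1)
    total = csum[hi_bin + 1] - csum[lo_bin]
    total -= (lo - lo_bin) * stim.values[lo_bin]
    total -= (hi_bin + 1 - hi) * stim.values[hi_bin]
    return total / (hi - lo)


def integrate_sample_window(stim: StimulusTrace, t: float, width: float) -> float:
    """Overlap-weighted mean of the stimulus over ``[t - width/2, t + width/2]``.

    ``width == 0`` reduces to the value of the bin containing ``t``.
    """
    if width < 0:
        raise ValueError("width must be non-negative")
    if stim.values.ndim != 1:
        raise ValueError("integrate_sample_window requires a single-channel stimulus")
    if width == 0:
        b = int(stim.bin_of(t))
        if b < 0 or b >= stim.n_bins:
            raise ValueError("time outside the stimulus record")
        return float(stim.values[b])
    return float(_window_means(stim, np.array([[t]]), width)[0, 0])
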