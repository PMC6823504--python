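"""Synthetic experiments: stimuli, model filters, responses and sampling schemes.

Everything the estimators are validated against is generated here: Gaussian
white / binary / impulse / sparse-onset stimuli, the three model filters
(damped oscillation, exponential, bilobed), additive Gaussian noise under two
signal-to-noise conventions, the two-photon-like sampling schemes (continuous,
volumetric, plane-by-plane), and a sign-modulated model cell whose mean filter
is zero but whose second-order structure carries the receptive field.

The stated defaults reproduce three canonical simulated experiments,
packaged as :func:`fig1_experiment`, :func:`fig2_experiment` and
:func:`fig3_experiment`:

1. damped 20 Hz oscillation filter (tau1 = 100 ms, tau2 = 50 ms, unit mean
   square), 1 ms Gaussian white stimulus, response sampled for 1 ms every
   100 ms, peak/sigma SNR ~ 60;
2. exponential filter (tau = 10 steps), unit-step white stimulus, response
   sampled every 10 steps, noiseless;
3. bilobed filter (tau = 20/100/200 ms), 100 Hz stimulus, response sampled
   for 10 ms every 500 ms, SD/SD SNR = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .core import FilterEstimate, LagGrid, StimulusTrace, TimedSamples, build_pairs

__all__ = [
    "FilterSpec",
    "SamplingScheme",
    "NoiseSpec",
    "make_filter",
    "generate_stimulus",
    "simulate_response",
    "sample_scheme",
    "amplitude_modulated_cell",
    "fig1_experiment",
    "fig2_experiment",
    "fig3_experiment",
    "second_order_experiment",
    "volumetric_vs_planes_cell",
]

STIMULUS_KINDS = ("gaussian_white", "binary", "impulse_train", "sparse_onset")


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FilterSpec:
    """Parametric description of a causal model filter.

    kinds
    -----
    ``damped_osc``   ``f(t) = (1/Z) exp(-t/tau1) sin(2 pi t / tau2)``
    ``exponential``  ``f(t) = exp(-t/tau1) / tau1``
    ``bilobed``      ``f(t) = (1 - exp(-t/tau1)) *
                     ((1/tau2) exp(-t/tau2) - (t/tau3^2) exp(-t/tau3))``
    ``custom``       explicit values via ``params["values"]``

    All filters are causal (``f(t < 0) = 0``) and evaluated at bin centres
    ``t = (k + 1/2) dt``. ``normalize="unit_mean_square"`` rescales so the
    mean squared value over the window equals 1.
    """

    kind: str
    params: dict = field(default_factory=dict)
    dt: float = 1.0
    length: int = 100
    normalize: str = "none"


@dataclass
class SamplingScheme:
    """Acquisition timing for one ROI.

    ``frame_interval`` is the interval between successive measurements of the
    same voxel (inverse frame rate); ``integration_time`` the brief window a
    single measurement averages over. ``scheme`` is one of ``continuous``
    (every stimulus bin), ``volumetric`` (one sample per frame interval at
    this ROI's plane phase) or ``plane_by_plane`` (dense sampling at the
    plane rate for a contiguous block whose sample count matches the
    equivalent volumetric run).
    """

    frame_interval: float
    integration_time: float = 0.0
    phase: Union[float, str] = 0.0
    scheme: str = "volumetric"
    n_planes: int = 1
    plane_of_roi: int = 0
    n_samples: Optional[int] = None
    block_start: Union[float, str, None] = None

    def __post_init__(self):
        if self.integration_time > self.frame_interval:
            raise ValueError("integration_time must not exceed frame_interval")
        if not isinstance(self.phase, str):
            if not 0 <= self.phase < self.frame_interval:
                raise ValueError("phase must lie in [0, frame_interval)")


@dataclass
class NoiseSpec:
    """Additive Gaussian noise level under one of two SNR conventions.

    ``peak_over_sd``: SNR = max|clean response| / SD(noise).
    ``sd_over_sd``:   SNR = SD(clean response) / SD(noise).
    """

    snr: float
    convention: str = "sd_over_sd"
    seed: Optional[int] = None

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.convention not in ("peak_over_sd", "sd_over_sd"):
            raise ValueError("convention must be 'peak_over_sd' or 'sd_over_sd'")


def make_filter(spec: FilterSpec) -> FilterEstimate:
    """Realise a :class:`FilterSpec` on its causal lag grid."""
    t = (np.arange(spec.length) + 0.5) * spec.dt
    p = spec.params

    def need(*names):
        for nm in names:
            if nm not in p:
                raise ValueError(f"filter kind {spec.kind!r} needs parameter {nm!r}")

    if spec.kind == "damped_osc":
        need("tau1", "tau2")
        v = np.exp(-t / p["tau1"]) * np.sin(2 * np.pi * t / p["tau2"])
    elif spec.kind == "exponential":
        need("tau1")
        v = np.exp(-t / p["tau1"]) / p["tau1"]
    elif spec.kind == "bilobed":
        need("tau1", "tau2", "tau3")
        v = (1 - np.exp(-t / p["tau1"])) * (
            np.exp(-t / p["tau2"]) / p["tau2"]
            - t / p["tau3"] ** 2 * np.exp(-t / p["tau3"])
        )
    elif spec.kind == "custom":
        need("values")
        v = np.asarray(p["values"], dtype=float)
        if len(v) != spec.length:
            raise ValueError("custom values must match spec.length")
    else:
        raise ValueError(f"unknown filter kind {spec.kind!r}")

    if spec.normalize == "unit_mean_square":
        v = v / np.sqrt(np.mean(v**2))
    elif spec.normalize != "none":
        raise ValueError("normalize must be 'none' or 'unit_mean_square'")

    lags = LagGrid.from_window(spec.dt, n_causal=spec.length, n_acausal=0)
    return FilterEstimate(lags=lags, values=v, method="truth",
                          meta={"kind": spec.kind, **{k: v_ for k, v_ in p.items()
                                                      if k != "values"}})


def generate_stimulus(kind: str, dt: float, duration_total: float,
                      params: Optional[dict] = None,
                      seed: Union[int, np.random.Generator, None] = None) -> StimulusTrace:
    """Generate a dense stimulus trace.

    kinds: ``gaussian_white`` (iid N(0, sd^2) per bin), ``binary``
    (iid +-contrast), ``impulse_train`` (unit impulses at fixed spacing with
    random phase, or Poisson), ``sparse_onset`` (0/1 Bernoulli onset
    indicator at the given rate).
    """
    rng = _rng(seed)
    p = dict(params or {})
    n = int(round(duration_total / dt))
    meta = {"kind": kind, "seed": None if isinstance(seed, np.random.Generator) else seed}

    if kind == "gaussian_white":
        v = rng.standard_normal(n) * p.get("sd", 1.0)
    elif kind == "binary":
        contrast = p.get("contrast", 0.9)
        v = rng.choice([-contrast, contrast], size=n)
    elif kind == "impulse_train":
        v = np.zeros(n)
        if p.get("poisson", False):
            rate = p["rate"]
            k = rng.poisson(rate * dt, size=n)
            v = k.astype(float)
        else:
            spacing = int(round(p["spacing"] / dt))
            phase = int(rng.integers(0, spacing))
            v[phase::spacing] = 1.0
            meta["period"] = spacing * dt
    elif kind == "sparse_onset":
        rate = p["rate"]
        v = (rng.random(n) < rate * dt).astype(float)
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}; choose from {STIMULUS_KINDS}")
    return StimulusTrace(t0=0.0, dt=dt, values=v, meta=meta)


def simulate_response(stim: StimulusTrace, f: FilterEstimate,
                      noise: Optional[NoiseSpec] = None,
                      seed: Union[int, np.random.Generator, None] = None) -> StimulusTrace:
    """Dense response: causal convolution of the stimulus with a filter,
    plus iid Gaussian noise at the level set by the SNR convention."""
    if stim.values.ndim != 1:
        raise ValueError("simulate_response requires a single-channel stimulus")
    if len(f.lags) > 1 and not np.isclose(f.lags.dt, stim.dt, rtol=1e-9):
        raise ValueError("filter and stimulus grids must match")
    if f.lags.n_acausal > 0:
        raise ValueError("model filters must be causal")
    clean = np.convolve(stim.values, f.values)[: stim.n_bins]
    out = clean.copy()
    if noise is not None and np.isfinite(noise.snr):
        rng = _rng(noise.seed if seed is None else seed)
        if noise.convention == "peak_over_sd":
            sd = np.max(np.abs(clean)) / noise.snr
        else:
            sd = np.std(clean) / noise.snr
        out = clean + rng.standard_normal(stim.n_bins) * sd
    return StimulusTrace(t0=stim.t0, dt=stim.dt, values=out,
                         meta={**stim.meta, "response": True})


def sample_scheme(dense: StimulusTrace, scheme: SamplingScheme,
                  seed: Union[int, np.random.Generator, None] = None) -> TimedSamples:
    """Sample a dense response according to an acquisition scheme.

    Sample values are the dense trace averaged over ``integration_time``
    centred on the sample time (a point sample when the integration time is
    at most one bin). Warns when the frame interval is commensurate with a
    periodic stimulus (not every phase gets sampled).
    """
    rng = _rng(seed)
    fi = scheme.frame_interval

    period = dense.meta.get("period")
    if period is not None and fi >= period - 1e-12:
        ratio = fi / period
        if abs(ratio - round(ratio)) < 1e-9:
            warnings.warn(
                "frame interval is an integer multiple of the stimulus repeat "
                "period: not all stimulus phases will be sampled; choose "
                "incommensurate rates", UserWarning)

    if scheme.scheme == "continuous":
        return TimedSamples(times=dense.times.copy(), values=dense.values.copy(),
                            integration_time=dense.dt)

    if scheme.scheme == "volumetric":
        phase = (rng.uniform(0, fi) if isinstance(scheme.phase, str)
                 else float(scheme.phase))
        plane_offset = scheme.plane_of_roi * fi / max(scheme.n_planes, 1)
        t_first = dense.t0 + phase + plane_offset
        half = scheme.integration_time / 2.0
        times = np.arange(t_first, dense.t_end - half - 1e-12, fi)
        times = times[times - half >= dense.t0]
        if scheme.n_samples is not None:
            times = times[: scheme.n_samples]
        values = _integrated_values(dense, times, scheme.integration_time)
        return TimedSamples(times=times, values=values,
                            integration_time=scheme.integration_time,
                            meta={"scheme": "volumetric", "phase": phase})

    if scheme.scheme == "plane_by_plane":
        if scheme.n_samples is None:
            raise ValueError("plane_by_plane needs n_samples (matched to the "
                             "volumetric run)")
        fast = fi / max(scheme.n_planes, 1)
        span = scheme.n_samples * fast
        if span > dense.n_bins * dense.dt:
            raise ValueError("contiguous block longer than the record")
        if scheme.block_start in (None, "random"):
            start = rng.uniform(dense.t0, dense.t_end - span)
        else:
            start = float(scheme.block_start)
        half = scheme.integration_time / 2.0
        times = start + half + np.arange(scheme.n_samples) * fast
        values = _integrated_values(dense, times, scheme.integration_time)
        return TimedSamples(times=times, values=values,
                            integration_time=scheme.integration_time,
                            meta={"scheme": "plane_by_plane", "block_start": start})

    raise ValueError(f"unknown scheme {scheme.scheme!r}")


def _integrated_values(dense: StimulusTrace, times: np.ndarray, width: float) -> np.ndarray:
    from .core import _window_means
    if width <= dense.dt:
        bins = np.clip(dense.bin_of(times), 0, dense.n_bins - 1)
        return dense.values[bins]
    return _window_means(dense, np.asarray(times)[:, None], width)[:, 0]


def amplitude_modulated_cell(stim: StimulusTrace, f: FilterEstimate,
                             epoch_length: float, noise: Optional[NoiseSpec] = None,
                             seed: Union[int, np.random.Generator, None] = None,
                             amplitude: str = "sign") -> StimulusTrace:
    """Response of a model cell whose receptive-field amplitude changes sign.

    ``response(t) = a(t) * (f * s)(t) + noise`` with ``a(t)`` piecewise
    constant over epochs of ``epoch_length``, drawn iid +-1 per epoch
    (``amplitude="sign"``) or N(0, 1) (``amplitude="gaussian"``). The
    first-order (mean) filter of this cell is zero; its receptive field is
    only visible in the response-weighted stimulus covariance.
    """
    filt_span = len(f.lags) * f.lags.dt if len(f.lags) > 1 else stim.dt
    if epoch_length < filt_span:
        raise ValueError("epoch_length must be at least the filter length")
    rng = _rng(seed)
    clean = np.convolve(stim.values, f.values)[: stim.n_bins]
    ep_bins = max(1, int(round(epoch_length / stim.dt)))
    n_ep = stim.n_bins // ep_bins + 1
    if amplitude == "sign":
        a = rng.choice([-1.0, 1.0], size=n_ep)
    elif amplitude == "gaussian":
        a = rng.standard_normal(n_ep)
    else:
        raise ValueError("amplitude must be 'sign' or 'gaussian'")
    mod = clean * a.repeat(ep_bins)[: stim.n_bins]
    out = mod
    if noise is not None:
        sd = (np.max(np.abs(clean)) if noise.convention == "peak_over_sd"
              else np.std(clean)) / noise.snr
        out = mod + rng.standard_normal(stim.n_bins) * sd
    return StimulusTrace(t0=stim.t0, dt=stim.dt, values=out,
                         meta={**stim.meta, "modulated": True})


# ---------------------------------------------------------------------------
# canonical packaged experiments
# ---------------------------------------------------------------------------

def fig1_experiment(n_samples: int = 10_000, seed: int = 0, n_lags: int = 400,
                    n_acausal: int = 0):
    """Damped-oscillation cell, 1 ms white stimulus, 1 ms / 100 ms sampling.

    Returns ``(pairs, f_true)``. SNR ~ 60 as peak response over noise SD.
    """
    rng = _rng(seed)
    dt = 1e-3
    f_true = make_filter(FilterSpec("damped_osc", {"tau1": 0.1, "tau2": 0.05},
                                    dt=dt, length=n_lags,
                                    normalize="unit_mean_square"))
    frame = 0.1
    margin = (n_lags + n_acausal + 2) * dt
    duration = n_samples * frame + 2 * margin
    stim = generate_stimulus("gaussian_white", dt, duration, seed=rng)
    resp = simulate_response(stim, f_true,
                             NoiseSpec(60.0, "peak_over_sd"), seed=rng)
    scheme = SamplingScheme(frame_interval=frame, integration_time=dt,
                            phase=margin % frame, n_samples=n_samples)
    samples = sample_scheme(resp, scheme, seed=rng)
    # shift first sample past the history margin
    keep = samples.times >= margin
    samples = TimedSamples(samples.times[keep][:n_samples],
                           samples.values[keep][:n_samples], dt)
    lags = LagGrid.from_window(dt, n_causal=n_lags, n_acausal=n_acausal)
    return build_pairs(stim, samples, lags), f_true


def fig2_experiment(n_samples: int = 200, seed: int = 0, n_lags: int = 50):
    """Exponential filter (tau = 10 steps), noiseless, sampled every 10 steps."""
    rng = _rng(seed)
    dt = 1.0
    f_true = make_filter(FilterSpec("exponential", {"tau1": 10.0}, dt=dt,
                                    length=n_lags))
    stride = 10
    margin = n_lags + 1
    duration = n_samples * stride + 2 * margin
    stim = generate_stimulus("gaussian_white", dt, duration, seed=rng)
    resp = simulate_response(stim, f_true, noise=None)
    scheme = SamplingScheme(frame_interval=float(stride), integration_time=dt,
                            phase=0.5, n_samples=n_samples)
    samples = sample_scheme(resp, scheme, seed=rng)
    keep = samples.times >= margin
    samples = TimedSamples(samples.times[keep][:n_samples],
                           samples.values[keep][:n_samples], dt)
    lags = LagGrid.from_window(dt, n_causal=n_lags)
    return build_pairs(stim, samples, lags), f_true


def fig3_experiment(n_samples: int = 1000, seed: int = 0, n_lags: int = 100):
    """Bilobed filter, 100 Hz stimulus, 10 ms samples every 500 ms, SNR = 1."""
    rng = _rng(seed)
    dt = 0.01
    f_true = make_filter(FilterSpec("bilobed",
                                    {"tau1": 0.02, "tau2": 0.1, "tau3": 0.2},
                                    dt=dt, length=n_lags))
    frame = 0.5
    margin = (n_lags + 2) * dt
    duration = n_samples * frame + 2 * margin
    stim = generate_stimulus("gaussian_white", dt, duration, seed=rng)
    resp = simulate_response(stim, f_true, NoiseSpec(1.0, "sd_over_sd"), seed=rng)
    scheme = SamplingScheme(frame_interval=frame, integration_time=dt,
                            phase=margin % frame, n_samples=n_samples)
    samples = sample_scheme(resp, scheme, seed=rng)
    keep = samples.times >= margin
    samples = TimedSamples(samples.times[keep][:n_samples],
                           samples.values[keep][:n_samples], dt)
    lags = LagGrid.from_window(dt, n_causal=n_lags)
    return build_pairs(stim, samples, lags), f_true


def second_order_experiment(n_samples: int = 4000, seed: int = 0, n_lags: int = 20,
                            stride: int = 20, snr: float = 1.5,
                            epoch_bins: int = 20):
    """Sign-modulated cell: zero mean filter, recoverable second order.

    Defaults place exactly one sample per amplitude epoch (epoch = filter
    span = sampling stride) so that the sampled amplitudes are independent
    and per-sample bootstrap intervals for the first-order filter are
    calibrated.
    """
    rng = _rng(seed)
    dt = 0.01
    tt = (np.arange(n_lags) + 0.5) * dt
    v = np.exp(-tt / 0.1) * np.sin(2 * np.pi * tt / 0.16)
    f_true = make_filter(FilterSpec("custom", {"values": v}, dt=dt, length=n_lags,
                                    normalize="unit_mean_square"))
    margin = (n_lags + 2) * dt
    duration = n_samples * stride * dt + 2 * margin
    stim = generate_stimulus("gaussian_white", dt, duration, seed=rng)
    resp = amplitude_modulated_cell(stim, f_true, epoch_length=epoch_bins * dt,
                                    noise=NoiseSpec(snr, "sd_over_sd"), seed=rng)
    scheme = SamplingScheme(frame_interval=stride * dt, integration_time=dt,
                            phase=margin % (stride * dt), n_samples=n_samples)
    samples = sample_scheme(resp, scheme, seed=rng)
    keep = samples.times >= margin
    samples = TimedSamples(samples.times[keep][:n_samples],
                           samples.values[keep][:n_samples], dt)
    lags = LagGrid.from_window(dt, n_causal=n_lags)
    return build_pairs(stim, samples, lags), f_true


def volumetric_vs_planes_cell(seed, noise: str = "ar1", ar_coef: float = 0.8,
                              n_lags: int = 30, plane_rate: float = 30.0,
                              n_planes: int = 15, duration: float = 1200.0,
                              snr: float = 1.0):
    """One model cell sampled volumetrically and plane-by-plane.

    The dense record runs at the plane rate; volumetric sampling takes one
    sample per volume (``plane_rate / n_planes`` Hz) for the whole record,
    plane-by-plane takes a contiguous block at the full plane rate with the
    same total sample count. Measurement noise is added on the dense grid:
    white, or AR(1) with coefficient ``ar_coef`` per plane-rate step, scaled
    to the same marginal SD (= SD(clean)/snr).

    Returns ``(pairs_volumetric, pairs_plane_by_plane, f_true)``.
    """
    from scipy.signal import lfilter

    rng = _rng(seed)
    dt = 1.0 / plane_rate
    tt = (np.arange(n_lags) + 0.5) * dt
    v = np.exp(-tt / 0.3) - np.exp(-tt / 0.05)  # calcium-indicator-like kernel
    f_true = make_filter(FilterSpec("custom", {"values": v}, dt=dt, length=n_lags,
                                    normalize="unit_mean_square"))
    margin = (n_lags + 2) * dt
    stim = generate_stimulus("gaussian_white", dt, duration + 2 * margin, seed=rng)
    clean = np.convolve(stim.values, f_true.values)[: stim.n_bins]
    e = rng.standard_normal(stim.n_bins)
    if noise == "ar1":
        e = lfilter([1.0], [1.0, -ar_coef], e) * np.sqrt(1 - ar_coef**2)
    elif noise != "white":
        raise ValueError("noise must be 'ar1' or 'white'")
    resp = StimulusTrace(stim.t0, dt, clean + e * np.std(clean) / snr)

    frame = n_planes / plane_rate
    n_samp = int((duration - 2 * margin - frame) // frame)
    lags = LagGrid.from_window(dt, n_causal=n_lags)

    vol = sample_scheme(resp, SamplingScheme(
        frame_interval=frame, integration_time=dt,
        phase=margin % frame), seed=rng)
    keep = vol.times >= margin
    vol = TimedSamples(vol.times[keep][:n_samp], vol.values[keep][:n_samp], dt)
    assert len(vol) == n_samp

    pbp = sample_scheme(resp, SamplingScheme(
        frame_interval=frame, integration_time=dt, scheme="plane_by_plane",
        n_planes=n_planes, n_samples=n_samp,
        block_start=float(rng.uniform(margin, duration - n_samp * dt))), seed=rng)

    return (build_pairs(stim, vol, lags), build_pairs(stim, pbp, lags), f_true)
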