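"""Mapping real imaging experiments onto timed samples.

Scan-geometry timing (which line of which frame a ROI was measured in, hence
the exact acquisition time of every sample), deltaF/F with a fitted
exponential bleach baseline, every-k-th subsampling, bin-mean downsampling,
stimulus-onset traces, and per-line filter averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import FilterEstimate, StimulusTrace, TimedSamples

__all__ = [
    "ScanGeometry",
    "RoiTrace",
    "sample_times_from_scan",
    "dff",
    "subsample",
    "downsample_dense",
    "onset_trace",
    "per_line_filter_average",
    "roi_means_from_tiff",
]


@dataclass
class ScanGeometry:
    """Frame/line timing of a serial-scanning acquisition."""

    frame_period: float
    line_period: float
    lines_per_frame: int
    bidirectional: bool = False
    frame_start_times: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.line_period * self.lines_per_frame > self.frame_period * (1 + 1e-9):
            raise ValueError("line_period * lines_per_frame must fit in frame_period")
        if self.frame_start_times is not None:
            self.frame_start_times = np.asarray(self.frame_start_times, dtype=float)
            if len(self.frame_start_times) > 1 and \
                    not np.all(np.diff(self.frame_start_times) > 0):
                raise ValueError("frame_start_times must be strictly increasing")

    def starts(self, n_frames: int) -> np.ndarray:
        if self.frame_start_times is not None:
            if len(self.frame_start_times) < n_frames:
                raise ValueError("fewer frame_start_times than frames")
            return self.frame_start_times[:n_frames]
        return np.arange(n_frames) * self.frame_period


@dataclass
class RoiTrace:
    """Raw fluorescence of one ROI: per-line values or per-frame means."""

    roi_id: str
    line_indices: Sequence[int]
    per_line_values: Optional[np.ndarray] = None  # (frames, lines)
    per_frame_values: Optional[np.ndarray] = None

    def __post_init__(self):
        self.line_indices = np.asarray(self.line_indices, dtype=int)
        if self.per_line_values is not None:
            self.per_line_values = np.asarray(self.per_line_values, dtype=float)
            if self.per_line_values.shape[1] != len(self.line_indices):
                raise ValueError("per_line_values must have one column per ROI line")
        if self.per_frame_values is not None:
            self.per_frame_values = np.asarray(self.per_frame_values, dtype=float)


def sample_times_from_scan(geom: ScanGeometry, roi: RoiTrace) -> List[TimedSamples]:
    """Exact acquisition times for a ROI's samples.

    Per-line traces give one :class:`TimedSamples` per ROI line: line ``l`` of
    frame ``k`` is acquired at ``frame_start[k] + l * line_period``
    (bidirectional scans mirror the line order on odd frames). Per-frame
    means give a single series timed at the ROI's centre line, with
    ``integration_time = line_period * n_lines``.
    """
    lines = np.asarray(roi.line_indices)
    if np.any(lines < 0) or np.any(lines >= geom.lines_per_frame):
        raise ValueError("ROI line index out of range")

    if roi.per_line_values is not None:
        n_frames = roi.per_line_values.shape[0]
        starts = geom.starts(n_frames)
        out = []
        for j, line in enumerate(lines):
            if geom.bidirectional:
                eff = np.where(np.arange(n_frames) % 2 == 0, line,
                               geom.lines_per_frame - 1 - line)
                times = starts + eff * geom.line_period
            else:
                times = starts + line * geom.line_period
            out.append(TimedSamples(times=times, values=roi.per_line_values[:, j],
                                    integration_time=geom.line_period,
                                    meta={"roi": roi.roi_id, "line": int(line)}))
        return out

    if roi.per_frame_values is None:
        raise ValueError("RoiTrace carries neither per-line nor per-frame values")
    n_frames = len(roi.per_frame_values)
    starts = geom.starts(n_frames)
    center = float(np.mean(lines))
    times = starts + center * geom.line_period
    return [TimedSamples(times=times, values=roi.per_frame_values,
                         integration_time=geom.line_period * len(lines),
                         meta={"roi": roi.roi_id, "center_line": center})]


def dff(trace: TimedSamples, fallback: str = "mean") -> TimedSamples:
    """Convert raw fluorescence to deltaF/F against an exponential baseline.

    Fits ``F(t) = A exp(-t / tau_b) + C`` to the whole trace by least
    squares and returns ``(raw - F) / F``. If the fit diverges (or the
    fitted baseline is not strictly positive), falls back to a constant
    baseline equal to the trace mean and flags it in ``meta``.
    """
    if len(trace) < 4:
        raise ValueError("need at least 4 samples to fit a baseline")
    t = trace.times - trace.times[0]
    y = trace.values
    span = max(t[-1], 1e-9)

    def model(tt, A, tau, C):
        return A * np.exp(-tt / tau) + C

    used_fallback = False
    try:
        ptp = np.ptp(y)
        p0 = [max(ptp, 1e-9), span / 3.0, float(np.min(y))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, t, y, p0=p0,
                                bounds=([-np.inf, span * 1e-4, -np.inf],
                                        [np.inf, span * 1e4, np.inf]),
                                maxfev=10000)
        F = model(t, *popt)
        if np.any(F <= 0):
            raise RuntimeError("fitted baseline not positive")
    except (RuntimeError, ValueError):
        used_fallback = True
        F = np.full_like(y, float(np.mean(y)))
        popt = None
        if np.any(F <= 0):
            raise ValueError("baseline fit failed and trace mean is not positive")

    meta = {**trace.meta, "dff": True, "baseline_fallback": used_fallback}
    if popt is not None:
        meta["baseline_params"] = {"A": float(popt[0]), "tau_b": float(popt[1]),
                                   "C": float(popt[2])}
    return TimedSamples(times=trace.times.copy(), values=(y - F) / F,
                        integration_time=trace.integration_time, meta=meta)


def subsample(samples: TimedSamples, k: int, phase: int = 0) -> TimedSamples:
    """Keep every ``k``-th sample starting at ``phase`` (times untouched)."""
    if not 0 <= phase < k:
        raise ValueError("phase must lie in [0, k)")
    return TimedSamples(times=samples.times[phase::k].copy(),
                        values=samples.values[phase::k].copy(),
                        integration_time=samples.integration_time,
                        meta={**samples.meta, "subsample_k": k, "subsample_phase": phase})


def downsample_dense(trace: StimulusTrace, target_dt: float) -> StimulusTrace:
    """Bin-mean downsampling of a dense trace to a coarser grid.

    Non-integer rate ratios fall back to nearest-bin assignment with a
    warning.
    """
    if target_dt < trace.dt:
        raise ValueError("target_dt must be at least the source dt")
    ratio = target_dt / trace.dt
    n = trace.n_bins
    if abs(ratio - round(ratio)) < 1e-9:
        k = int(round(ratio))
        m = n // k
        v = trace.values[: m * k].reshape(m, k, *trace.values.shape[1:]).mean(axis=1)
    else:
        warnings.warn("non-integer downsampling ratio; using nearest-bin "
                      "assignment", UserWarning)
        m = int(np.floor(n * trace.dt / target_dt))
        idx = np.minimum((np.arange(n) * trace.dt / target_dt).astype(int), m - 1)
        sums = np.zeros((m, *trace.values.shape[1:]))
        counts = np.bincount(idx, minlength=m)
        np.add.at(sums, idx, trace.values)
        v = sums / counts.reshape(-1, *([1] * (trace.values.ndim - 1)))
    return StimulusTrace(t0=trace.t0, dt=target_dt, values=v, units=trace.units,
                         meta={**trace.meta, "downsampled_from_dt": trace.dt})


def onset_trace(event_times, t0: float, dt: float, n_bins: int,
                channels=None, n_channels: int = 1) -> StimulusTrace:
    """Binary per-bin indicator of stimulus onsets (1 if any onset in the bin).

    Events are binned half-open onto ``[t0 + b*dt, t0 + (b+1)*dt)``; events
    outside the grid are dropped with a logged count in ``meta``.
    """
    event_times = np.asarray(event_times, dtype=float)
    bins = np.floor((event_times - t0) / dt).astype(int)
    ok = (bins >= 0) & (bins < n_bins)
    dropped = int(np.sum(~ok))
    if dropped:
        warnings.warn(f"{dropped} events outside the grid were dropped", UserWarning)
    if channels is None:
        v = np.zeros(n_bins)
        v[bins[ok]] = 1.0
    else:
        channels = np.asarray(channels, dtype=int)
        v = np.zeros((n_bins, n_channels))
        v[bins[ok], channels[ok]] = 1.0
    return StimulusTrace(t0=t0, dt=dt, values=v, units="onset",
                         meta={"events_dropped": dropped})


def per_line_filter_average(filters: List[FilterEstimate]) -> FilterEstimate:
    """Element-wise mean of per-line filters; SE from across-line dispersion
    when at least 3 lines are available."""
    if not filters:
        raise ValueError("no filters to average")
    taus0 = filters[0].lags.taus
    for f in filters[1:]:
        if len(f.lags.taus) != len(taus0) or not np.allclose(f.lags.taus, taus0):
            raise ValueError("all filters must share the same lag grid")
    V = np.stack([f.values for f in filters])
    mean = V.mean(axis=0)
    se = V.std(axis=0, ddof=1) / np.sqrt(len(filters)) if len(filters) >= 3 else None
    return FilterEstimate(lags=filters[0].lags, values=mean, se=se,
                          method="line_average",
                          meta={"n_lines": len(filters)})


def roi_means_from_tiff(path, mask: np.ndarray) -> np.ndarray:
    """Mean pixel value per frame within a boolean ROI mask of a TIFF stack.

    Reads a multi-frame TIFF purely to extract ROI means; no segmentation.
    """
    import tifffile

    mask = np.asarray(mask, dtype=bool)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[-2:] != mask.shape:
        raise ValueError("mask shape must match frame shape")
    return stack[..., mask].mean(axis=-1)
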