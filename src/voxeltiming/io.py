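"""Reading and writing the package's file formats.

Stimulus traces and filters travel as delimited text with a ``#``-prefixed
JSON metadata header, or as HDF5 mirrors; response samples as
``roi,time,value`` tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .core import FilterEstimate, LagGrid, StimulusTrace, TimedSamples

__all__ = [
    "read_stimulus_csv", "write_stimulus_csv",
    "read_stimulus_h5", "write_stimulus_h5",
    "read_samples_csv", "write_samples_csv",
    "read_filter_csv", "write_filter_csv",
]


def _read_meta_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line[1:].strip()
            if stripped.startswith("{"):
                meta.update(json.loads(stripped))
    return meta


def write_stimulus_csv(path, stim: StimulusTrace, meta: Optional[dict] = None):
    """Write a stimulus as ``time,value[,value2,...]`` with metadata header."""
    hdr = {"t0": stim.t0, "dt": stim.dt, "units": stim.units,
           **stim.meta, **(meta or {})}
    vals = stim.values if stim.values.ndim == 2 else stim.values[:, None]
    cols = ["value"] if vals.shape[1] == 1 else [f"value{i}" for i in range(vals.shape[1])]
    df = pd.DataFrame(vals, columns=cols)
    df.insert(0, "time", stim.times)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(hdr, default=str) + "\n")
        df.to_csv(fh, index=False)


def read_stimulus_csv(path) -> StimulusTrace:
    meta = _read_meta_header(path)
    df = pd.read_csv(path, comment="#")
    if "time" not in df.columns:
        raise ValueError("stimulus file must have a 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError("stimulus time grid is not uniform")
        dt = float(dts[0])
    else:
        dt = float(meta.get("dt", 1.0))
    vals = df.drop(columns="time").to_numpy(dtype=float)
    if vals.shape[1] == 1:
        vals = vals[:, 0]
    t0 = float(meta.get("t0", t[0] - dt / 2.0))
    units = str(meta.get("units", "a.u."))
    keep = {k: v for k, v in meta.items() if k not in ("t0", "dt", "units")}
    return StimulusTrace(t0=t0, dt=dt, values=vals, units=units, meta=keep)


def write_stimulus_h5(path, stim: StimulusTrace, group: str = "stimulus"):
    import h5py

    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("t0", data=stim.t0)
        g.create_dataset("dt", data=stim.dt)
        g.create_dataset("values", data=stim.values)
        g.attrs["units"] = stim.units
        g.attrs["meta"] = json.dumps(stim.meta, default=str)


def read_stimulus_h5(path, group: str = "stimulus") -> StimulusTrace:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh[group]
        meta = json.loads(g.attrs.get("meta", "{}"))
        return StimulusTrace(t0=float(g["t0"][()]), dt=float(g["dt"][()]),
                             values=g["values"][()],
                             units=str(g.attrs.get("units", "a.u.")), meta=meta)


def write_samples_csv(path, samples: Dict[str, TimedSamples],
                      meta: Optional[dict] = None):
    """Write per-ROI samples as ``roi,time,value`` rows; the integration time
    goes into the metadata header."""
    hdr = dict(meta or {})
    hdr["integration_time"] = {k: s.integration_time for k, s in samples.items()}
    frames = [pd.DataFrame({"roi": k, "time": s.times, "value": s.values})
              for k, s in samples.items()]
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(hdr, default=str) + "\n")
        pd.concat(frames, ignore_index=True).to_csv(fh, index=False)


def read_samples_csv(path, integration_time: Optional[float] = None
                     ) -> Dict[str, TimedSamples]:
    meta = _read_meta_header(path)
    it_map = meta.get("integration_time", {})
    df = pd.read_csv(path, comment="#", dtype={"roi": str})
    out = {}
    for roi, sub in df.groupby("roi", sort=False):
        it = integration_time if integration_time is not None \
            else float(it_map.get(roi, 0.0))
        sub = sub.sort_values("time")
        out[str(roi)] = TimedSamples(times=sub["time"].to_numpy(dtype=float),
                                     values=sub["value"].to_numpy(dtype=float),
                                     integration_time=it, meta={"roi": str(roi)})
    return out


def write_filter_csv(path, f: FilterEstimate, meta: Optional[dict] = None):
    """Write a filter as ``lag_s,value[,se]`` with method and parameters in a
    JSON metadata header. Lag sign convention: positive lag = stimulus
    preceding the response."""
    hdr = {"method": f.method, "lag_convention": "positive = stimulus precedes response",
           **f.meta, **(meta or {})}
    df = pd.DataFrame({"lag_s": f.lags.taus, "value": f.values})
    if f.se is not None:
        df["se"] = f.se
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(hdr, default=str) + "\n")
        df.to_csv(fh, index=False)


def read_filter_csv(path) -> FilterEstimate:
    meta = _read_meta_header(path)
    df = pd.read_csv(path, comment="#")
    lags = LagGrid(df["lag_s"].to_numpy(dtype=float))
    se = df["se"].to_numpy(dtype=float) if "se" in df.columns else None
    method = str(meta.pop("method", ""))
    meta.pop("lag_convention", None)
    return FilterEstimate(lags=lags, values=df["value"].to_numpy(dtype=float),
                          se=se, method=method, meta=meta)
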