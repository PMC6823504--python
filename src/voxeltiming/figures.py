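"""Regenerate the synthetic figure panels from scratch.

Each panel is produced by running the simulator and the estimators end to
end; nothing is cached. Used by ``voxeltiming figures``.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import LagGrid, build_pairs
from .estimators import (asd_fit, cross_correlation, gaussian_kernel,
                         interpolated_filter, laguerre_fit, ols_filter,
                         response_weighted_covariance, smooth_filter,
                         triangle_kernel)
from .synthetic import (fig1_experiment, fig2_experiment, fig3_experiment,
                        second_order_experiment)

__all__ = ["make_figures"]


def _plot_filters(ax, lags, curves, title):
    for label, v in curves.items():
        ax.plot(lags * 1e3 if np.max(np.abs(lags)) < 10 else lags, v, label=label,
                lw=1.2)
    ax.set_xlabel("time lag (ms)" if np.max(np.abs(lags)) < 10 else "time lag (steps)")
    ax.set_ylabel("filter (a.u.)")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)


def fig1_panels(seed, out_dir: Path):
    pairs, f_true = fig1_experiment(n_samples=10_000, seed=seed)
    c = cross_correlation(pairs)
    fig, ax = plt.subplots(figsize=(5, 3))
    _plot_filters(ax, c.lags.taus,
                  {"true filter": f_true.values, "cross-correlation": c.values},
                  "20 Hz damped-oscillation cell, 1 ms / 100 ms sampling")
    fig.tight_layout()
    p = out_dir / "fig1_reconstruction.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    return [p]


def fig2_panels(seed, out_dir: Path):
    pairs, f_true = fig2_experiment(n_samples=400, seed=seed)
    c = cross_correlation(pairs)
    o = ols_filter(pairs)
    fig, ax = plt.subplots(figsize=(5, 3))
    _plot_filters(ax, c.lags.taus,
                  {"true filter": f_true.values,
                   "cross-correlation": c.values / np.var(pairs.S),
                   "OLS": o.values},
                  "exponential filter, noiseless, sampled every 10 steps")
    fig.tight_layout()
    p = out_dir / "fig2_procedure.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    return [p]


def fig3_panels(seed, out_dir: Path):
    paths = []
    pairs, f_true = fig3_experiment(n_samples=1200, seed=seed)
    o = ols_filter(pairs)
    dt = pairs.lags.dt

    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    # interpolation baselines need the raw stimulus/samples; rebuild
    from .synthetic import fig3_experiment as _f3
    curves = {"true": f_true.values, "voxel-timing OLS": o.values}
    _plot_filters(axes[0, 0], o.lags.taus, curves, "voxel-timing vs truth")

    sm = {f"{sd*1e3:.0f} ms": smooth_filter(o, gaussian_kernel(sd, dt)).values
          for sd in (0.01, 0.03, 0.1)}
    _plot_filters(axes[0, 1], o.lags.taus, {"true": f_true.values, **sm},
                  "Gaussian smoothing (SD)")

    tri = smooth_filter(o, triangle_kernel(0.5, dt))
    _plot_filters(axes[1, 0], o.lags.taus,
                  {"true": f_true.values, "triangle-smoothed": tri.values},
                  "triangle smoothing to the interpolation filter")

    lag = laguerre_fit(pairs)
    asd = asd_fit(pairs)
    _plot_filters(axes[1, 1], o.lags.taus,
                  {"true": f_true.values, "Laguerre (5)": lag.values,
                   "ASD": asd.values}, "regularisation")
    fig.tight_layout()
    p = out_dir / "fig3_noise_regularisation.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    return paths


def second_order_panels(seed, out_dir: Path):
    pairs, f_true = second_order_experiment(seed=seed)
    c1 = cross_correlation(pairs)
    cov = response_weighted_covariance(pairs)
    fig, axes = plt.subplots(1, 3, figsize=(11, 3))
    _plot_filters(axes[0], c1.lags.taus,
                  {"true RF": f_true.values, "first-order filter": c1.values},
                  "mean filter is ~0")
    im = axes[1].imshow(cov.C, cmap="RdBu_r")
    axes[1].set_title("response-weighted covariance", fontsize=9)
    fig.colorbar(im, ax=axes[1], shrink=0.8)
    top = cov.eigenvectors[:, 0]
    sgn = np.sign(top @ f_true.values) or 1.0
    _plot_filters(axes[2], c1.lags.taus,
                  {"true RF (scaled)": f_true.values / np.linalg.norm(f_true.values),
                   "top eigenvector": sgn * top}, "second-order recovery")
    fig.tight_layout()
    p = out_dir / "secondorder_recovery.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    return [p]


def make_figures(which: str = "all", seed: int = 0, out_dir="figures"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jobs = {
        "fig1": fig1_panels,
        "fig2": fig2_panels,
        "fig3": fig3_panels,
        "secondorder": second_order_panels,
    }
    names = list(jobs) if which == "all" else [which]
    paths = []
    for name in names:
        paths.extend(jobs[name](seed, out))
    return paths
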