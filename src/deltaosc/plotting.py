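"""Plots for spatial envelopes, corrected traces, and cluster summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusterResult
from .oscillation import AutocorrResult, CorrectedTrace
from .spatial import LCurveSet

__all__ = [
    "plot_l_curve",
    "plot_corrected_trace",
    "plot_autocorrelation",
    "plot_trace_heatmap",
    "plot_group_composition",
]


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_l_curve(curves: LCurveSet, path: str | Path | None = None):
    """Observed L(r) against the shaded simulation envelope and the CSR line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(
        curves.radii, curves.env_lo, curves.env_hi, color="0.85",
        label=f"{curves.level:.0%} envelope ({curves.n_sim} sims)",
    )
    ax.plot(curves.radii, curves.radii, "k:", lw=1, label="CSR (L = r)")
    ax.plot(curves.radii, curves.l_obs, "C3-", lw=1.5, label="observed")
    ax.set_xlabel("r (µm)")
    ax.set_ylabel("L(r) (µm)")
    ax.legend(frameon=False, fontsize=8)
    return _finish(fig, path)


def plot_corrected_trace(c: CorrectedTrace, path: str | Path | None = None):
    fig, axes = plt.subplots(2, 1, figsize=(6, 5), sharex=True)
    axes[0].plot(c.t, c.normalized, "0.6", lw=1, label="normalized")
    axes[0].set_ylabel("mCherry / GFP")
    axes[0].legend(frameon=False, fontsize=8)
    axes[1].plot(c.t, c.detrended, "0.8", lw=1, label="detrended")
    axes[1].plot(c.t, c.smoothed, "C0-", lw=1.5, label="smoothed")
    axes[1].plot(c.peak_times, c.smoothed[c.peaks], "rv", ms=6, label="peaks")
    axes[1].set_xlabel("time (min)")
    axes[1].set_ylabel("corrected signal")
    axes[1].legend(frameon=False, fontsize=8)
    fig.suptitle(c.cell_id, fontsize=10)
    return _finish(fig, path)


def plot_autocorrelation(acf: AutocorrResult, dt: float = 5.0, path=None):
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.stem(acf.lags * dt, acf.r, basefmt="k-")
    ax.axhline(0.3, color="0.7", ls="--", lw=1)
    ax.axhline(-0.3, color="0.7", ls="--", lw=1)
    ax.set_xlabel("lag (min)")
    ax.set_ylabel("autocorrelation")
    return _finish(fig, path)


def plot_trace_heatmap(cells: list[CorrectedTrace], path=None):
    """Per-cell smoothed signals as rows of a pseudo-colour heatmap."""
    if not cells:
        raise ValueError("no traces to plot")
    mat = np.vstack([c.smoothed for c in cells])
    fig, ax = plt.subplots(figsize=(6, 0.15 * len(cells) + 1.5))
    im = ax.imshow(
        mat, aspect="auto", cmap="jet",
        extent=[cells[0].t[0], cells[0].t[-1], len(cells), 0],
    )
    fig.colorbar(im, ax=ax, label="corrected signal")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cell")
    return _finish(fig, path)


def plot_group_composition(result: ClusterResult, path=None):
    fig, ax = plt.subplots(figsize=(4, 4))
    counts = np.bincount(result.assignments, minlength=result.k)
    ax.pie(counts, labels=[f"group {g}" for g in range(result.k)], autopct="%1.0f%%")
    return _finish(fig, path)
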