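"""Optional matplotlib renderings of the standard figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from fateinfo.information import InformationTrace
from fateinfo.survival import FateMatrix, KillingCurve


def plot_killing_curve(curve: KillingCurve, path: str | Path) -> Path:
    """Mean killing curve with a ±SD band across replicate positions."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    t = curve.time_grid
    ax.plot(t, 100 * curve.dead_fraction, color="k", lw=1.5)
    ax.fill_between(
        t,
        100 * (curve.dead_fraction - curve.sd_across_positions),
        100 * (curve.dead_fraction + curve.sd_across_positions),
        alpha=0.3,
        color="gray",
        lw=0,
    )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("dead cells (%)")
    ax.set_ylim(-2, 102)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_fate_matrix(matrix: FateMatrix, path: str | Path) -> Path:
    """Decile heatmap: cumulative % dead per covariate bin over time."""
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    im = ax.imshow(
        100 * matrix.values,
        aspect="auto",
        origin="lower",
        cmap="magma",
        extent=(matrix.time_grid[0], matrix.time_grid[-1], -0.5, matrix.n_bins - 0.5),
        vmin=0,
        vmax=100,
    )
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"{matrix.covariate_name} bin (low→high)")
    fig.colorbar(im, ax=ax, label="dead cells (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_information_trace(trace: InformationTrace, path: str | Path) -> Path:
    """Information over time with the peak marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(trace.time_grid, trace.info_bits, color="tab:blue", lw=1.5)
    ax.axvline(trace.peak_time, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("information (bits)")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
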