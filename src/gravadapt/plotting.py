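"""Diagnostic figures mirroring the model's standard panel layout: MAP
trajectory, likelihood/HML cascade, jitter width, mixture weight, particle
cloud (sized by posterior weight), and LTM density evolution."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import SimulationResult

__all__ = ["plot_adaptation", "plot_particles", "save_standard_plots"]


def plot_adaptation(result: SimulationResult, ax=None):
    """MAP gravity estimate against the true schedule."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(result.t_step, result.g_true_step, "k--", lw=1, label="actual |g|")
    ax.plot(result.t_step, result.map_g, "C0", lw=1.2, label="MAP estimate")
    ax.set_xlabel("time (model s)")
    ax.set_ylabel("|g| (g)")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_particles(result: SimulationResult, ax=None, stride: int = 1):
    """Scatter of particle positions over time, sized by posterior weight."""
    if result.particle_x is None:
        raise ValueError("particles were not stored for this run")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    k_idx = np.arange(0, result.n_steps, stride)
    for k in k_idx:
        xs = result.particle_x[k]
        uniq, counts = np.unique(xs, return_counts=True)
        ax.scatter(
            np.full(uniq.size, result.t_step[k]),
            uniq,
            s=2 + 60 * counts / counts.sum(),
            c="C0",
            alpha=0.35,
            edgecolors="none",
        )
    ax.plot(result.t_step, result.g_true_step, "k--", lw=1)
    ax.set_xlabel("time (model s)")
    ax.set_ylabel("hypotheses (g)")
    return ax


def save_standard_plots(result: SimulationResult, out_dir: str | Path) -> list[Path]:
    """Write the standard diagnostic panels as PNG files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, axes = plt.subplots(4, 1, figsize=(8, 9), sharex=True)
    plot_adaptation(result, axes[0])
    axes[1].semilogy(result.t_step, np.maximum(result.max_lik, 1e-30), "k", lw=0.8, label="max likelihood")
    axes[1].semilogy(result.t_step, np.maximum(result.hml, 1e-30), "C3", lw=1.2, label="HML")
    axes[1].set_ylabel("likelihood")
    axes[1].legend(fontsize=8)
    axes[2].plot(result.t_step, result.sigma, "C2")
    axes[2].set_ylabel(r"$\sigma_{jitter}$ (g)")
    axes[3].plot(result.t_step, result.W, "C4")
    axes[3].set_ylabel("W")
    axes[3].set_xlabel("time (model s)")
    fig.tight_layout()
    p = out / "adaptation.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if result.particle_x is not None:
        fig, ax = plt.subplots(figsize=(8, 3))
        plot_particles(result, ax)
        fig.tight_layout()
        p = out / "particles.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.imshow(
        result.ltm_mass.T,
        aspect="auto",
        origin="lower",
        extent=(result.t_step[0], result.t_step[-1], 0, result.ltm_mass.shape[1]),
        cmap="viridis",
    )
    ax.set_xlabel("time (model s)")
    ax.set_ylabel("grid bin")
    ax.set_title("LTM density")
    fig.tight_layout()
    p = out / "ltm_density.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
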