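"""Diagnostic figures: weight distributions, Levy trajectories, loss curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .heavytail import KDEConfig, kde_pdf, sample_alpha_stable, silverman_bandwidth, simulate_ou_levy
from .heavytail import StableSpec

__all__ = [
    "plot_weight_distribution",
    "plot_levy_trajectories",
    "plot_stable_densities",
    "plot_loss_curves",
]


def plot_weight_distribution(weights_by_rule: dict, path=None, ax=None):
    """Smoothed weight densities per STDP rule (Gaussian KDE)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for rule, w in weights_by_rule.items():
        w = np.asarray(w).ravel()
        grid = np.linspace(w.min(), w.max(), 256)
        pdf = kde_pdf(w, KDEConfig(t=silverman_bandwidth(w), grid=grid))
        ax.plot(grid, pdf, label=rule)
    ax.set_xlabel("synaptic weight")
    ax.set_ylabel("density")
    ax.legend()
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def plot_levy_trajectories(alphas=(2.0, 1.7, 1.4, 1.1), n_steps=2000, seed=0, path=None):
    """3-D random walks driven by alpha-stable noise, one panel per alpha."""
    fig = plt.figure(figsize=(3 * len(alphas), 3))
    for k, alpha in enumerate(alphas):
        x = simulate_ou_levy(alpha, drift_rate=0.05, scale=1.0, n_steps=n_steps,
                             dt=0.01, dims=3, seed=seed + k)
        ax = fig.add_subplot(1, len(alphas), k + 1, projection="3d")
        ax.plot(x[:, 0], x[:, 1], x[:, 2], lw=0.5)
        ax.set_title(f"alpha = {alpha}")
    if path:
        fig.savefig(path, bbox_inches="tight")
    return fig


def plot_stable_densities(alphas=(2.0, 1.7, 1.4, 1.1), n=20000, seed=0, path=None, ax=None):
    """Empirical densities of alpha-stable samples; heavier tails as alpha drops."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    grid = np.linspace(-8, 8, 400)
    for k, alpha in enumerate(alphas):
        x = sample_alpha_stable(StableSpec(alpha=alpha, scale=1.0, n=n, seed=seed + k))
        x = x[np.abs(x) < 50]
        pdf = kde_pdf(x, KDEConfig(t=silverman_bandwidth(x), grid=grid))
        ax.plot(grid, pdf, label=f"alpha = {alpha}")
    ax.set_yscale("log")
    ax.set_xlabel("x")
    ax.set_ylabel("density")
    ax.legend()
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def plot_loss_curves(loss_table, path=None, ax=None):
    """Per-iteration training loss with repeat spread.

    ``loss_table`` is an iterable of (label, iterations, mean, spread).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for label, iters, mean, spread in loss_table:
        iters, mean, spread = map(np.asarray, (iters, mean, spread))
        ax.plot(iters, mean, label=label)
        ax.fill_between(iters, mean - spread, mean + spread, alpha=0.25)
    ax.set_xlabel("training iteration")
    ax.set_ylabel("cross-entropy loss")
    ax.legend()
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
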