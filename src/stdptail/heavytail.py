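"""Heavy-tailed process toolkit.

The learning trajectory of an STDP-trained network is modelled as an
Ornstein-Uhlenbeck process driven by alpha-stable Levy noise.  The
roughness of its sample paths — and through it the generalization
behaviour of the trained model — is summarised by the Blumenthal-Getoor
(BG) index, the maximum over network layers of the tail index ``alpha`` of
the weight-update increments.  ``alpha`` lies in (0, 2]: 2 is the Gaussian
(Brownian) boundary, smaller values mean heavier tails.

This module provides

* a symmetric alpha-stable sampler (Chambers-Mallows-Stuck construction),
* Euler-Maruyama simulation of Levy-driven OU trajectories,
* a jump-SDE simulator for the membrane potential of a single synapse
  driven by Poisson presynaptic spikes and state-dependent postsynaptic
  firing,
* the block log-moment tail-index estimator and the BG index built on it,
* a plain Gaussian kernel density estimator for weight distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "StableSpec",
    "TailReport",
    "KDEConfig",
    "sample_alpha_stable",
    "simulate_ou_levy",
    "simulate_membrane_sde",
    "estimate_tail_index",
    "bg_index",
    "kde_pdf",
    "silverman_bandwidth",
]


@dataclass
class StableSpec:
    """Parameters for symmetric alpha-stable sampling."""

    alpha: float
    scale: float = 1.0
    n: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 2.0:
            raise ValueError("alpha must lie in (0, 2]")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass
class KDEConfig:
    """Gaussian KDE settings: bandwidth ``t`` is the kernel *variance*."""

    t: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("bandwidth t must be > 0")
        self.grid = np.asarray(self.grid, dtype=float)


@dataclass
class TailReport:
    """Per-group tail indices and their maximum, the BG index."""

    alpha_hat: dict
    bg_index: float
    m: int
    K: dict
    clipped: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def sample_alpha_stable(spec: StableSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw symmetric alpha-stable deviates (Chambers-Mallows-Stuck).

    For ``alpha == 2`` this reduces to a Gaussian with variance
    ``2 * scale**2``; for ``alpha == 1`` to a Cauchy with the given scale.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    alpha = spec.alpha
    U = rng.uniform(-math.pi / 2, math.pi / 2, size=spec.n)
    W = rng.exponential(1.0, size=spec.n)
    if alpha == 1.0:
        X = np.tan(U)
    else:
        X = (
            np.sin(alpha * U)
            / np.cos(U) ** (1.0 / alpha)
            * (np.cos(U - alpha * U) / W) ** ((1.0 - alpha) / alpha)
        )
    return spec.scale * X


def simulate_ou_levy(
    alpha: float,
    drift_rate: float,
    scale: float,
    n_steps: int,
    dt: float,
    dims: int = 1,
    seed: int | None = None,
    x0: float = 0.0,
) -> np.ndarray:
    """Euler-Maruyama trajectory of a Levy-driven OU process.

    Iterates ``x_{k+1} = x_k - drift_rate*x_k*dt + scale*dt^{1/alpha}*L_k``
    with ``L_k`` iid symmetric alpha-stable.  Returns an array of shape
    (n_steps + 1, dims); ``dims=3`` reproduces the classic 3-D random-walk
    illustration of heavy-tailed trajectories.
    """
    if drift_rate < 0:
        raise ValueError("drift_rate must be >= 0")
    rng = np.random.default_rng(seed)
    spec = StableSpec(alpha=alpha, scale=1.0, n=n_steps * dims)
    L = sample_alpha_stable(spec, rng).reshape(n_steps, dims)
    x = np.empty((n_steps + 1, dims))
    x[0] = x0
    step_scale = scale * dt ** (1.0 / alpha)
    for k in range(n_steps):
        x[k + 1] = x[k] - drift_rate * x[k] * dt + step_scale * L[k]
    return x


def simulate_membrane_sde(
    W: float,
    lambda_pre: float,
    tau: float,
    beta_fn: Callable[[float], float] | None = None,
    g_drop_fn: Callable[[float], float] | None = None,
    T: float = 1000.0,
    dt: float = 0.1,
    seed: int | None = None,
    x0: float = 0.0,
):
    """Single-synapse membrane potential driven by Poisson input.

    Simulates ``dX = -X/tau dt + W dN_lambda - g(X-) dN_{beta,X}`` where
    ``N_lambda`` is a homogeneous Poisson process of presynaptic spikes at
    rate ``lambda_pre`` (each adds ``W`` to X) and the postsynaptic neuron
    fires as an inhomogeneous Poisson process with intensity ``beta_fn(X)``,
    dropping the potential by ``g_drop_fn(X)``.  Rates are per unit of the
    same time unit as ``tau``/``T``/``dt``.

    With ``beta_fn`` absent the process is filtered shot noise with
    stationary mean ``W * lambda_pre * tau``.

    Returns ``(times, path, post_spike_times)``.
    """
    if lambda_pre < 0:
        raise ValueError("lambda_pre must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    decay = math.exp(-dt / tau)
    times = np.arange(n_steps + 1) * dt
    path = np.empty(n_steps + 1)
    path[0] = x0
    x = x0
    post_times = []
    for k in range(n_steps):
        # exact leak over dt, then jumps accumulated within the step
        x *= decay
        if lambda_pre > 0:
            n_pre = rng.poisson(lambda_pre * dt)
            if n_pre:
                x += W * n_pre
        if beta_fn is not None:
            rate = beta_fn(x)
            if rate > 0 and rng.random() < -math.expm1(-rate * dt):
                drop = g_drop_fn(x) if g_drop_fn is not None else x
                x -= drop
                post_times.append(times[k + 1])
        path[k + 1] = x
    return times, path, np.asarray(post_times)


def estimate_tail_index(increments, m: int | None = None) -> float:
    """Block log-moment estimate of the stability (tail) index alpha.

    The input values are centered by their mean and partitioned into K
    blocks of size ``m`` (default ``floor(sqrt(N))``); with block sums
    ``Y_j`` the estimator is

        1/alpha = (1/log m) * [ mean_j log|Y_j| - mean_i log|X_i| ]

    which is exact in expectation for iid alpha-stable data because the sum
    of m stable deviates scales like ``m^{1/alpha}``.  The estimate is
    clipped into (0, 2].
    """
    X = np.asarray(increments, dtype=float).ravel()
    if X.size < 40:
        raise ValueError("need at least 40 increments for a stable estimate")
    X = X - X.mean()
    N = X.size
    if m is None:
        m = int(math.isqrt(N))
    if m < 2:
        raise ValueError("block size m must be >= 2")
    K = N // m
    if K < 20:
        raise ValueError(f"need at least 20 blocks (got {K}); reduce m")
    used = K * m
    if used < N:
        warnings.warn(f"dropping {N - used} trailing values not filling a block")
    X = X[:used]
    # guard exact zeros before taking logs
    eps = np.finfo(float).tiny
    absX = np.maximum(np.abs(X), eps)
    Y = X.reshape(K, m).sum(axis=1)
    absY = np.maximum(np.abs(Y), eps)
    inv_alpha = (np.log(absY).mean() - np.log(absX).mean()) / math.log(m)
    if inv_alpha <= 0:
        return 2.0
    return float(min(1.0 / inv_alpha, 2.0))


def bg_index(
    trajectory,
    grouping: Mapping[str, np.ndarray] | None = None,
    m: int | None = None,
    last_k: int = 1,
) -> TailReport:
    """BG index of a weight trajectory: max over groups of the tail index.

    ``trajectory`` is either a ``WeightTrajectory`` (anything exposing
    ``snapshots`` as an (n_iter+1, n_weights) array) or a raw 2-D snapshot
    array.  The tail index is estimated from the final-iteration increment
    vector (last snapshot minus the previous one), the point at which the
    network has learned its representations and the weight dynamics
    diffuse around a local minimum.  ``grouping`` maps group labels to
    index arrays into the flattened weight vector; by default the single
    plastic layer forms one group.

    ``last_k`` pools the increment vectors of the final ``last_k``
    iterations into one estimate.  At desk scale a single iteration's
    estimate fluctuates by about +-0.1 from iteration to iteration simply
    because only ~100 neurons share the work; pooling the final few
    iterations damps that finite-size noise while still measuring the
    post-convergence dynamics.  Full-scale runs can keep ``last_k=1``.
    """
    snaps = getattr(trajectory, "snapshots", trajectory)
    snaps = np.asarray(snaps, dtype=float)
    if snaps.ndim != 2 or snaps.shape[0] < 2:
        raise ValueError("trajectory must contain at least 2 snapshots")
    if not 1 <= last_k <= snaps.shape[0] - 1:
        raise ValueError("last_k must be in [1, n_increments]")
    final_inc = np.concatenate(
        [snaps[k] - snaps[k - 1] for k in range(snaps.shape[0] - last_k, snaps.shape[0])]
    )
    n_per = snaps.shape[1]
    if grouping is None:
        grouping = {"input_to_exc": np.arange(n_per)}
    # expand group indices across the pooled iterations
    grouping = {
        label: (np.asarray(idx)[None, :] + n_per * np.arange(last_k)[:, None]).ravel()
        for label, idx in grouping.items()
    }
    alpha_hat: dict = {}
    Ks: dict = {}
    clipped: dict = {}
    flags: list = []
    m_used = m
    for label, idx in grouping.items():
        vals = final_inc[np.asarray(idx)]
        if np.allclose(vals, vals.flat[0]):
            flags.append(f"group {label!r}: constant increments, tail index undefined")
            alpha_hat[label] = float("nan")
            Ks[label] = 0
            continue
        mm = m_used if m_used is not None else int(math.isqrt(vals.size))
        a = estimate_tail_index(vals, m=mm)
        alpha_hat[label] = a
        Ks[label] = vals.size // mm
        clipped[label] = a == 2.0
        m_used = mm
    finite = [a for a in alpha_hat.values() if np.isfinite(a)]
    if not finite:
        raise ValueError("no group produced a finite tail index: " + "; ".join(flags))
    return TailReport(
        alpha_hat=alpha_hat,
        bg_index=float(max(finite)),
        m=int(m_used) if m_used else 0,
        K=Ks,
        clipped=clipped,
        flags=flags,
    )


def silverman_bandwidth(values) -> float:
    """Silverman's rule-of-thumb bandwidth, returned as kernel *variance*."""
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 2:
        return 1.0
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    if s == 0:
        s = max(abs(x[0]), 1.0)
    h = 0.9 * s * n ** (-0.2)
    return float(h * h)


def kde_pdf(values, cfg: KDEConfig) -> np.ndarray:
    """Gaussian kernel density estimate on ``cfg.grid``.

    f_hat(x; t) = (1/N) sum_i (2 pi t)^{-1/2} exp(-(x - X_i)^2 / (2 t)).
    """
    X = np.asarray(values, dtype=float).ravel()
    if X.size == 0:
        raise ValueError("need at least one value")
    t = cfg.t
    diff = cfg.grid[:, None] - X[None, :]
    return np.exp(-(diff**2) / (2.0 * t)).sum(axis=1) / (X.size * math.sqrt(2.0 * math.pi * t))
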