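"""Spike-timing-dependent plasticity rules.

Three classical pair-based STDP variants are implemented through their
scaling functions ``a_plus`` (LTP) and ``a_minus`` (LTD):

* **add** — additive STDP: both scaling functions are weight independent
  (``a+ = c+``, ``a- = c-``).  Requires hard weight bounds for stability;
  with ``c+ tau+ < c- tau-`` depression dominates and weights drift toward
  zero under uncorrelated activity.
* **mult** — multiplicative STDP: linear weight dependence for depression
  (``a- = c- W``) and constant potentiation.
* **log** — logarithmic STDP: potentiation decays exponentially in the
  weight, depression grows linearly below the fixed point ``W0`` and
  saturates logarithmically above it, with saturation degree ``S``.  The
  log rule interpolates between the other two: it coincides with the mult
  rule as ``S -> 0, gamma -> inf`` and approaches the add rule (flat LTD)
  as ``S -> inf``.

A single pairing event with pre-minus-post lag ``u`` changes the weight by

    dW = eta * (1 + zeta) * H(W; u)

where ``zeta ~ N(0, sigma^2)`` is multiplicative update noise and the STDP
window ``H`` applies ``a_plus``/``a_minus`` with exponential time kernels
``exp(-|u|/tau_plus)`` / ``exp(-|u|/tau_minus)``.

For network simulation the same pair rule is realised online through
additive synaptic traces (all-to-all pairing): every pre spike bumps the
presynaptic trace by ``A_pre0`` and triggers depression proportional to the
postsynaptic trace; every post spike bumps the postsynaptic trace by
``A_post0`` and triggers potentiation proportional to the presynaptic
trace.  For an isolated spike pair the trace formulation reproduces the
pair rule exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "STDPConfig",
    "TraceState",
    "a_plus",
    "a_minus",
    "stdp_window",
    "delta_w",
    "on_pre_spike",
    "on_post_spike",
    "decay_traces",
]

_RULES = ("add", "mult", "log")

# Default log-rule LTD amplitude: the fixed-point calibration
# tau+ * a+(W0) = tau- * a-(W0)  =>  c- = (tau+/tau-) * c+ * exp(-1/gamma)
_LOG_C_MINUS = 0.5 * math.exp(-1.0 / 50.0)


@dataclass
class STDPConfig:
    """Full hyperparameter set for one STDP rule.

    Defaults follow the reference benchmark configuration: learning rate
    ``eta`` 2e-4, window constants ``tau_plus`` 17 ms / ``tau_minus`` 34 ms,
    trace increments ``A_pre0`` 1.0 and ``A_post0`` 0.5 (0.55 for the add
    rule), and for the log rule ``S`` = 5, ``gamma`` = 50, ``W0`` = 0.006.
    Network-training presets use a larger ``eta`` and a ``W0`` on the scale
    of the weight bounds; see :func:`for_rule`.
    """

    rule: str = "log"
    eta: float = 0.0002
    sigma: float = 0.0
    c_plus: float = 1.0
    c_minus: float = _LOG_C_MINUS
    tau_plus: float = 17.0
    tau_minus: float = 34.0
    S: float = 5.0
    gamma: float = 50.0
    W0: float = 0.006
    w_min: float = 0.0
    w_max: float = 1.0
    A_pre0: float = 1.0
    A_post0: float = 0.5
    truncate_noise: bool = False

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"unknown STDP rule {self.rule!r}; expected one of {_RULES}")
        if self.eta < 0:
            raise ValueError("eta must be >= 0 (0 freezes learning)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.c_plus <= 0 or self.c_minus <= 0:
            raise ValueError("c_plus and c_minus must be > 0")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("tau_plus and tau_minus must be > 0")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be < w_max")
        if self.rule == "log":
            if self.S <= 0 or self.gamma <= 0 or self.W0 <= 0:
                raise ValueError("log rule requires S > 0, gamma > 0, W0 > 0")

    @property
    def sfr(self) -> float:
        """Scaling-function ratio c+/c-, the LTP/LTD amplitude ratio."""
        return self.c_plus / self.c_minus

    def with_sfr(self, sfr: float) -> "STDPConfig":
        """Return a copy with c_plus set so that c+/c- equals ``sfr``."""
        return replace(self, c_plus=sfr * self.c_minus)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "STDPConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown STDPConfig keys: {sorted(unknown)}")
        rule = doc.get("rule", "log")
        if rule != "log":
            bad = {"S", "gamma"} & set(doc)
            if bad:
                raise ValueError(
                    f"keys {sorted(bad)} only apply to the log rule, not {rule!r}"
                )
        return cls(**doc)

    @classmethod
    def from_json(cls, text: str) -> "STDPConfig":
        return cls.from_dict(json.loads(text))

    @classmethod
    def for_rule(cls, rule: str, **overrides) -> "STDPConfig":
        """Benchmark defaults per rule (add: c-=0.6, A_post0=0.55; mult: c-=2)."""
        base: dict = {"rule": rule}
        if rule == "add":
            base.update(c_minus=0.6, A_post0=0.55)
        elif rule == "mult":
            base.update(c_minus=2.0, A_post0=0.5)
        base.update(overrides)
        return cls(**base)


@dataclass
class TraceState:
    """Pre-/post-synaptic trace values used by the online implementation."""

    x_pre: np.ndarray
    x_post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(np.zeros(n_pre), np.zeros(n_post))


def a_plus(W, cfg: STDPConfig):
    """LTP scaling function a+(W)."""
    W = np.asarray(W, dtype=float)
    if cfg.rule in ("add", "mult"):
        return np.broadcast_to(np.float64(cfg.c_plus), W.shape).copy() if W.shape else np.float64(cfg.c_plus)
    return cfg.c_plus * np.exp(-W / (cfg.W0 * cfg.gamma))


def a_minus(W, cfg: STDPConfig):
    """LTD scaling function a-(W)."""
    W = np.asarray(W, dtype=float)
    if cfg.rule == "add":
        return np.broadcast_to(np.float64(cfg.c_minus), W.shape).copy() if W.shape else np.float64(cfg.c_minus)
    if cfg.rule == "mult":
        return cfg.c_minus * W
    # log rule: linear below W0, log-saturating above
    r = W / cfg.W0
    below = cfg.c_minus * r
    with np.errstate(invalid="ignore"):
        above = cfg.c_minus * (1.0 + np.log1p(cfg.S * (r - 1.0)) / cfg.S)
    return np.where(r <= 1.0, below, above)


def stdp_window(W, u, cfg: STDPConfig):
    """Pair-based STDP window H(W; u) with u = t_pre - t_post.

    Negative lags (pre before post) potentiate, positive lags depress.
    An exact tie u = 0 is treated as potentiation (simultaneous events are
    artifacts of the discrete simulation clock).
    """
    u = np.asarray(u, dtype=float)
    ltp = a_plus(W, cfg) * np.exp(-np.abs(u) / cfg.tau_plus)
    ltd = -a_minus(W, cfg) * np.exp(-np.abs(u) / cfg.tau_minus)
    return np.where(u <= 0.0, ltp, ltd)


def delta_w(W, u, cfg: STDPConfig, rng: np.random.Generator):
    """Noisy weight increment eta*(1+zeta)*H(W;u), clipped into bounds.

    ``zeta`` is drawn independently per element; the returned increment is
    clipped so that W + dW stays within [w_min, w_max].
    """
    W = np.asarray(W, dtype=float)
    H = stdp_window(W, u, cfg)
    zeta = rng.normal(0.0, cfg.sigma, size=np.shape(H)) if cfg.sigma > 0 else 0.0
    if cfg.truncate_noise and cfg.sigma > 0:
        zeta = np.maximum(zeta, -1.0)
    dW = cfg.eta * (1.0 + zeta) * H
    return np.clip(W + dW, cfg.w_min, cfg.w_max) - W


def decay_traces(traces: TraceState, dt: float, cfg: STDPConfig) -> TraceState:
    """Exponential trace decay over one time step of length ``dt`` ms."""
    return TraceState(
        traces.x_pre * math.exp(-dt / cfg.tau_plus),
        traces.x_post * math.exp(-dt / cfg.tau_minus),
    )


def on_pre_spike(
    traces: TraceState,
    weights: np.ndarray,
    pre_idx,
    cfg: STDPConfig,
    rng: np.random.Generator | None = None,
):
    """Process presynaptic spikes: bump x_pre and depress their synapses.

    ``weights`` has shape (n_pre, n_post); rows ``pre_idx`` are depressed in
    proportion to the postsynaptic trace through ``a_minus``.
    """
    pre_idx = np.atleast_1d(np.asarray(pre_idx, dtype=int))
    if pre_idx.size == 0:
        return traces, weights
    x_pre = traces.x_pre.copy()
    x_pre[pre_idx] += cfg.A_pre0
    w = weights.copy()
    rows = w[pre_idx, :]
    dW = cfg.eta * a_minus(rows, cfg) * traces.x_post[None, :]
    if cfg.sigma > 0:
        if rng is None:
            raise ValueError("rng required when sigma > 0")
        zeta = rng.normal(0.0, cfg.sigma, size=dW.shape)
        if cfg.truncate_noise:
            zeta = np.maximum(zeta, -1.0)
        dW = dW * (1.0 + zeta)
    w[pre_idx, :] = np.clip(rows - dW, cfg.w_min, cfg.w_max)
    return TraceState(x_pre, traces.x_post), w


def on_post_spike(
    traces: TraceState,
    weights: np.ndarray,
    post_idx,
    cfg: STDPConfig,
    rng: np.random.Generator | None = None,
):
    """Process postsynaptic spikes: bump x_post and potentiate their synapses."""
    post_idx = np.atleast_1d(np.asarray(post_idx, dtype=int))
    if post_idx.size == 0:
        return traces, weights
    x_post = traces.x_post.copy()
    x_post[post_idx] += cfg.A_post0
    w = weights.copy()
    cols = w[:, post_idx]
    dW = cfg.eta * a_plus(cols, cfg) * traces.x_pre[:, None]
    if cfg.sigma > 0:
        if rng is None:
            raise ValueError("rng required when sigma > 0")
        zeta = rng.normal(0.0, cfg.sigma, size=dW.shape)
        if cfg.truncate_noise:
            zeta = np.maximum(zeta, -1.0)
        dW = dW * (1.0 + zeta)
    w[:, post_idx] = np.clip(cols + dW, cfg.w_min, cfg.w_max)
    return TraceState(traces.x_pre, x_post), w
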