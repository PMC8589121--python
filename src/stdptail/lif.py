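"""Conductance-based leaky integrate-and-fire network simulation.

Two-layer architecture for unsupervised digit learning: an input layer of
Poisson units (one per pixel) projects all-to-all through plastic synapses
onto an excitatory layer; each excitatory neuron drives one partner
inhibitory neuron, and each inhibitory neuron projects back onto every
excitatory neuron except its partner.  The lateral inhibition creates
competition among excitatory neurons, and an adaptive firing threshold
(homeostasis) keeps their long-run firing rates comparable.

The membrane potential X of each neuron follows

    tau dX/dt = (E_rest - X) + g_e (E_exc - X) + g_i (E_inh - X)

with conductances that jump by the synaptic weight on each presynaptic
spike and otherwise decay exponentially (tau_g dg/dt = -g).  Integration
is clock-driven explicit Euler for the membrane; the conductance, adaptive
threshold and trace decays use exact exponential factors, so the only
O(dt) error lives in the membrane step.  Default dt is 0.5 ms.

The excitatory firing threshold is ``v_thresh + theta``; theta increases
by ``theta_inc`` on every spike and decays with time constant
``tau_theta``, so neurons that dominate the response become harder to
excite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import stdp as stdp_mod
from .stdp import STDPConfig, TraceState
from ._kernels import presentation_kernel

__all__ = [
    "NeuronParams",
    "NeuronState",
    "NetworkTopology",
    "IntegrationFault",
    "step_membrane",
    "deliver_spikes",
    "fire_and_reset",
    "build_network",
    "run_presentation",
    "relax_state",
]


class IntegrationFault(RuntimeError):
    """Raised when the integrator produces non-finite state."""

    def __init__(self, message: str, neuron_index: int):
        super().__init__(message)
        self.neuron_index = neuron_index


@dataclass
class NeuronParams:
    """LIF parameters for one population (all times in ms, potentials in mV).

    Defaults for the excitatory and inhibitory populations follow the
    reference two-layer implementation and are exposed through
    :meth:`excitatory` / :meth:`inhibitory`.
    """

    tau_m: float = 100.0
    E_rest: float = -65.0
    E_exc: float = 0.0
    E_inh: float = -100.0
    v_thresh: float = -52.0
    v_reset: float = -65.0
    t_refrac: float = 5.0
    tau_ge: float = 1.0
    tau_gi: float = 2.0
    theta_inc: float = 0.05
    tau_theta: float = 1.0e5

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_ge <= 0 or self.tau_gi <= 0 or self.tau_theta <= 0:
            raise ValueError("time constants must be > 0")
        if not (self.E_inh < self.E_rest < self.v_thresh < self.E_exc):
            raise ValueError("need E_inh < E_rest < v_thresh < E_exc")
        if self.t_refrac < 0 or self.theta_inc < 0:
            raise ValueError("t_refrac and theta_inc must be >= 0")

    @classmethod
    def excitatory(cls, **overrides) -> "NeuronParams":
        return cls(**overrides)

    @classmethod
    def inhibitory(cls, **overrides) -> "NeuronParams":
        base = dict(
            tau_m=10.0, E_rest=-60.0, E_exc=0.0, E_inh=-85.0,
            v_thresh=-40.0, v_reset=-45.0, t_refrac=2.0,
            theta_inc=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class NeuronState:
    """Dynamic state of one population."""

    X: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    theta: np.ndarray
    refrac_until: np.ndarray  # absolute time (ms) until which firing is forbidden
    spike_count: np.ndarray

    @classmethod
    def resting(cls, n: int, params: NeuronParams) -> "NeuronState":
        return cls(
            X=np.full(n, params.E_rest, dtype=float),
            g_e=np.zeros(n),
            g_i=np.zeros(n),
            theta=np.zeros(n),
            refrac_until=np.zeros(n),
            spike_count=np.zeros(n, dtype=np.int64),
        )

    def copy(self) -> "NeuronState":
        return NeuronState(*(a.copy() for a in (
            self.X, self.g_e, self.g_i, self.theta, self.refrac_until, self.spike_count)))


@dataclass
class NetworkTopology:
    """Connectivity and weights of the two-layer network.

    ``input_to_exc`` is the dense plastic matrix; the excitatory-to-
    inhibitory projection is one-to-one with fixed weight ``w_ei``; the
    inhibitory-to-excitatory projection is all-to-all-except-partner with
    fixed weight ``w_ie``.
    """

    n_input: int
    n_exc: int
    input_to_exc: np.ndarray
    w_ei: float = 10.4
    w_ie: float = 17.0
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        self.input_to_exc = np.asarray(self.input_to_exc, dtype=float)
        if self.input_to_exc.shape != (self.n_input, self.n_exc):
            raise ValueError("input_to_exc must have shape (n_input, n_exc)")

    @property
    def n_inh(self) -> int:
        return self.n_exc

    def partner(self, i: int) -> int:
        """The excitatory partner of inhibitory neuron i (a bijection)."""
        return i

    def inh_to_exc_pairs(self):
        """Iterate (inh, exc) connection pairs: all except the partner."""
        for i in range(self.n_inh):
            for j in range(self.n_exc):
                if j != i:
                    yield (i, j)

    def n_inh_to_exc(self) -> int:
        return self.n_inh * (self.n_exc - 1)

    def copy(self) -> "NetworkTopology":
        return replace(self, input_to_exc=self.input_to_exc.copy())


def build_network(
    n_input: int,
    n_exc: int,
    fixed_weights: tuple[float, float] = (10.4, 17.0),
    init_seed: int | None = None,
    w_min: float = 0.0,
    w_max: float = 1.0,
) -> NetworkTopology:
    """Fresh topology with plastic weights uniform in [w_min, w_max]."""
    if n_exc < 2:
        raise ValueError("n_exc must be >= 2 (lateral inhibition needs a non-partner)")
    rng = np.random.default_rng(init_seed)
    W = rng.uniform(w_min, w_max, size=(n_input, n_exc))
    return NetworkTopology(
        n_input=n_input, n_exc=n_exc, input_to_exc=W,
        w_ei=fixed_weights[0], w_ie=fixed_weights[1],
        w_min=w_min, w_max=w_max,
    )


# ---------------------------------------------------------------------------
# Fine-grained operations (pure-numpy reference semantics)


def step_membrane(
    state: NeuronState,
    params: NeuronParams,
    dt: float,
    t_now: float = 0.0,
) -> NeuronState:
    """One explicit-Euler membrane step plus exact conductance decay.

    Neurons inside their refractory window stay clamped at ``v_reset``.
    Raises :class:`IntegrationFault` naming the first offending neuron if
    the state goes non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > params.tau_m / 5.0:
        raise ValueError(f"dt={dt} too large for membrane tau_m={params.tau_m}")
    out = state.copy()
    refractory = state.refrac_until > t_now
    drive = (
        (params.E_rest - state.X)
        + state.g_e * (params.E_exc - state.X)
        + state.g_i * (params.E_inh - state.X)
    )
    out.X = np.where(refractory, params.v_reset, state.X + (dt / params.tau_m) * drive)
    out.g_e = state.g_e * math.exp(-dt / params.tau_ge)
    out.g_i = state.g_i * math.exp(-dt / params.tau_gi)
    bad = ~np.isfinite(out.X)
    if bad.any():
        idx = int(np.argmax(bad))
        raise IntegrationFault(f"non-finite membrane potential at neuron {idx}", idx)
    return out


def deliver_spikes(
    state: NeuronState,
    weights: np.ndarray,
    pre_spikes,
    synapse_kind: str = "excitatory",
) -> NeuronState:
    """Add the connecting weights to the conductances of the targets.

    ``weights`` has shape (n_pre, n_post); rows indexed by ``pre_spikes``
    are summed into g_e (excitatory synapses) or g_i (inhibitory).  The
    membrane potential is untouched.
    """
    pre_spikes = np.atleast_1d(np.asarray(pre_spikes, dtype=int))
    out = state.copy()
    if pre_spikes.size == 0:
        return out
    weights = np.asarray(weights, dtype=float)
    if (weights[pre_spikes] < 0).any():
        raise ValueError("negative synaptic weight delivered; invariant violated")
    increment = weights[pre_spikes, :].sum(axis=0)
    if synapse_kind == "excitatory":
        out.g_e = state.g_e + increment
    elif synapse_kind == "inhibitory":
        out.g_i = state.g_i + increment
    else:
        raise ValueError(f"unknown synapse kind {synapse_kind!r}")
    return out


def fire_and_reset(
    state: NeuronState,
    params: NeuronParams,
    t_now: float,
    dt: float | None = None,
):
    """Threshold check, spike emission, reset and homeostatic update.

    Neurons with X >= v_thresh + theta that are out of their refractory
    window fire: X -> v_reset, theta += theta_inc, refractory until
    t_now + t_refrac.  Afterwards theta of *all* neurons decays one step
    (skipped when ``dt`` is None).  Returns ``(state, spike_indices)``.
    """
    out = state.copy()
    eligible = (state.X >= params.v_thresh + state.theta) & (state.refrac_until <= t_now)
    spikes = np.flatnonzero(eligible)
    if spikes.size:
        out.X[spikes] = params.v_reset
        out.theta[spikes] = out.theta[spikes] + params.theta_inc
        out.refrac_until[spikes] = t_now + params.t_refrac
        out.spike_count[spikes] += 1
    if dt is not None:
        out.theta = out.theta * math.exp(-dt / params.tau_theta)
    return out, spikes


def relax_state(
    exc: NeuronState,
    inh: NeuronState,
    exc_params: NeuronParams,
    inh_params: NeuronParams,
    traces: TraceState | None,
    cfg: STDPConfig | None,
    interval: float,
):
    """Closed-form relaxation over a silent interval (no input).

    With zero input every state variable decays independently once the
    conductances have emptied; the interval (default 150 ms) is two orders
    of magnitude above tau_g, so conductances are damped to ~0 and the
    membrane relaxes toward E_rest with tau_m.  Exact for g, theta and the
    traces; the membrane closed form neglects the residual conductance
    drive inside the first few ms of silence.
    """
    def _relax(state: NeuronState, p: NeuronParams) -> NeuronState:
        out = state.copy()
        out.X = p.E_rest + (state.X - p.E_rest) * math.exp(-interval / p.tau_m)
        out.g_e = state.g_e * math.exp(-interval / p.tau_ge)
        out.g_i = state.g_i * math.exp(-interval / p.tau_gi)
        out.theta = state.theta * math.exp(-interval / p.tau_theta)
        out.refrac_until = np.zeros_like(state.refrac_until)
        return out

    exc2, inh2 = _relax(exc, exc_params), _relax(inh, inh_params)
    if traces is not None and cfg is not None:
        traces = TraceState(
            traces.x_pre * math.exp(-interval / cfg.tau_plus),
            traces.x_post * math.exp(-interval / cfg.tau_minus),
        )
    return exc2, inh2, traces


class BoostDivergence(RuntimeError):
    """Raised when rate boosting cannot elicit the minimum spike count."""


def _run_numpy(
    topology, exc_params, inh_params, cfg, input_spikes, dt, t0,
    exc, inh, traces, rng,
):
    """Reference presentation loop composed from the fine-grained ops.

    Mirrors the kernel ordering step for step; used for cross-checking the
    numba path on small problems.
    """
    W = topology.input_to_exc
    n_exc = topology.n_exc
    pend_gi_e = np.zeros(n_exc)
    pend_ge_i = np.zeros(n_exc)
    plastic = cfg is not None
    n_steps = input_spikes.shape[0]
    total = 0
    for step in range(n_steps):
        t_now = t0 + step * dt
        exc.g_i = exc.g_i + pend_gi_e
        inh.g_e = inh.g_e + pend_ge_i
        pend_gi_e = np.zeros(n_exc)
        pend_ge_i = np.zeros(n_exc)

        pre = np.flatnonzero(input_spikes[step])
        if pre.size:
            exc = deliver_spikes(exc, W, pre, "excitatory")
            if plastic:
                traces, W = stdp_mod.on_pre_spike(traces, W, pre, cfg, rng)

        exc = step_membrane(exc, exc_params, dt, t_now)
        inh = step_membrane(inh, inh_params, dt, t_now)

        exc, exc_spikes = fire_and_reset(exc, exc_params, t_now, dt=None)
        if exc_spikes.size:
            total += exc_spikes.size
            pend_ge_i[exc_spikes] += topology.w_ei
            if plastic:
                traces, W = stdp_mod.on_post_spike(traces, W, exc_spikes, cfg, rng)
        inh, inh_spikes = fire_and_reset(inh, inh_params, t_now, dt=None)
        for k in inh_spikes:
            pend_gi_e += topology.w_ie
            pend_gi_e[k] -= topology.w_ie

        exc.theta = exc.theta * math.exp(-dt / exc_params.tau_theta)
        if plastic:
            traces = stdp_mod.decay_traces(traces, dt, cfg)
    topology.input_to_exc = W
    return total, exc, inh, traces


def run_presentation(
    topology: NetworkTopology,
    exc_params: NeuronParams,
    inh_params: NeuronParams,
    stdp: STDPConfig | None,
    rates: np.ndarray,
    duration: float = 350.0,
    dt: float = 0.5,
    rng: np.random.Generator | int | None = None,
    exc_state: NeuronState | None = None,
    inh_state: NeuronState | None = None,
    traces: TraceState | None = None,
    min_spikes: int = 5,
    boost_hz: float = 32.0,
    rate_ceiling: float = 63.75,
    boost_cap: int = 20,
    rest_interval: float = 150.0,
    backend: str = "numba",
):
    """Present one rate-coded stimulus to the network.

    The per-pixel ``rates`` (Hz) drive independent Poisson trains for
    ``duration`` ms.  If the excitatory layer emits fewer than
    ``min_spikes`` spikes, the rate ceiling is raised by ``boost_hz`` Hz
    (all pixel rates rescaled proportionally) and the stimulus is
    re-presented after a silent ``rest_interval``; this repeats up to
    ``boost_cap`` times before a :class:`BoostDivergence` is raised.  A
    final rest interval relaxes all dynamic variables before the next
    stimulus.  With ``stdp=None`` the weights are frozen.

    Returns ``(spike_counts, topology, carry)`` where ``carry`` is the
    ``(exc_state, inh_state, traces)`` triple to thread into the next call.
    Weights are modified on a copy; the input topology is untouched.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    topo = topology.copy()
    exc = exc_state.copy() if exc_state is not None else NeuronState.resting(topo.n_exc, exc_params)
    inh = inh_state.copy() if inh_state is not None else NeuronState.resting(topo.n_inh, inh_params)
    if traces is None:
        traces = TraceState.zeros(topo.n_input, topo.n_exc)
    else:
        traces = TraceState(traces.x_pre.copy(), traces.x_post.copy())
    n_steps = int(round(duration / dt))
    counts_before = exc.spike_count.copy()

    for boost in range(boost_cap + 1):
        scale = (rate_ceiling + boost_hz * boost) / rate_ceiling
        p = np.clip(rates * scale * dt / 1000.0, 0.0, 1.0)
        raster = rng.random((n_steps, rates.size)) < p[None, :]
        if backend == "numba":
            cfg = stdp
            noise_seed = int(rng.integers(0, 2**31 - 1)) if (cfg and cfg.sigma > 0) else -1
            rule_code = {"add": 0, "mult": 1, "log": 2}[cfg.rule] if cfg else 0
            total = presentation_kernel(
                noise_seed, dt, raster.astype(np.uint8), topo.input_to_exc,
                topo.w_ei, topo.w_ie,
                exc_params.tau_m, exc_params.E_rest, exc_params.E_exc, exc_params.E_inh,
                exc_params.v_thresh, exc_params.v_reset, exc_params.t_refrac,
                exc_params.tau_ge, exc_params.tau_gi,
                exc_params.theta_inc, exc_params.tau_theta,
                inh_params.tau_m, inh_params.E_rest, inh_params.E_exc, inh_params.E_inh,
                inh_params.v_thresh, inh_params.v_reset, inh_params.t_refrac,
                exc.X, exc.g_e, exc.g_i, exc.theta,
                _refrac_remaining(exc, dt),
                inh.X, inh.g_e, _refrac_remaining(inh, dt),
                traces.x_pre, traces.x_post,
                cfg is not None, rule_code,
                cfg.eta if cfg else 0.0, cfg.sigma if cfg else 0.0,
                cfg.c_plus if cfg else 1.0, cfg.c_minus if cfg else 1.0,
                cfg.tau_plus if cfg else 17.0, cfg.tau_minus if cfg else 34.0,
                cfg.S if cfg else 1.0, cfg.gamma if cfg else 1.0,
                cfg.W0 if cfg else 1.0,
                topo.w_min, topo.w_max,
                cfg.A_pre0 if cfg else 1.0, cfg.A_post0 if cfg else 1.0,
                cfg.truncate_noise if cfg else False,
                exc.spike_count,
            )
            exc.refrac_until = np.zeros_like(exc.refrac_until)
            inh.refrac_until = np.zeros_like(inh.refrac_until)
        elif backend == "numpy":
            total, exc, inh, traces = _run_numpy(
                topo, exc_params, inh_params, stdp, raster, dt, 0.0,
                exc, inh, traces, rng,
            )
        else:
            raise ValueError(f"unknown backend {backend!r}")
        exc2, inh2, traces2 = relax_state(
            exc, inh, exc_params, inh_params, traces, stdp, rest_interval
        )
        exc, inh, traces = exc2, inh2, traces2
        if total >= min_spikes:
            spike_counts = exc.spike_count - counts_before
            return spike_counts, topo, (exc, inh, traces)
    raise BoostDivergence(
        f"fewer than {min_spikes} excitatory spikes after {boost_cap} rate boosts"
    )


def _refrac_remaining(state: NeuronState, dt: float) -> np.ndarray:
    """The kernel tracks refractoriness as remaining time; the dataclass as
    an absolute deadline.  Presentations start at t=0, so clamp at zero."""
    return np.maximum(state.refrac_until, 0.0)
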