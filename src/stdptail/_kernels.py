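"""Numba hot loop for the clock-driven network simulation.

One fused kernel advances the whole two-layer network over a presentation.
The per-step ordering is the contract shared with the pure-numpy reference
path in :mod:`stdptail.lif` (``run_presentation(..., backend="numpy")``):

1. pending recurrent conductance increments from the previous step land;
2. input spikes arrive from the precomputed Poisson raster and are
   delivered to the excitatory layer; each presynaptic spike triggers
   trace-based depression (LTD) against the postsynaptic trace, then
   bumps its own trace;
3. membranes integrate one explicit-Euler step (conductances decay with
   exact exponential factors; refractory neurons stay clamped at reset);
4. excitatory threshold crossings fire: reset, homeostatic theta bump,
   refractory arm, one-to-one drive onto the partner inhibitory neuron,
   and trace-based potentiation (LTP) against the presynaptic trace;
5. inhibitory crossings fire onto all excitatory neurons except the
   partner;
6. adaptive thresholds and synaptic traces decay.

Update noise ``zeta ~ N(0, sigma^2)`` is drawn per synapse per event from
numba's internal RNG, seeded once per kernel call.
"""

import numpy as np
from numba import njit

__all__ = ["presentation_kernel"]


@njit(cache=True, fastmath=False)
def _a_plus(w, rule, c_plus, gamma, W0):
    if rule == 2:  # log
        return c_plus * np.exp(-w / (W0 * gamma))
    return c_plus


@njit(cache=True, fastmath=False)
def _a_minus(w, rule, c_minus, S, W0):
    if rule == 0:  # add
        return c_minus
    if rule == 1:  # mult
        return c_minus * w
    r = w / W0
    if r <= 1.0:
        return c_minus * r
    return c_minus * (1.0 + np.log1p(S * (r - 1.0)) / S)


@njit(cache=True, fastmath=False)
def _zeta(sigma, truncate):
    if sigma <= 0.0:
        return 0.0
    z = np.random.normal() * sigma
    if truncate and z < -1.0:
        z = -1.0
    return z


@njit(cache=True, fastmath=False)
def presentation_kernel(
    seed,
    dt,
    input_spikes,
    W,
    w_ei,
    w_ie,
    # excitatory population parameters
    tau_e, Erest_e, Eexc_e, Einh_e, vth_e, vreset_e, tref_e,
    tau_ge, tau_gi, theta_inc, tau_theta,
    # inhibitory population parameters
    tau_i, Erest_i, Eexc_i, Einh_i, vth_i, vreset_i, tref_i,
    # mutable state
    X_e, ge_e, gi_e, theta, ref_e,
    X_i, ge_i, ref_i,
    x_pre, x_post,
    # plasticity
    plastic, rule, eta, sigma,
    c_plus, c_minus, tau_plus, tau_minus, S, gamma, W0,
    w_min, w_max, A_pre0, A_post0, truncate,
    # output
    spike_count_exc,
):
    """Advance the network over the ``input_spikes`` raster (n_steps rows of
    per-pixel booleans), ``dt`` ms per step. Returns total excitatory spikes
    emitted. All state arrays are updated in place; ``seed`` feeds the
    update-noise RNG only (input randomness lives in the raster)."""
    if seed >= 0:
        np.random.seed(seed)
    n_steps = input_spikes.shape[0]
    n_input = W.shape[0]
    n_exc = W.shape[1]

    dec_ge = np.exp(-dt / tau_ge)
    dec_gi = np.exp(-dt / tau_gi)
    dec_theta = np.exp(-dt / tau_theta)
    dec_xpre = np.exp(-dt / tau_plus)
    dec_xpost = np.exp(-dt / tau_minus)

    pend_gi_e = np.zeros(n_exc)
    pend_ge_i = np.zeros(n_exc)

    total_spikes = 0

    for step in range(n_steps):
        # 1. pending recurrent conductances from the previous step
        for j in range(n_exc):
            gi_e[j] += pend_gi_e[j]
            ge_i[j] += pend_ge_i[j]
            pend_gi_e[j] = 0.0
            pend_ge_i[j] = 0.0

        # 2. input spikes: deliver, LTD, trace bump
        for i in range(n_input):
            if input_spikes[step, i]:
                for j in range(n_exc):
                    ge_e[j] += W[i, j]
                if plastic:
                    for j in range(n_exc):
                        if x_post[j] > 0.0:
                            dw = (
                                eta
                                * (1.0 + _zeta(sigma, truncate))
                                * _a_minus(W[i, j], rule, c_minus, S, W0)
                                * x_post[j]
                            )
                            w_new = W[i, j] - dw
                            if w_new < w_min:
                                w_new = w_min
                            elif w_new > w_max:
                                w_new = w_max
                            W[i, j] = w_new
                x_pre[i] += A_pre0

        # 3. membrane integration (refractory countdown precedes the clamp
        # check so a neuron is clamped for exactly t_refrac/dt - 1 steps
        # after its reset step, matching the absolute-deadline reference)
        for j in range(n_exc):
            if ref_e[j] > 0.0:
                ref_e[j] -= dt
            if ref_e[j] > 0.0:
                X_e[j] = vreset_e
            else:
                X_e[j] += (dt / tau_e) * (
                    (Erest_e - X_e[j])
                    + ge_e[j] * (Eexc_e - X_e[j])
                    + gi_e[j] * (Einh_e - X_e[j])
                )
            ge_e[j] *= dec_ge
            gi_e[j] *= dec_gi
        for j in range(n_exc):
            if ref_i[j] > 0.0:
                ref_i[j] -= dt
            if ref_i[j] > 0.0:
                X_i[j] = vreset_i
            else:
                X_i[j] += (dt / tau_i) * (
                    (Erest_i - X_i[j]) + ge_i[j] * (Eexc_i - X_i[j])
                )
            ge_i[j] *= dec_ge

        # 4. excitatory firing
        for j in range(n_exc):
            if ref_e[j] <= 0.0 and X_e[j] >= vth_e + theta[j]:
                X_e[j] = vreset_e
                ref_e[j] = tref_e
                theta[j] += theta_inc
                spike_count_exc[j] += 1
                total_spikes += 1
                pend_ge_i[j] += w_ei
                if plastic:
                    ap = 0.0
                    for i in range(n_input):
                        if x_pre[i] > 0.0:
                            ap = _a_plus(W[i, j], rule, c_plus, gamma, W0)
                            dw = (
                                eta
                                * (1.0 + _zeta(sigma, truncate))
                                * ap
                                * x_pre[i]
                            )
                            w_new = W[i, j] + dw
                            if w_new < w_min:
                                w_new = w_min
                            elif w_new > w_max:
                                w_new = w_max
                            W[i, j] = w_new
                x_post[j] += A_post0

        # 5. inhibitory firing: onto all excitatory except the partner
        for k in range(n_exc):
            if ref_i[k] <= 0.0 and X_i[k] >= vth_i:
                X_i[k] = vreset_i
                ref_i[k] = tref_i
                for j in range(n_exc):
                    pend_gi_e[j] += w_ie
                pend_gi_e[k] -= w_ie

        # 6. homeostatic threshold and trace decay
        for j in range(n_exc):
            theta[j] *= dec_theta
            x_post[j] *= dec_xpost
        for i in range(n_input):
            x_pre[i] *= dec_xpre

    return total_spikes
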