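"""Numba kernels for the sequential voltage recursions.

The event-driven scheme is an affine recursion per synaptic event and the
grid schemes are per-step Euler updates; both are inherently sequential,
so they are compiled rather than vectorized.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def exact_scan(times, We, Wi, tau, Ve, Vi, v_inf, V0):
    """Event-driven voltage scan with the Marcus jump rule.

    Between events the voltage relaxes exponentially toward ``v_inf``
    (the current-induced equilibrium I/G) with time constant ``tau``;
    at each event it jumps by
    J = ((We Ve + Wi Vi)/(We + Wi) - V) (1 - exp(-(We + Wi))).
    Returns the voltage just before and just after every event.
    """
    n = times.shape[0]
    v_pre = np.empty(n)
    v_post = np.empty(n)
    v = V0
    t_prev = 0.0
    for i in range(n):
        v = v_inf + (v - v_inf) * np.exp(-(times[i] - t_prev) / tau)
        v_pre[i] = v
        s = We[i] + Wi[i]
        target = (We[i] * Ve + Wi[i] * Vi) / s
        v = v + (target - v) * (1.0 - np.exp(-s))
        v_post[i] = v
        t_prev = times[i]
    return v_pre, v_post


@njit(cache=True)
def if_scan(times, We, Wi, tau, Ve, Vi, v_inf, V0, VT, VR):
    """Event-driven scan with integrate-and-fire threshold and reset.

    Threshold crossings are checked after each jump; if the relaxation
    equilibrium itself exceeds threshold (v_inf >= VT), the continuous
    upward relaxation between events is root-solved in closed form.
    Returns per-event voltages and the spike times.
    """
    n = times.shape[0]
    v_pre = np.empty(n)
    v_post = np.empty(n)
    spikes = []
    v = V0
    t_prev = 0.0
    for i in range(n):
        dt = times[i] - t_prev
        if v_inf >= VT and v < VT:
            # exponential approach to v_inf crosses VT at a finite time
            t_cross = tau * np.log((v_inf - v) / (v_inf - VT))
            while t_cross < dt:
                spikes.append(t_prev + t_cross)
                v = VR
                t_prev = t_prev + t_cross
                dt = times[i] - t_prev
                t_cross = tau * np.log((v_inf - v) / (v_inf - VT))
        v = v_inf + (v - v_inf) * np.exp(-dt / tau)
        v_pre[i] = v
        s = We[i] + Wi[i]
        target = (We[i] * Ve + Wi[i] * Vi) / s
        v = v + (target - v) * (1.0 - np.exp(-s))
        if v >= VT:
            spikes.append(times[i])
            v = VR
        v_post[i] = v
        t_prev = times[i]
    return v_pre, v_post, np.array(spikes)


@njit(cache=True)
def euler_scan(he, hi, dt, tau, Ve, Vi, i_over_g, V0):
    """Explicit Euler integration of the conductance-based voltage ODE.

    ``he``/``hi`` are the reduced conductances (1/s) sampled on the grid.
    """
    n = he.shape[0]
    v = np.empty(n + 1)
    v[0] = V0
    x = V0
    for m in range(n):
        x = x + dt * (-x / tau + he[m] * (Ve - x) + hi[m] * (Vi - x) + i_over_g / tau)
        v[m + 1] = x
    return v


@njit(cache=True)
def ou_scan(n_steps, dt, tau_eff, mean, sigma, V0, noise):
    """Euler-Maruyama scan of the matched Ornstein-Uhlenbeck surrogate."""
    v = np.empty(n_steps + 1)
    v[0] = V0
    x = V0
    sq = np.sqrt(dt)
    for m in range(n_steps):
        x = x + dt * (mean - x) / tau_eff + sigma * sq * noise[m]
        v[m + 1] = x
    return v


@njit(cache=True)
def ou_if_scan(n_steps, dt, tau_eff, mean, sigma, V0, noise, VT, VR):
    """OU surrogate with threshold/reset; returns trace and spike times."""
    v = np.empty(n_steps + 1)
    v[0] = V0
    x = V0
    sq = np.sqrt(dt)
    spikes = []
    for m in range(n_steps):
        x = x + dt * (mean - x) / tau_eff + sigma * sq * noise[m]
        if x >= VT:
            spikes.append((m + 1) * dt)
            x = VR
        v[m + 1] = x
    return v, np.array(spikes)
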