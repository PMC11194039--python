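"""Simulation of the all-or-none conductance-based (AONCB) membrane voltage.

The AONCB neuron obeys

    dV/dt = -V / tau + he (Ve - V) + hi (Vi - V) + I / C,

with leak reversal fixed at zero and reduced conductances he, hi that
switch on to W / tau_s for a duration tau_s at each synaptic event
(all-or-none activation, overlapping pulses add). In the instantaneous-
synapse limit tau_s -> 0 the drive becomes shot noise and the voltage
admits an exact event-driven scheme: exponential relaxation between
events plus the Marcus jump

    J = ((We Ve + Wi Vi) / (We + Wi) - V) (1 - exp(-(We + Wi)))

at each event, which confines the voltage to [Vi, Ve]. The finite-tau_s
dynamics is integrated with an explicit Euler reference scheme; an
integrate-and-fire variant and a moment-matched Ornstein-Uhlenbeck
(diffusion) surrogate support cross-method comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .drive import DriveRealization

__all__ = [
    "IFSpec",
    "NeuronSpec",
    "TraceMoments",
    "VoltageTrace",
    "marcus_jump",
    "psp_peak_unitary",
    "simulate_diffusion_approx",
    "simulate_euler",
    "simulate_exact",
    "simulate_if",
    "trace_moments",
]


@dataclass(frozen=True)
class NeuronSpec:
    """Membrane parameters of the AONCB neuron.

    tau is the passive membrane time constant in seconds; Ve and Vi are
    the excitatory/inhibitory reversal potentials in mV relative to the
    leak reversal (Vi < 0 < Ve); I_over_G expresses a constant current as
    a voltage offset (mV); eps = tau_s / tau, with 0 meaning
    instantaneous synapses.
    """

    tau: float = 15e-3
    Ve: float = 60.0
    Vi: float = -10.0
    I_over_G: float = 0.0
    eps: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not self.Vi < 0.0 < self.Ve:
            raise ValueError("require Vi < 0 < Ve (leak reversal at 0)")
        if self.eps < 0:
            raise ValueError("eps = tau_s / tau must be nonnegative")

    @property
    def tau_s(self) -> float:
        return self.eps * self.tau


@dataclass(frozen=True)
class IFSpec:
    """Integrate-and-fire threshold VT and reset VR (mV), VR <= VT."""

    VT: float
    VR: float

    def __post_init__(self):
        if self.VR > self.VT:
            raise ValueError("reset must not exceed threshold")


@dataclass(frozen=True)
class VoltageTrace:
    """A simulated voltage trajectory.

    Either an event-segment representation (event times with pre/post
    voltages; the trace is piecewise-exponential between events, exactly
    reconstructible) or a grid representation (uniform sampling). The
    event form is the source of truth for the exact scheme; grid export
    is a view.
    """

    kind: str  # "events" | "grid"
    T: float
    neuron: NeuronSpec
    V0: float
    times: np.ndarray | None = None
    v_pre: np.ndarray | None = None
    v_post: np.ndarray | None = None
    dt: float | None = None
    v_grid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_grid(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample the trace on a uniform grid (exact for event traces)."""
        if self.kind == "grid":
            t = np.arange(self.v_grid.shape[0]) * self.dt
            return t, self.v_grid
        t = np.arange(0.0, self.T, dt)
        v_inf = self.neuron.I_over_G
        if self.times.shape[0] == 0:
            return t, v_inf + (self.V0 - v_inf) * np.exp(-t / self.neuron.tau)
        idx = np.searchsorted(self.times, t, side="right") - 1
        v_start = np.where(idx >= 0, self.v_post[np.clip(idx, 0, None)], self.V0)
        t_start = np.where(idx >= 0, self.times[np.clip(idx, 0, None)], 0.0)
        v = v_inf + (v_start - v_inf) * np.exp(-(t - t_start) / self.neuron.tau)
        return t, v

    def to_frame(self, dt: float = 1e-3) -> pd.DataFrame:
        t, v = self.to_grid(dt)
        return pd.DataFrame({"time_s": t, "V_mV": v})

    def to_hdf5(self, path, dt: float = 1e-3) -> None:
        """Write a grid view of the trace to HDF5."""
        import h5py

        t, v = self.to_grid(dt)
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_s", data=t)
            fh.create_dataset("V_mV", data=v)
            fh.attrs.update({"tau": self.neuron.tau, "T": self.T, "kind": self.kind})


def marcus_jump(V, We, Wi, Ve: float, Vi: float):
    """Voltage jump caused by a synaptic event of sizes (We, Wi).

    The jump drives V toward the conductance-weighted reversal potential
    (We Ve + Wi Vi)/(We + Wi) with saturation 1 - exp(-(We + Wi)); it is
    the instantaneous-synapse limit of the all-or-none conductance pulse
    and never takes the voltage outside [Vi, Ve].
    """
    We = np.asarray(We, dtype=float)
    Wi = np.asarray(Wi, dtype=float)
    s = We + Wi
    if np.any(s <= 0):
        raise ValueError("a synaptic event requires We + Wi > 0")
    target = (We * Ve + Wi * Vi) / s
    return (target - V) * -np.expm1(-s)


def simulate_exact(drive: DriveRealization, neuron: NeuronSpec, V0: float = 0.0) -> VoltageTrace:
    """Exact event-driven simulation in the instantaneous-synapse regime.

    Between events the voltage relaxes in closed form toward I/G with
    time constant tau (no discretization error); at each event the
    Marcus jump is applied. Bit-reproducible for a fixed drive.
    """
    if neuron.eps != 0:
        raise ValueError("exact event-driven scheme requires eps = 0")
    times = drive.times
    if times.shape[0] == 0:
        return VoltageTrace(kind="events", T=drive.T, neuron=neuron, V0=V0,
                            times=times, v_pre=times, v_post=times)
    v_pre, v_post = _kernels.exact_scan(
        times, drive.We, drive.Wi, neuron.tau, neuron.Ve, neuron.Vi, neuron.I_over_G, V0
    )
    return VoltageTrace(
        kind="events", T=drive.T, neuron=neuron, V0=V0,
        times=times, v_pre=v_pre, v_post=v_post,
    )


def simulate_if(
    drive: DriveRealization, neuron: NeuronSpec, if_spec: IFSpec, V0: float = 0.0
) -> tuple[VoltageTrace, np.ndarray]:
    """Event-driven simulation with integrate-and-fire threshold/reset.

    In the instantaneous-synapse regime upward moves occur only at jumps
    when I/G < VT, so crossings are checked at event times; when the
    relaxation equilibrium I/G exceeds VT, the continuous crossing time
    is solved in closed form between events.
    """
    if neuron.eps != 0:
        raise ValueError("exact event-driven scheme requires eps = 0")
    v_pre, v_post, spikes = _kernels.if_scan(
        drive.times, drive.We, drive.Wi, neuron.tau, neuron.Ve, neuron.Vi,
        neuron.I_over_G, V0, if_spec.VT, if_spec.VR,
    )
    trace = VoltageTrace(
        kind="events", T=drive.T, neuron=neuron, V0=V0,
        times=drive.times, v_pre=v_pre, v_post=v_post,
        meta={"VT": if_spec.VT, "VR": if_spec.VR},
    )
    return trace, spikes


def _conductance_grid(times, W, tau_s, dt, n_steps):
    """Reduced-conductance time series from all-or-none pulses.

    Each event contributes a rectangular pulse of height W / tau_s over
    [T_n, T_n + tau_s); pulses are aligned to the true event time with
    fractional-weight corrections at the partially covered edge bins, so
    the integrated conductance per pulse is exactly W irrespective of dt.
    """
    h = np.zeros(n_steps)
    if times.shape[0] == 0:
        return h
    height = W / tau_s
    start = times / dt
    end = (times + tau_s) / dt
    i0 = np.floor(start).astype(np.int64)
    i1 = np.floor(end).astype(np.int64)
    # accumulate d(coverage)/d(bin) then cumulative-sum: standard edge trick
    frac0 = 1.0 - (start - i0)
    frac1 = end - i1
    acc = np.zeros(n_steps + 2)
    np.add.at(acc, np.clip(i0, 0, n_steps + 1), height * frac0)
    np.add.at(acc, np.clip(i0 + 1, 0, n_steps + 1), height * (1.0 - frac0))
    np.add.at(acc, np.clip(i1, 0, n_steps + 1), -height * (1.0 - frac1))
    np.add.at(acc, np.clip(i1 + 1, 0, n_steps + 1), -height * frac1)
    h = np.cumsum(acc)[:n_steps]
    return h


def simulate_euler(
    drive: DriveRealization,
    neuron: NeuronSpec,
    dt: float | None = None,
    V0: float = 0.0,
) -> VoltageTrace:
    """Explicit Euler reference scheme for finite synaptic time constant.

    Conductances are all-or-none pulses of height W / tau_s and duration
    tau_s (amplitude scaling as 1/eps preserves charge transfer as
    eps -> 0); overlapping pulses add. Default dt = min(tau_s/20, tau/200).
    """
    if neuron.eps <= 0:
        raise ValueError("Euler scheme requires eps > 0 (finite tau_s)")
    tau_s = neuron.tau_s
    if dt is None:
        dt = min(tau_s / 20.0, neuron.tau / 200.0)
    if dt > tau_s / 20.0 + 1e-15:
        raise ValueError("dt must satisfy dt <= tau_s / 20 for stability")
    n_steps = int(round(drive.T / dt))
    he = _conductance_grid(drive.times, drive.We, tau_s, dt, n_steps)
    hi = _conductance_grid(drive.times, drive.Wi, tau_s, dt, n_steps)
    v = _kernels.euler_scan(he, hi, dt, neuron.tau, neuron.Ve, neuron.Vi, neuron.I_over_G, V0)
    return VoltageTrace(kind="grid", T=drive.T, neuron=neuron, V0=V0, dt=dt, v_grid=v)


def simulate_diffusion_approx(
    neuron: NeuronSpec,
    mean: float,
    variance: float,
    tau_eff: float,
    T: float,
    dt: float = 1e-4,
    seed: int | np.random.Generator = 0,
    if_spec: IFSpec | None = None,
    V0: float | None = None,
):
    """Moment-matched Ornstein-Uhlenbeck (diffusion) surrogate.

    Simulates dV = -(V - mean)/tau_eff dt + sigma dB with
    sigma^2 = 2 variance / tau_eff so that the stationary law matches the
    supplied first two moments; tau_eff = tau / (1 + ae1 + ai1) is the
    effective time constant including the mean conductance load. With
    ``if_spec`` a threshold/reset is applied per step and spike times are
    returned alongside the trace.
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    sigma = math.sqrt(2.0 * variance / tau_eff)
    noise = rng.standard_normal(n_steps)
    start = mean if V0 is None else V0
    if if_spec is None:
        v = _kernels.ou_scan(n_steps, dt, tau_eff, mean, sigma, start, noise)
        return VoltageTrace(kind="grid", T=T, neuron=neuron, V0=start, dt=dt, v_grid=v)
    v, spikes = _kernels.ou_if_scan(
        n_steps, dt, tau_eff, mean, sigma, start, noise, if_spec.VT, if_spec.VR
    )
    trace = VoltageTrace(kind="grid", T=T, neuron=neuron, V0=start, dt=dt, v_grid=v)
    return trace, spikes


def psp_peak_unitary(w: float, neuron: NeuronSpec) -> float:
    """Peak somatic deflection of one all-or-none pulse delivered at rest.

    During the pulse the voltage obeys dV/dt = -V/tau + (w/tau_s)(Ve - V)
    from V(0) = 0, which relaxes toward (w/tau_s) Ve / (1/tau + w/tau_s)
    with rate 1/tau + w/tau_s; the all-or-none conductance makes the
    deflection maximal exactly at the pulse end t = tau_s.
    """
    if neuron.eps <= 0:
        raise ValueError("a finite pulse duration (eps > 0) is required")
    tau_s = neuron.tau_s
    rate = 1.0 / neuron.tau + w / tau_s
    v_target = (w / tau_s) * neuron.Ve / rate
    return v_target * -math.expm1(-rate * tau_s)


# ---------------------------------------------------------------------------
# trace moments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceMoments:
    """Time-weighted stationary-moment estimates with batch-means SEs."""

    mean: float
    variance: float
    se_mean: float
    se_variance: float
    T_effective: float
    n_batches: int

    def z_mean(self, target: float) -> float:
        return (self.mean - target) / self.se_mean

    def z_variance(self, target: float) -> float:
        return (self.variance - target) / self.se_variance


def _segment_integrals(v_start, v_inf, tau, dur):
    """Exact time integrals of V and V^2 over exponential segments."""
    decay1 = -np.expm1(-dur / tau)
    decay2 = -np.expm1(-2.0 * dur / tau)
    dv = v_start - v_inf
    i1 = v_inf * dur + dv * tau * decay1
    i2 = v_inf**2 * dur + 2.0 * v_inf * dv * tau * decay1 + dv**2 * (tau / 2.0) * decay2
    return i1, i2


def trace_moments(
    trace: VoltageTrace,
    burn_in: float | None = None,
    n_batches: int = 50,
) -> TraceMoments:
    """Stationary mean and variance of a voltage trace.

    Event-segment traces are integrated in closed form segment by
    segment (no sampling grid); grid traces use step sums. The default
    burn-in is 20 tau. Standard errors come from batch means over
    ``n_batches`` equal time batches, which accommodates the O(tau)
    autocorrelation of the voltage.
    """
    tau = trace.neuron.tau
    if burn_in is None:
        burn_in = 20.0 * tau
    if trace.T <= burn_in:
        raise ValueError("trace shorter than the burn-in period")
    span = trace.T - burn_in

    if trace.kind == "grid":
        m0 = int(round(burn_in / trace.dt))
        v = trace.v_grid[m0:]
        batches = np.array_split(v, n_batches)
        b_mean = np.array([b.mean() for b in batches])
        b_var = np.array([b.var() for b in batches])
        mean = float(v.mean())
        var = float(v.var())
        return TraceMoments(
            mean=mean,
            variance=var,
            se_mean=float(b_mean.std(ddof=1) / math.sqrt(n_batches)),
            se_variance=float(b_var.std(ddof=1) / math.sqrt(n_batches)),
            T_effective=span,
            n_batches=n_batches,
        )

    v_inf = trace.neuron.I_over_G
    times = trace.times
    # segment start times/voltages, clipped to [burn_in, T]
    starts = np.concatenate([[0.0], times])
    v_starts = np.concatenate([[trace.V0], trace.v_post]) if times.shape[0] else np.array([trace.V0])
    ends = np.concatenate([times, [trace.T]])
    keep = ends > burn_in
    starts, v_starts, ends = starts[keep], v_starts[keep], ends[keep]
    # advance the first retained segment to the burn-in point
    if starts[0] < burn_in:
        v_starts[0] = v_inf + (v_starts[0] - v_inf) * math.exp(-(burn_in - starts[0]) / tau)
        starts[0] = burn_in
    dur = ends - starts
    i1, i2 = _segment_integrals(v_starts, v_inf, tau, dur)

    edges = np.linspace(burn_in, trace.T, n_batches + 1)
    which = np.clip(np.searchsorted(edges, starts, side="right") - 1, 0, n_batches - 1)
    bt = np.bincount(which, weights=dur, minlength=n_batches)
    b1 = np.bincount(which, weights=i1, minlength=n_batches)
    b2 = np.bincount(which, weights=i2, minlength=n_batches)
    ok = bt > 0
    b_mean = b1[ok] / bt[ok]
    b_var = b2[ok] / bt[ok] - b_mean**2
    nb = int(ok.sum())

    mean = float(i1.sum() / span)
    var = float(i2.sum() / span - mean**2)
    if nb >= 2:
        se_mean = float(b_mean.std(ddof=1) / math.sqrt(nb))
        se_var = float(b_var.std(ddof=1) / math.sqrt(nb))
    else:  # a single occupied batch carries no dispersion information
        se_mean = se_var = math.nan
    return TraceMoments(
        mean=mean,
        variance=var,
        se_mean=se_mean,
        se_variance=se_var,
        T_effective=span,
        n_batches=nb,
    )
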