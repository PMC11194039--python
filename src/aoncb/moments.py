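"""Exact stationary voltage moments and their approximations.

In the instantaneous-synapse limit the stationary mean and variance of
the AONCB voltage are exact functionals of the jump distribution through
dimensionless synaptic efficacies:

    ae1 = b tau E[We/(We+Wi) (1 - e^-(We+Wi))]          (first order)
    ae2 = b tau / 2 E[We/(We+Wi) (1 - e^-2(We+Wi))]      (second order)
    ae12 = ae1 - ae2 = b tau / 2 E[We/(We+Wi) (1 - e^-(We+Wi))^2]
    cei = b tau / 2 E[We Wi/(We+Wi)^2 (1 - e^-(We+Wi))^2]

with symmetric inhibitory forms, and

    E[V] = (ae1 Ve + ai1 Vi + I/G) / (1 + ae1 + ai1)
    V[V] = [ae12 (Ve-E[V])^2 + ai12 (Vi-E[V])^2 - cei (Ve-Vi)^2]
           / (1 + ae2 + ai2).

The module also provides the small-weight (mean-field) approximation and
its synchrony corrections, the relative error incurred by dropping the
exponential saturation, the infinite-input scaling limit driven by a
degenerate beta (Levy) measure, and the asynchronous scaling decay of
the variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .simulate import NeuronSpec
from .synchrony import (
    JumpModel,
    PoolSpec,
    PopulationSpec,
    event_rate_single_pool,
    joint_jump_model_independent,
    jump_pmf_single_pool,
    rho_to_beta,
)

__all__ = [
    "EfficacySet",
    "ScalingLimitSpec",
    "StationaryMoments",
    "asynchronous_scaling_decay",
    "effective_driving_force",
    "efficacies",
    "scaling_limit_moments",
    "small_weight_error",
    "small_weight_moments",
    "stationary_mean",
    "stationary_moments",
    "stationary_variance",
    "synchrony_corrections",
]


@dataclass(frozen=True)
class EfficacySet:
    """Dimensionless synaptic efficacies of a jump model at time constant tau.

    The identity ae12 = ae1 - ae2 (and its inhibitory counterpart) holds
    algebraically; it is verified at construction to machine precision.
    """

    ae1: float
    ai1: float
    ae2: float
    ai2: float
    ae12: float
    ai12: float
    cei: float
    tau: float
    b: float

    def __post_init__(self):
        scale = max(abs(self.ae1), abs(self.ai1), 1.0)
        if abs(self.ae12 - (self.ae1 - self.ae2)) > 1e-12 * scale:
            raise FloatingPointError("efficacy identity ae12 = ae1 - ae2 violated")
        if abs(self.ai12 - (self.ai1 - self.ai2)) > 1e-12 * scale:
            raise FloatingPointError("efficacy identity ai12 = ai1 - ai2 violated")

    @property
    def tau_eff(self) -> float:
        """Effective membrane time constant tau / (1 + ae1 + ai1)."""
        return self.tau / (1.0 + self.ae1 + self.ai1)


@dataclass(frozen=True)
class StationaryMoments:
    """Stationary voltage mean (mV) and variance (mV^2) with provenance."""

    mean: float
    variance: float
    method: str  # exact | small_weight | scaling_limit | monte_carlo
    efficacies: EfficacySet | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variance < -1e-12:
            raise ValueError("negative stationary variance")


def efficacies(model: JumpModel, tau: float) -> EfficacySet:
    """Exact synaptic efficacies as weighted sums over the jump pmf.

    Expectations are evaluated exactly on the support (no sampling); the
    difference-prone combination ae1 - ae2 is computed from its own
    squared-saturation form so that no cancellation occurs.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    p = model.probs
    We, Wi = model.We, model.Wi
    s = We + Wi
    xe = np.where(s > 0, We / np.where(s > 0, s, 1.0), 0.0)
    xi = np.where(s > 0, Wi / np.where(s > 0, s, 1.0), 0.0)
    sat1 = -np.expm1(-s)
    bt = model.b * tau
    ae1 = bt * float(np.sum(p * xe * sat1))
    ai1 = bt * float(np.sum(p * xi * sat1))
    # ae12 from its squared-saturation form (no cancellation), ae2 via identity
    ae12 = 0.5 * bt * float(np.sum(p * xe * sat1**2))
    ai12 = 0.5 * bt * float(np.sum(p * xi * sat1**2))
    cei = 0.5 * bt * float(np.sum(p * xe * xi * sat1**2))
    return EfficacySet(
        ae1=ae1, ai1=ai1, ae2=ae1 - ae12, ai2=ai1 - ai12, ae12=ae12, ai12=ai12,
        cei=cei, tau=tau, b=model.b,
    )


def stationary_mean(eff: EfficacySet, neuron: NeuronSpec) -> float:
    """E[V] = (ae1 Ve + ai1 Vi + I/G) / (1 + ae1 + ai1)."""
    return (eff.ae1 * neuron.Ve + eff.ai1 * neuron.Vi + neuron.I_over_G) / (
        1.0 + eff.ae1 + eff.ai1
    )


def stationary_variance(eff: EfficacySet, mean: float, neuron: NeuronSpec) -> float:
    """V[V] from the second-order efficacies and the matched mean.

    The factorized origin of the formula guarantees non-negativity; a
    negative value beyond rounding therefore signals an inconsistent
    (eff, mean) pairing and raises.
    """
    num = (
        eff.ae12 * (neuron.Ve - mean) ** 2
        + eff.ai12 * (neuron.Vi - mean) ** 2
        - eff.cei * (neuron.Ve - neuron.Vi) ** 2
    )
    var = num / (1.0 + eff.ae2 + eff.ai2)
    scale = max(abs(eff.ae12) * neuron.Ve**2, 1e-30)
    if var < -1e-12 * scale:
        raise FloatingPointError(f"stationary variance came out negative: {var}")
    return max(var, 0.0)


def stationary_moments(model: JumpModel, neuron: NeuronSpec) -> StationaryMoments:
    """Exact stationary moments of the AONCB voltage for a jump model."""
    eff = efficacies(model, neuron.tau)
    mean = stationary_mean(eff, neuron)
    var = stationary_variance(eff, mean, neuron)
    return StationaryMoments(mean=mean, variance=var, method="exact", efficacies=eff)


# ---------------------------------------------------------------------------
# small-weight (mean-field) approximation
# ---------------------------------------------------------------------------

_SMALL_WEIGHT_WARN = 0.05


def _small_weight_mean(spec: PopulationSpec, neuron: NeuronSpec) -> float:
    ae1 = spec.Ke * spec.re * neuron.tau * spec.we
    ai1 = spec.Ki * spec.ri * neuron.tau * spec.wi
    return (ae1 * neuron.Ve + ai1 * neuron.Vi + neuron.I_over_G) / (1.0 + ae1 + ai1)


def small_weight_moments(
    spec: PopulationSpec,
    neuron: NeuronSpec,
    rho_ei: float | None = None,
) -> StationaryMoments:
    """Mean-field moments for weak weights (we, wi << 1).

    The mean uses first-order efficacies ae1 = Ke re tau we and is
    independent of correlations. The variance is

        [ (1 + rho_e (Ke-1)) Ke re we^2 (Ve-E[V])^2
        + (1 + rho_i (Ki-1)) Ki ri wi^2 (Vi-E[V])^2
        - 2 rho_ei sqrt(re ri) Ke we Ki wi (Ve-E[V]) (E[V]-Vi) ]
        / (2 (1/tau + Ke re we + Ki ri wi)).
    """
    import warnings

    if max(spec.we, spec.wi) > _SMALL_WEIGHT_WARN:
        warnings.warn("small-weight approximation applied with weights above 0.05")
    rho_ei = spec.rho_ei if rho_ei is None else rho_ei
    if not 0.0 <= rho_ei < 1.0:
        raise ValueError("rho_ei must lie in [0, 1)")
    mean = _small_weight_mean(spec, neuron)
    fe = (1.0 + spec.rho_e * (spec.Ke - 1)) * spec.Ke * spec.re * spec.we**2 * (
        neuron.Ve - mean
    ) ** 2
    fi = (1.0 + spec.rho_i * (spec.Ki - 1)) * spec.Ki * spec.ri * spec.wi**2 * (
        neuron.Vi - mean
    ) ** 2
    cross = (
        2.0
        * rho_ei
        * math.sqrt(spec.re * spec.ri)
        * spec.Ke * spec.we * spec.Ki * spec.wi
        * (neuron.Ve - mean) * (mean - neuron.Vi)
    )
    denom = 2.0 * (1.0 / neuron.tau + spec.Ke * spec.re * spec.we + spec.Ki * spec.ri * spec.wi)
    var = (fe + fi - cross) / denom
    return StationaryMoments(
        mean=mean,
        variance=var,
        method="small_weight",
        params={"rho_e": spec.rho_e, "rho_i": spec.rho_i, "rho_ei": rho_ei},
    )


def synchrony_corrections(
    spec: PopulationSpec, neuron: NeuronSpec, rho_ei: float | None = None
) -> tuple[float, float]:
    """Small-weight variance corrections due to synchrony.

    Returns (delta_within, delta_cross) in mV^2, where delta_within >= 0
    is the within-pool increase rho (K-1) x the Poisson-level term and
    delta_cross <= 0 is the excitation/inhibition cancellation. The
    decomposition small_weight = asynchronous + delta_within +
    delta_cross is exact (the small-weight mean is correlation-free).
    """
    rho_ei = spec.rho_ei if rho_ei is None else rho_ei
    mean = _small_weight_mean(spec, neuron)
    denom = 2.0 * (1.0 / neuron.tau + spec.Ke * spec.re * spec.we + spec.Ki * spec.ri * spec.wi)
    d_within = (
        spec.rho_e * (spec.Ke - 1) * spec.Ke * spec.re * spec.we**2 * (neuron.Ve - mean) ** 2
        + spec.rho_i * (spec.Ki - 1) * spec.Ki * spec.ri * spec.wi**2 * (neuron.Vi - mean) ** 2
    ) / denom
    d_cross = (
        -2.0
        * rho_ei
        * math.sqrt(spec.re * spec.ri)
        * spec.Ke * spec.we * spec.Ki * spec.wi
        * (neuron.Ve - mean) * (mean - neuron.Vi)
    ) / denom
    return d_within, d_cross


def effective_driving_force(K: int, w: float, v_rev: float, mean: float) -> float:
    """Effective driving force F = K w^2 (v_rev - E[V])^2 (mV^2/s per Hz)."""
    return K * w**2 * (v_rev - mean) ** 2


def small_weight_error(Ke: int, we: float, rho_e: float) -> float:
    """Relative error of the first-order efficacy approximation Ke re tau we.

    Compares the exact excitatory-only first-order efficacy
    ae1 = b tau E[1 - e^{-k we}] (jump pmf and event rate of the
    beta-derived model) with its linearization; re and tau cancel in the
    ratio. Always >= 0 because 1 - e^{-x} <= x.
    """
    beta = rho_to_beta(rho_e)
    counts = jump_pmf_single_pool(Ke, beta)
    b_over_r = event_rate_single_pool(Ke, 1.0, beta)
    exact = b_over_r * counts.expect(lambda k: -np.expm1(-k * we))
    approx = Ke * we
    return abs(exact - approx) / exact


# ---------------------------------------------------------------------------
# infinite-input scaling limit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalingLimitSpec:
    """Excitation-only scaling limit we = Omega_e / Ke, Ke -> infinity.

    The jump measure converges weakly to the degenerate beta (Levy)
    density nu(dw) = (re beta_e / w) (1 - w/Omega_e)^(beta_e - 1) dw on
    (0, Omega_e), which has infinite mass near zero but finite
    saturation integrals.
    """

    omega_e: float
    rho_e: float
    re: float

    def __post_init__(self):
        if self.omega_e <= 0:
            raise ValueError("aggregate weight Omega_e must be positive")
        if not 0.0 <= self.rho_e < 1.0:
            raise ValueError("rho_e must lie in [0, 1)")
        if self.re < 0:
            raise ValueError("rate must be nonnegative")

    @property
    def beta_e(self) -> float:
        return rho_to_beta(self.rho_e)


def _levy_integral(spec: ScalingLimitSpec, fn) -> float:
    """Integral of fn(w) nu(dw) with the algebraic endpoint weight handled
    by quadpack's weighted rule; fn must vanish linearly at w = 0."""
    omega, beta = spec.omega_e, spec.beta_e
    scale = spec.re * beta / omega ** (beta - 1.0)

    def smooth(w):
        return scale * fn(w) / w

    val, err = quad(
        smooth, 0.0, omega, weight="alg", wvar=(0.0, beta - 1.0), limit=200, epsrel=1e-10
    )
    if not np.isfinite(val) or err > 1e-6 * max(abs(val), 1.0):
        raise RuntimeError(f"scaling-limit quadrature did not converge (err={err:.2e})")
    return val


def scaling_limit_moments(spec: ScalingLimitSpec, neuron: NeuronSpec) -> StationaryMoments:
    """Stationary moments under the degenerate-beta drive.

    E[V] = Ve I1 / (1/tau + I1) and
    V[V] = (Ve - E[V])^2 I12 / (2/tau + I2), with
    I1 = int (1-e^-w) nu(dw), I12 = int (1-e^-w)^2 nu(dw),
    I2 = int (1-e^-2w) nu(dw). Asynchrony (rho_e = 0) gives zero
    variance: the measure collapses onto zero-size jumps.
    """
    if spec.rho_e == 0.0:
        tau_drive = neuron.tau * spec.re * spec.omega_e
        mean = neuron.Ve * tau_drive / (1.0 + tau_drive)
        return StationaryMoments(mean=mean, variance=0.0, method="scaling_limit")
    i1 = _levy_integral(spec, lambda w: -np.expm1(-w))
    i12 = _levy_integral(spec, lambda w: np.expm1(-w) ** 2)
    i2 = _levy_integral(spec, lambda w: -np.expm1(-2.0 * w))
    mean = neuron.Ve * i1 / (1.0 / neuron.tau + i1)
    var = (neuron.Ve - mean) ** 2 * i12 / (2.0 / neuron.tau + i2)
    return StationaryMoments(
        mean=mean, variance=var, method="scaling_limit",
        params={"I1": i1, "I12": i12, "I2": i2},
    )


# ---------------------------------------------------------------------------
# asynchronous scaling decay
# ---------------------------------------------------------------------------

_SCALING_RULES = {
    "1/K": lambda K, c: c / K,
    "1/sqrtK": lambda K, c: c / math.sqrt(K),
    "1/logK": lambda K, c: c / math.log(K),
}


def asynchronous_scaling_decay(
    rule: str,
    Ke_grid,
    neuron: NeuronSpec,
    re: float = 10.0,
    c: float = 1.0,
) -> pd.DataFrame:
    """Exact variance along a weight-scaling rule at zero correlation.

    For rho = 0 the drive is Poisson with single activations; the exact
    variance is O(we) and therefore vanishes for every rule with
    we -> 0, regardless of balance assumptions.
    """
    if rule not in _SCALING_RULES:
        raise ValueError(f"unknown scaling rule {rule!r}; choose from {sorted(_SCALING_RULES)}")
    rows = []
    for Ke in Ke_grid:
        we = _SCALING_RULES[rule](Ke, c)
        model = joint_jump_model_independent(
            PoolSpec(K=int(Ke), r=re, w=we, rho=0.0), PoolSpec(K=0, r=0.0, w=0.0)
        )
        mom = stationary_moments(model, neuron)
        rows.append({"Ke": int(Ke), "we": we, "mean_mV": mom.mean, "var_mV2": mom.variance})
    return pd.DataFrame(rows)
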