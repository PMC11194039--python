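"""Exchangeable synchronous-input models.

Synaptic inputs impinging on a neuron are modeled as exchangeable binary
processes: within a pool (excitatory or inhibitory) no synapse plays a
distinguished role. By de Finetti's theorem, the per-bin activation pattern
of an infinite exchangeable pool is a mixture of independent Bernoulli
draws governed by a directing measure over activation probabilities.
Choosing beta-distributed directing measures yields beta-binomial per-bin
activation counts, and taking the bin size to zero turns the aggregate
drive into a compound Poisson process whose jump-size distribution carries
all the synchrony structure.

This module constructs and interrogates those probability objects:

- per-bin (discrete-time) beta-binomial activation-count distributions,
- their vanishing-bin jump-count limits (digamma-normalized),
- joint excitatory/inhibitory jump models (independent or maximally
  coupled pools) with their overall synaptic-event rate ``b``,
- spiking-correlation coefficients within and across pools.

The user-facing synchrony parameter is the pairwise spiking correlation
``rho`` in [0, 1); internally it maps to the beta shape ``beta = 1/rho - 1``,
with ``rho = 0`` represented exactly by ``beta = inf`` (asynchronous,
single-activation jumps).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

__all__ = [
    "ASYNCHRONOUS",
    "CountDistribution",
    "DirectingMeasure",
    "JumpModel",
    "PoolSpec",
    "PopulationSpec",
    "beta_binomial_pmf",
    "beta_to_rho",
    "digamma_span",
    "discrete_correlations",
    "event_rate_single_pool",
    "heterogeneous_jump_pmf",
    "HeterogeneousJumpSize",
    "joint_jump_model_independent",
    "joint_jump_model_maximal",
    "jump_pmf_single_pool",
    "relevance_threshold",
    "rho_cross",
    "rho_to_beta",
    "rho_within",
]

#: Symbolic representation of the asynchronous limit beta -> infinity.
ASYNCHRONOUS = math.inf

_NORM_TOL = 1e-10
_MAX_DENSE_GRID = 2**24


def rho_to_beta(rho: float) -> float:
    """Map a spiking correlation rho in [0, 1) to the beta shape parameter."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"spiking correlation must lie in [0, 1), got {rho}")
    if rho == 0.0:
        return ASYNCHRONOUS
    return 1.0 / rho - 1.0


def beta_to_rho(beta: float) -> float:
    """Inverse of :func:`rho_to_beta`; beta = inf maps to rho = 0."""
    if math.isinf(beta):
        return 0.0
    if beta <= 0:
        raise ValueError(f"beta shape parameter must be positive, got {beta}")
    return 1.0 / (1.0 + beta)


def digamma_span(beta: float, K: int) -> float:
    """Evaluate psi(beta + K) - psi(beta) for integer K >= 0.

    Uses the exact finite-sum identity psi(b + K) - psi(b) =
    sum_{j<K} 1/(b + j), which is free of the catastrophic cancellation
    that the naive digamma difference suffers at large beta.
    """
    if K < 0:
        raise ValueError("K must be nonnegative")
    if math.isinf(beta):
        return 0.0
    if beta <= 0:
        raise ValueError(f"beta shape parameter must be positive, got {beta}")
    return float(np.sum(1.0 / (beta + np.arange(K, dtype=float))))


def relevance_threshold(rho: float) -> float:
    """Input count above which a pairwise correlation rho is non-negligible.

    The empirical criterion for a correlation to be weak among K
    exchangeable inputs is rho < 1/K; the threshold count is 1/rho.
    """
    if rho <= 0:
        return math.inf
    return 1.0 / rho


# ---------------------------------------------------------------------------
# count distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountDistribution:
    """Probability mass function over activation counts.

    ``support`` is an integer array of shape (n,) for a single pool or
    (n, 2) for joint excitatory/inhibitory counts (k, l). ``kind`` is
    ``"bin_count"`` for discrete-time per-bin counts (which may include
    zero) or ``"jump_count"`` for vanishing-bin jump counts (which assign
    no mass to the all-zero count).
    """

    support: np.ndarray
    probs: np.ndarray
    kind: str

    def __post_init__(self):
        support = np.asarray(self.support)
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape[0] != support.shape[0]:
            raise ValueError("support and probs must have equal length")
        if np.any(probs < -_NORM_TOL):
            raise ValueError("negative probability encountered")
        total = probs.sum()
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"pmf normalization residual {total - 1.0:.3e} exceeds tolerance")
        if self.kind == "jump_count":
            zero = np.all(support.reshape(support.shape[0], -1) == 0, axis=1)
            if probs[zero].sum() > _NORM_TOL:
                raise ValueError("jump-count distribution puts mass on the all-zero count")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", np.clip(probs, 0.0, None) / total)

    @property
    def is_bivariate(self) -> bool:
        return self.support.ndim == 2

    def expect(self, fn) -> float:
        """Expectation of fn(k) (or fn(k, l) for bivariate supports)."""
        if self.is_bivariate:
            vals = fn(self.support[:, 0], self.support[:, 1])
        else:
            vals = fn(self.support)
        return float(np.sum(self.probs * vals))

    def mean(self) -> float | tuple[float, float]:
        if self.is_bivariate:
            return (
                float(np.sum(self.probs * self.support[:, 0])),
                float(np.sum(self.probs * self.support[:, 1])),
            )
        return float(np.sum(self.probs * self.support))

    def to_frame(self) -> pd.DataFrame:
        if self.is_bivariate:
            return pd.DataFrame(
                {"k": self.support[:, 0], "l": self.support[:, 1], "prob": self.probs}
            )
        return pd.DataFrame({"k": self.support, "prob": self.probs})

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "support": self.support.tolist(),
                "probs": self.probs.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "CountDistribution":
        obj = json.loads(payload)
        return cls(
            support=np.asarray(obj["support"]),
            probs=np.asarray(obj["probs"], dtype=float),
            kind=obj["kind"],
        )


def beta_binomial_pmf(K: int, alpha: float, beta: float) -> CountDistribution:
    """Per-bin activation-count pmf of K exchangeable inputs.

    Mixing a Binomial(K, theta) over theta ~ Beta(alpha, beta) gives
    P(k) = C(K, k) B(alpha + k, beta + K - k) / B(alpha, beta).
    Evaluated in the log domain so that it remains stable for K up to 1e5.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta-distribution shape parameters must be positive")
    k = np.arange(K + 1, dtype=float)
    log_choose = gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
    logp = log_choose + betaln(alpha + k, beta + K - k) - betaln(alpha, beta)
    probs = np.exp(logp)
    residual = abs(probs.sum() - 1.0)
    if residual > _NORM_TOL:
        raise FloatingPointError(f"beta-binomial normalization residual {residual:.3e}")
    return CountDistribution(support=np.arange(K + 1), probs=probs, kind="bin_count")


def jump_pmf_single_pool(K: int, beta: float) -> CountDistribution:
    """Vanishing-bin jump-count pmf for a single pool of K inputs.

    Conditioning the beta-binomial bin count on being nonzero and letting
    the bin size shrink to zero (alpha -> 0 at fixed rate) yields
    p(k) = C(K, k) B(k, beta + K - k) / (psi(beta + K) - psi(beta)),
    supported on 1..K. ``beta = inf`` is the asynchronous limit: a point
    mass on single activations k = 1.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    if math.isinf(beta):
        probs = np.zeros(K)
        probs[0] = 1.0
        return CountDistribution(support=np.arange(1, K + 1), probs=probs, kind="jump_count")
    if beta <= 0:
        raise ValueError(f"beta shape parameter must be positive, got {beta}")
    k = np.arange(1, K + 1, dtype=float)
    log_choose = gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
    logp = log_choose + betaln(k, beta + K - k) - math.log(digamma_span(beta, K))
    probs = np.exp(logp)
    residual = abs(probs.sum() - 1.0)
    if residual > _NORM_TOL:
        raise FloatingPointError(f"jump pmf normalization residual {residual:.3e}")
    return CountDistribution(support=np.arange(1, K + 1), probs=probs, kind="jump_count")


def event_rate_single_pool(K: int, r: float, beta: float) -> float:
    """Rate of aggregate synaptic events for one pool.

    Population spike-rate conservation K r = b E[k] fixes the event rate
    at b = r beta (psi(beta + K) - psi(beta)); it interpolates between
    b = r (perfect synchrony, beta -> 0) and b = K r (asynchrony,
    beta -> inf).
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    if r < 0:
        raise ValueError("rate must be nonnegative")
    if math.isinf(beta):
        return K * r
    return r * beta * digamma_span(beta, K)


# ---------------------------------------------------------------------------
# joint jump models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolSpec:
    """One synaptic pool: K inputs firing at rate r (Hz) with weight w and
    pairwise spiking correlation rho."""

    K: int
    r: float
    w: float
    rho: float = 0.0

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("input count K must be nonnegative")
        if self.r < 0 or self.w < 0:
            raise ValueError("rates and weights must be nonnegative")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")

    @property
    def beta(self) -> float:
        return rho_to_beta(self.rho)

    @property
    def empty(self) -> bool:
        return self.K == 0 or self.r == 0.0


@dataclass(frozen=True)
class JumpModel:
    """Bivariate jump-size model of the compound-Poisson synaptic drive.

    ``counts`` is the joint jump-count pmf over (ke, ki) excluding (0, 0);
    jump sizes are We = ke * we and Wi = ki * wi. ``b`` is the overall
    synaptic-event rate, ``be``/``bi`` the marginal event rates. The
    bounds max(be, bi) <= b <= be + bi hold by construction.
    """

    counts: CountDistribution
    we: float
    wi: float
    b: float
    be: float
    bi: float
    Ke: int
    Ki: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts.is_bivariate:
            raise ValueError("JumpModel requires a bivariate count distribution")
        if self.b < max(self.be, self.bi) - 1e-9 or self.b > self.be + self.bi + 1e-9:
            raise ValueError("event rate violates max(be, bi) <= b <= be + bi")

    @property
    def ke(self) -> np.ndarray:
        return self.counts.support[:, 0]

    @property
    def ki(self) -> np.ndarray:
        return self.counts.support[:, 1]

    @property
    def We(self) -> np.ndarray:
        return self.ke * self.we

    @property
    def Wi(self) -> np.ndarray:
        return self.ki * self.wi

    @property
    def probs(self) -> np.ndarray:
        return self.counts.probs

    def expect(self, fn) -> float:
        """Expectation of fn(We, Wi) under the jump distribution."""
        return float(np.sum(self.probs * fn(self.We, self.Wi)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.counts.kind,
                "support": [
                    [int(k), int(l), float(p)]
                    for (k, l), p in zip(self.counts.support, self.counts.probs)
                ],
                "we": self.we,
                "wi": self.wi,
                "b": self.b,
                "be": self.be,
                "bi": self.bi,
                "Ke": self.Ke,
                "Ki": self.Ki,
                "params": self.params,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "JumpModel":
        obj = json.loads(payload)
        triples = np.asarray(obj["support"], dtype=float)
        counts = CountDistribution(
            support=triples[:, :2].astype(int), probs=triples[:, 2], kind=obj["kind"]
        )
        return cls(
            counts=counts,
            we=obj["we"],
            wi=obj["wi"],
            b=obj["b"],
            be=obj["be"],
            bi=obj["bi"],
            Ke=obj["Ke"],
            Ki=obj["Ki"],
            params=obj.get("params", {}),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.counts.to_frame()
        frame["We"] = frame["k"] * self.we
        frame["Wi"] = frame["l"] * self.wi
        return frame


def joint_jump_model_independent(spec_e: PoolSpec, spec_i: PoolSpec) -> JumpModel:
    """Jump model for independently driven excitatory and inhibitory pools.

    With no cross-pool synchrony the drive is the direct sum of two
    compound Poisson processes, so jumps are purely excitatory or purely
    inhibitory: the excitatory block {1..Ke} x {0} carries mass
    be / (be + bi) shaped like the single-pool jump pmf, the inhibitory
    block mass bi / (be + bi), and b = be + bi.
    """
    if spec_e.empty and spec_i.empty:
        raise ValueError("degenerate model: both pools are empty")
    be = 0.0 if spec_e.empty else event_rate_single_pool(spec_e.K, spec_e.r, spec_e.beta)
    bi = 0.0 if spec_i.empty else event_rate_single_pool(spec_i.K, spec_i.r, spec_i.beta)
    b = be + bi
    supports, probs = [], []
    if be > 0:
        pe = jump_pmf_single_pool(spec_e.K, spec_e.beta)
        supports.append(np.column_stack([pe.support, np.zeros(spec_e.K, dtype=int)]))
        probs.append(pe.probs * (be / b))
    if bi > 0:
        pi = jump_pmf_single_pool(spec_i.K, spec_i.beta)
        supports.append(np.column_stack([np.zeros(spec_i.K, dtype=int), pi.support]))
        probs.append(pi.probs * (bi / b))
    counts = CountDistribution(
        support=np.concatenate(supports), probs=np.concatenate(probs), kind="jump_count"
    )
    return JumpModel(
        counts=counts,
        we=spec_e.w,
        wi=spec_i.w,
        b=b,
        be=be,
        bi=bi,
        Ke=spec_e.K,
        Ki=spec_i.K,
        params={
            "coupling": "independent",
            "re": spec_e.r,
            "ri": spec_i.r,
            "rho_e": spec_e.rho,
            "rho_i": spec_i.rho,
        },
    )


def joint_jump_model_maximal(
    Ke: int, Ki: int, r: float, beta: float, we: float, wi: float
) -> JumpModel:
    """Jump model for maximally coupled pools sharing one directing variable.

    Maximal coupling (theta_e = theta_i, common rate r) gives the joint
    jump pmf p(k, l) = C(Ke, k) C(Ki, l) B(k + l, beta + Ke + Ki - k - l)
    / (psi(beta + Ke + Ki) - psi(beta)) on the grid minus (0, 0), with
    overall event rate b = r beta (psi(beta + Ke + Ki) - psi(beta)).
    """
    if Ke + Ki < 1:
        raise ValueError("at least one input is required")
    if math.isinf(beta):
        # Asynchronous limit: single activations split between the pools.
        e = PoolSpec(K=max(Ke, 1), r=r if Ke else 0.0, w=we, rho=0.0)
        i = PoolSpec(K=max(Ki, 1), r=r if Ki else 0.0, w=wi, rho=0.0)
        model = joint_jump_model_independent(e, i)
        return replace(model, Ke=Ke, Ki=Ki, params={"coupling": "maximal", "r": r, "rho": 0.0})
    if beta <= 0:
        raise ValueError(f"beta shape parameter must be positive, got {beta}")
    if (Ke + 1) * (Ki + 1) > _MAX_DENSE_GRID:
        raise ValueError("joint count grid too large for dense representation")
    Ktot = Ke + Ki
    span = digamma_span(beta, Ktot)
    k = np.arange(Ke + 1, dtype=float)[:, None]
    l = np.arange(Ki + 1, dtype=float)[None, :]
    s = k + l
    log_choose = (
        gammaln(Ke + 1)
        - gammaln(k + 1)
        - gammaln(Ke - k + 1)
        + gammaln(Ki + 1)
        - gammaln(l + 1)
        - gammaln(Ki - l + 1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = log_choose + betaln(s, beta + Ktot - s) - math.log(span)
    probs = np.exp(logp)
    probs[0, 0] = 0.0
    residual = abs(probs.sum() - 1.0)
    if residual > _NORM_TOL:
        raise FloatingPointError(f"joint jump pmf normalization residual {residual:.3e}")
    kk, ll = np.meshgrid(np.arange(Ke + 1), np.arange(Ki + 1), indexing="ij")
    support = np.column_stack([kk.ravel(), ll.ravel()])
    flat = probs.ravel()
    keep = flat > 0
    counts = CountDistribution(support=support[keep], probs=flat[keep], kind="jump_count")
    b = r * beta * span
    be = event_rate_single_pool(Ke, r, beta) if Ke else 0.0
    bi = event_rate_single_pool(Ki, r, beta) if Ki else 0.0
    return JumpModel(
        counts=counts,
        we=we,
        wi=wi,
        b=b,
        be=be,
        bi=bi,
        Ke=Ke,
        Ki=Ki,
        params={"coupling": "maximal", "r": r, "rho": beta_to_rho(beta)},
    )


# ---------------------------------------------------------------------------
# correlation functionals
# ---------------------------------------------------------------------------


def rho_within(counts: CountDistribution, K: int) -> float:
    """Pairwise spiking correlation implied by a jump-count distribution.

    In the continuous-time limit the correlation depends on the count
    distribution only through rho = E[k(k-1)] / (E[k] (K - 1)). For joint
    distributions, pass the pool of interest as the first support column.
    """
    if K < 2:
        raise ValueError("within-pool correlation requires at least two inputs")
    k = counts.support[:, 0] if counts.is_bivariate else counts.support
    ek = float(np.sum(counts.probs * k))
    if ek <= 0:
        raise ValueError("count distribution has zero mean; correlation undefined")
    ekk = float(np.sum(counts.probs * k * (k - 1.0)))
    return ekk / (ek * (K - 1))


def rho_cross(model: JumpModel) -> float:
    """Spiking correlation between the excitatory and inhibitory pools.

    rho_ei = E[ke ki] / sqrt(Ke E[ke] Ki E[ki]), which is zero for
    independent models and bounded above by sqrt(rho_e rho_i).
    """
    if model.Ke < 1 or model.Ki < 1:
        raise ValueError("cross correlation requires both pools to be nonempty")
    p, ke, ki = model.probs, model.ke, model.ki
    eke = float(np.sum(p * ke))
    eki = float(np.sum(p * ki))
    if eke <= 0 or eki <= 0:
        raise ValueError("zero marginal mean; cross correlation undefined")
    ekeki = float(np.sum(p * ke * ki))
    return ekeki / math.sqrt(model.Ke * eke * model.Ki * eki)


# ---------------------------------------------------------------------------
# directing measures (discrete-time view)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectingMeasure:
    """de Finetti directing measure of per-bin activation probabilities.

    ``family`` is ``"beta"`` (dispersed, synchronous) or ``"point"``
    (degenerate, asynchronous). For the beta family the marginals are
    Beta(alpha_e, beta_e) and Beta(alpha_i, beta_i); ``coupling`` is
    ``"independent"`` (product measure) or ``"identical"`` (theta_e =
    theta_i, requiring equal marginals).
    """

    family: str
    alpha_e: float
    beta_e: float
    alpha_i: float = math.nan
    beta_i: float = math.nan
    coupling: str = "independent"

    def __post_init__(self):
        if self.family not in ("beta", "point"):
            raise ValueError("family must be 'beta' or 'point'")
        if self.coupling not in ("independent", "identical"):
            raise ValueError("coupling must be 'independent' or 'identical'")
        if self.family == "beta" and (self.alpha_e <= 0 or self.beta_e <= 0):
            raise ValueError("beta-distribution shape parameters must be positive")
        if self.coupling == "identical" and self.has_inhibition:
            if not (
                np.isclose(self.alpha_e, self.alpha_i) and np.isclose(self.beta_e, self.beta_i)
            ):
                raise ValueError("identical coupling requires equal marginals")

    @property
    def has_inhibition(self) -> bool:
        return not math.isnan(self.alpha_i)

    @classmethod
    def point(cls, pi_e: float, pi_i: float = math.nan) -> "DirectingMeasure":
        """Point mass at activation probabilities (pi_e, pi_i): no synchrony."""
        return cls(family="point", alpha_e=pi_e, beta_e=math.nan, alpha_i=pi_i)

    @classmethod
    def from_rate(
        cls,
        r: float,
        dt: float,
        rho: float,
        r_i: float | None = None,
        coupling: str = "independent",
    ) -> "DirectingMeasure":
        """Beta measure matching spike probability r*dt and correlation rho.

        Solves r dt = alpha / (alpha + beta) and rho = 1 / (1 + alpha + beta).
        """
        if not 0 < r * dt < 1:
            raise ValueError("require 0 < r * dt < 1")
        if rho == 0.0:
            return cls.point(r * dt, (r_i or r) * dt if r_i is not None else math.nan)
        total = 1.0 / rho - 1.0
        alpha_e = r * dt * total
        beta_e = total - alpha_e
        if r_i is None:
            return cls(family="beta", alpha_e=alpha_e, beta_e=beta_e, coupling=coupling)
        alpha_i = r_i * dt * total
        return cls(
            family="beta",
            alpha_e=alpha_e,
            beta_e=beta_e,
            alpha_i=alpha_i,
            beta_i=total - alpha_i,
            coupling=coupling,
        )

    def moments(self, pool: str) -> tuple[float, float]:
        """(mean, variance) of the activation probability for one pool."""
        if self.family == "point":
            mean = self.alpha_e if pool == "e" else self.alpha_i
            return mean, 0.0
        a = self.alpha_e if pool == "e" else self.alpha_i
        b = self.beta_e if pool == "e" else self.beta_i
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return mean, var

    def sample_theta(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw n per-bin activation probabilities (theta_e, theta_i)."""
        if self.family == "point":
            te = np.full(n, self.alpha_e)
            ti = np.full(n, self.alpha_i) if self.has_inhibition else np.zeros(n)
            return te, ti
        te = rng.beta(self.alpha_e, self.beta_e, size=n)
        if not self.has_inhibition:
            return te, np.zeros(n)
        if self.coupling == "identical":
            return te, te
        return te, rng.beta(self.alpha_i, self.beta_i, size=n)


def discrete_correlations(measure: DirectingMeasure) -> tuple[float, float, float]:
    """Spiking correlations (rho_e, rho_i, rho_ei) of the discrete model.

    rho = V[theta] / (E[theta](1 - E[theta])) per pool, and the cross
    coefficient uses the covariance of (theta_e, theta_i). A point mass
    gives zero correlations; degenerate means (0 or 1) are rejected.
    """
    mean_e, var_e = measure.moments("e")
    if not 0 < mean_e < 1:
        raise ValueError("degenerate directing measure: E[theta_e] in {0, 1}")
    rho_e = var_e / (mean_e * (1.0 - mean_e))
    if not measure.has_inhibition:
        return rho_e, 0.0, 0.0
    mean_i, var_i = measure.moments("i")
    if not 0 < mean_i < 1:
        raise ValueError("degenerate directing measure: E[theta_i] in {0, 1}")
    rho_i = var_i / (mean_i * (1.0 - mean_i))
    if measure.coupling == "identical":
        cov = math.sqrt(var_e * var_i)
    else:
        cov = 0.0
    rho_ei = cov / math.sqrt(mean_e * (1 - mean_e) * mean_i * (1 - mean_i))
    return rho_e, rho_i, rho_ei


# ---------------------------------------------------------------------------
# population-level specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """Both synaptic pools plus their synchrony structure.

    ``cross`` selects how excitation and inhibition are coupled:
    ``"independent"`` (rho_ei = 0) or ``"maximal"`` (shared directing
    variable; requires re = ri and rho_e = rho_i, and implies
    rho_ei = rho_e).
    """

    Ke: int
    Ki: int
    re: float
    ri: float
    we: float
    wi: float
    rho_e: float = 0.0
    rho_i: float = 0.0
    cross: str = "independent"

    def __post_init__(self):
        if self.cross not in ("independent", "maximal"):
            raise ValueError("cross must be 'independent' or 'maximal'")
        if min(self.Ke, self.Ki) < 0 or min(self.re, self.ri, self.we, self.wi) < 0:
            raise ValueError("counts, rates and weights must be nonnegative")
        for rho in (self.rho_e, self.rho_i):
            if not 0.0 <= rho < 1.0:
                raise ValueError("correlations must lie in [0, 1)")
        if self.cross == "maximal":
            if not np.isclose(self.re, self.ri):
                raise ValueError("maximal coupling requires re = ri")
            if not np.isclose(self.rho_e, self.rho_i):
                raise ValueError("maximal coupling requires rho_e = rho_i")

    @property
    def rho_ei(self) -> float:
        return self.rho_e if self.cross == "maximal" else 0.0

    @property
    def pool_e(self) -> PoolSpec:
        return PoolSpec(K=self.Ke, r=self.re, w=self.we, rho=self.rho_e)

    @property
    def pool_i(self) -> PoolSpec:
        return PoolSpec(K=self.Ki, r=self.ri, w=self.wi, rho=self.rho_i)

    def jump_model(self) -> JumpModel:
        if self.cross == "maximal":
            return joint_jump_model_maximal(
                self.Ke, self.Ki, self.re, rho_to_beta(self.rho_e), self.we, self.wi
            )
        return joint_jump_model_independent(self.pool_e, self.pool_i)

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_dict(cls, obj: dict) -> "PopulationSpec":
        return cls(**obj)


# ---------------------------------------------------------------------------
# weight heterogeneity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeterogeneousJumpSize:
    """Aggregate jump-size distribution under heterogeneous weights.

    A jump of count k with i.i.d. per-synapse weights q(w) has aggregate
    size distributed as the k-fold convolution of q, mixed over the
    jump-count pmf: p(W) = sum_k p_k q^(*k)(W).
    """

    counts: CountDistribution
    weight_dist: object  # scipy.stats frozen distribution

    def mean(self) -> float:
        return self.counts.expect(lambda k: k) * float(self.weight_dist.mean())

    def var(self) -> float:
        ek = self.counts.expect(lambda k: k)
        vk = self.counts.expect(lambda k: k**2) - ek**2
        mu, s2 = float(self.weight_dist.mean()), float(self.weight_dist.var())
        return ek * s2 + vk * mu**2

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        ks = rng.choice(self.counts.support, size=size, p=self.counts.probs)
        total = int(ks.sum())
        draws = np.asarray(self.weight_dist.rvs(size=total, random_state=rng))
        edges = np.concatenate([[0], np.cumsum(ks)])
        sums = np.add.reduceat(np.concatenate([draws, [0.0]]), edges[:-1])
        sums[ks == 0] = 0.0
        return sums


def heterogeneous_jump_pmf(
    base_counts: CountDistribution, weight_dist
) -> HeterogeneousJumpSize:
    """Mixture of k-fold weight convolutions weighted by the jump counts."""
    if base_counts.is_bivariate:
        raise ValueError("heterogeneous weights are defined per pool")
    if base_counts.kind != "jump_count":
        raise ValueError("base_counts must be a jump-count distribution")
    return HeterogeneousJumpSize(counts=base_counts, weight_dist=weight_dist)
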