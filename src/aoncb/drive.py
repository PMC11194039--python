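"""Sampling of synaptic drives and empirical spike-count statistics.

Generates seeded realizations of the compound-Poisson synaptic drive
(event times with bivariate jump counts), discrete exchangeable rasters,
and temporally jittered spike trains, and estimates empirical pairwise
spike-count correlations from any of them.

The pairwise-correlation estimator uses the exchangeability shortcut
Var(sum_k X_k) = K v + K (K-1) c, where v is the average per-input count
variance and c the average pairwise covariance; this avoids the O(K^2)
pair enumeration that would otherwise dominate at K ~ 1000 inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synchrony import DirectingMeasure, JumpModel

__all__ = [
    "DriveRealization",
    "JitteredSpikeTrain",
    "SpikeRaster",
    "calibrate_jitter",
    "empirical_count_correlation",
    "jitter_drive",
    "sample_drive",
    "sample_raster",
]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class DriveRealization:
    """One sampled synaptic-event sequence on [0, T).

    ``times`` is strictly increasing; ``ke``/``ki`` are the integer
    coactivation counts per event, so jump sizes are We = ke we and
    Wi = ki wi.
    """

    times: np.ndarray
    ke: np.ndarray
    ki: np.ndarray
    we: float
    wi: float
    T: float
    seed: int | None = None
    model: JumpModel | None = None

    @property
    def We(self) -> np.ndarray:
        return self.ke * self.we

    @property
    def Wi(self) -> np.ndarray:
        return self.ki * self.wi

    @property
    def n_events(self) -> int:
        return int(self.times.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "ke": self.ke, "ki": self.ki, "We": self.We, "Wi": self.Wi}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, we: float, wi: float, T: float) -> "DriveRealization":
        frame = pd.read_csv(path)
        return cls(
            times=frame["time_s"].to_numpy(),
            ke=frame["ke"].to_numpy(),
            ki=frame["ki"].to_numpy(),
            we=we,
            wi=wi,
            T=T,
        )

    def to_hdf5(self, path) -> None:
        """Write the event list to HDF5 (preferred for long traces)."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_s", data=self.times)
            fh.create_dataset("ke", data=self.ke)
            fh.create_dataset("ki", data=self.ki)
            fh.attrs.update({"we": self.we, "wi": self.wi, "T": self.T})

    @classmethod
    def from_hdf5(cls, path) -> "DriveRealization":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                times=fh["time_s"][:],
                ke=fh["ke"][:],
                ki=fh["ki"][:],
                we=float(fh.attrs["we"]),
                wi=float(fh.attrs["wi"]),
                T=float(fh.attrs["T"]),
            )


def sample_drive(model: JumpModel, T: float, seed=0) -> DriveRealization:
    """Sample a compound-Poisson drive: Poisson event times at rate b,
    i.i.d. jump counts from the model's joint pmf."""
    if T <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(seed)
    if model.b <= 0:
        import warnings

        warnings.warn("jump model has zero event rate; returning an empty drive")
        empty = np.empty(0)
        return DriveRealization(empty, empty, empty, model.we, model.wi, T, model=model)
    n = rng.poisson(model.b * T)
    times = np.sort(rng.uniform(0.0, T, size=n))
    idx = rng.choice(model.probs.shape[0], size=n, p=model.probs)
    ke = model.counts.support[idx, 0].astype(float)
    ki = model.counts.support[idx, 1].astype(float)
    return DriveRealization(times, ke, ki, model.we, model.wi, T, model=model)


# ---------------------------------------------------------------------------
# discrete rasters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeRaster:
    """Binary activity array of exchangeable inputs, K x N bins."""

    e: np.ndarray  # (Ke, N) uint8
    i: np.ndarray  # (Ki, N) uint8
    dt: float
    seed: int | None = None

    @property
    def n_bins(self) -> int:
        return self.e.shape[1]

    @property
    def T(self) -> float:
        return self.n_bins * self.dt


def sample_raster(
    measure: DirectingMeasure, Ke: int, Ki: int, dt: float, n_bins: int, seed=0
) -> SpikeRaster:
    """Sample the discrete exchangeable model: per bin draw (theta_e,
    theta_i) from the directing measure, then independent Bernoulli
    activations per input."""
    rng = _as_rng(seed)
    te, ti = measure.sample_theta(n_bins, rng)
    if np.any(te >= 1.0) or np.any(ti >= 1.0):
        raise ValueError("activation probability r * dt must stay below 1")
    e = (rng.random((Ke, n_bins)) < te[None, :]).astype(np.uint8)
    i = (rng.random((Ki, n_bins)) < ti[None, :]).astype(np.uint8) if Ki else np.zeros((0, n_bins), np.uint8)
    return SpikeRaster(e=e, i=i, dt=dt)


# ---------------------------------------------------------------------------
# jittered spike trains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JitteredSpikeTrain:
    """Individual spikes obtained by splitting aggregate events.

    Each event of count k becomes k unit-weight spikes; each spike time
    is shifted by an independent centered Gaussian of SD ``sigma_j`` and
    wrapped periodically into [0, T) to preserve stationarity. Exposes
    ``times``/``We``/``Wi`` so that it can drive the event-based
    simulator directly.
    """

    times: np.ndarray
    weight: float
    K: int
    T: float
    sigma_j: float
    pool: str = "e"
    meta: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return int(self.times.shape[0])

    @property
    def We(self) -> np.ndarray:
        return np.full(self.n_spikes, self.weight) if self.pool == "e" else np.zeros(self.n_spikes)

    @property
    def Wi(self) -> np.ndarray:
        return np.full(self.n_spikes, self.weight) if self.pool == "i" else np.zeros(self.n_spikes)


def jitter_drive(
    drive: DriveRealization, sigma_j: float, seed=0, pool: str = "e"
) -> JitteredSpikeTrain:
    """Split aggregate events into unit spikes and jitter their times.

    An event of count k becomes k unit-weight spikes of one synapse
    each; the total spike count is conserved. sigma_j = 0 recovers the
    original event times as coincident unit spikes.
    """
    rng = _as_rng(seed)
    counts = (drive.ke if pool == "e" else drive.ki).astype(np.int64)
    if drive.model is not None:
        K = drive.model.Ke if pool == "e" else drive.model.Ki
    else:
        K = 0
    times = np.repeat(drive.times, counts)
    if sigma_j > 0:
        times = times + rng.normal(0.0, sigma_j, size=times.shape[0])
        times = np.mod(times, drive.T)
    times = np.sort(times, kind="stable")
    weight = drive.we if pool == "e" else drive.wi
    return JitteredSpikeTrain(
        times=times,
        weight=weight,
        K=K,
        T=drive.T,
        sigma_j=sigma_j,
        pool=pool,
    )


# ---------------------------------------------------------------------------
# empirical spike-count correlation
# ---------------------------------------------------------------------------


def _corr_from_count_matrix(counts: np.ndarray) -> float:
    """Average pairwise Pearson correlation from a (K, N) count matrix
    via the population-count identity Var(S) = sum_k v_k + K(K-1) c."""
    K = counts.shape[0]
    if K < 2:
        raise ValueError("need at least two inputs")
    S = counts.sum(axis=0)
    var_s = S.var()
    v = counts.var(axis=1)
    v_bar = v.mean()
    if v_bar <= 0:
        raise ValueError("empty spike set: per-input count variance is zero")
    c_bar = (var_s - v.sum()) / (K * (K - 1))
    return float(c_bar / v_bar)


def _rebin(matrix: np.ndarray, factor: int) -> np.ndarray:
    n = (matrix.shape[1] // factor) * factor
    return matrix[:, :n].reshape(matrix.shape[0], -1, factor).sum(axis=2)


def empirical_count_correlation(spikes, dt: float, pool: str = "e") -> float:
    """Average pairwise Pearson correlation of spike counts in dt bins.

    Accepts a :class:`SpikeRaster` (rebinned as needed; per-input count
    variances are taken from the raster itself) or a
    :class:`JitteredSpikeTrain`. For spike trains the estimator uses the
    population-count identity with the Poisson marginal variance: under
    exchangeability each input's train is an independently thinned
    Poisson process of rate r, a property preserved by jittering, so the
    per-input count variance in dt bins is r_hat dt with r_hat the
    observed per-input rate. For an unjittered synchronous drive the
    result is flat in dt and equals the model correlation up to sampling
    error.
    """
    if isinstance(spikes, SpikeRaster):
        matrix = spikes.e if pool == "e" else spikes.i
        factor = max(int(round(dt / spikes.dt)), 1)
        counts = _rebin(matrix.astype(np.int64), factor) if factor > 1 else matrix.astype(np.int64)
        return _corr_from_count_matrix(counts)
    if isinstance(spikes, JitteredSpikeTrain):
        if spikes.n_spikes == 0:
            raise ValueError("empty spike set")
        if spikes.K < 2:
            raise ValueError("need at least two inputs")
        n_bins = int(math.floor(spikes.T / dt))
        span = n_bins * dt
        in_span = spikes.times < span
        bins = (spikes.times[in_span] / dt).astype(np.int64)
        S = np.bincount(bins, minlength=n_bins).astype(float)
        K = spikes.K
        v = S.sum() / (K * n_bins)  # r_hat * dt, the Poisson marginal variance
        if v <= 0:
            raise ValueError("empty spike set")
        c_bar = (S.var() - K * v) / (K * (K - 1))
        return float(c_bar / v)
    raise TypeError(f"unsupported spike container {type(spikes)!r}")


# ---------------------------------------------------------------------------
# jitter calibration
# ---------------------------------------------------------------------------


def calibrate_jitter(
    target: float,
    dt: float,
    sigma_j: float,
    K: int,
    r: float,
    T: float = 200.0,
    seed=0,
    rho_max: float = 0.6,
    tol: float = 5e-4,
    max_iter: int = 40,
) -> tuple[float, float]:
    """Instantaneous correlation rho_inf whose jittered drive shows the
    target spike-count correlation in dt bins.

    Bisects on rho_inf with common random numbers per evaluation (the
    same seed drives every trial drive, making the empirical correlation
    monotone in rho_inf up to tiny discretization noise). Returns
    (rho_inf, achieved correlation). sigma_j = 0 returns the target
    itself, as unjittered synchronous drives have flat correlation.
    """
    from .synchrony import PoolSpec, joint_jump_model_independent

    if not 0.0 < target < 0.5:
        raise ValueError("target correlation must lie in (0, 0.5)")
    if sigma_j == 0.0:
        return target, target

    def measure(rho: float) -> float:
        model = joint_jump_model_independent(
            PoolSpec(K=K, r=r, w=1.0, rho=rho), PoolSpec(K=0, r=0.0, w=0.0)
        )
        drive = sample_drive(model, T, seed=np.random.default_rng(seed))
        train = jitter_drive(drive, sigma_j, seed=np.random.default_rng(seed + 1))
        return empirical_count_correlation(train, dt)

    lo, hi = target, rho_max
    f_lo = measure(lo)
    if f_lo >= target:
        return lo, f_lo
    f_hi = measure(hi)
    if f_hi < target:
        raise RuntimeError(
            f"calibration failed: correlation at rho_inf={hi} is {f_hi:.4f} < target {target}"
        )
    achieved = f_hi
    mid = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = measure(mid)
        achieved = f_mid
        if abs(f_mid - target) < tol or hi - lo < 1e-4:
            break
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return mid, achieved
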