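"""End-to-end validation and desk-scale parameter sweeps.

Ties the synchrony models, the drive sampler, the event-driven simulator
and the closed-form moments together: Monte Carlo vs. theory z-score
checks across synchrony conditions, the standard mean/variance sweeps
over rate and weight grids, and deterministic fixture generation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import moments as mo
from .drive import sample_drive
from .simulate import NeuronSpec, simulate_exact, trace_moments
from .synchrony import PopulationSpec

__all__ = [
    "ExperimentConfig",
    "ValidationReport",
    "default_validation_config",
    "generate_fixtures",
    "reproduce_sweep",
    "run_validation",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Schema for a seeded validation experiment."""

    population: dict
    neuron: dict = field(default_factory=dict)
    T: float = 200.0
    seed: int = 0
    burn_in: float | None = None
    V0: float = 0.0

    def neuron_spec(self) -> NeuronSpec:
        return NeuronSpec(**self.neuron)

    @classmethod
    def from_dict(cls, obj: dict) -> "ExperimentConfig":
        return cls(**obj)


@dataclass(frozen=True)
class CheckRecord:
    """One Monte Carlo vs. theory comparison."""

    name: str
    analytic_mean: float
    analytic_variance: float
    mc_mean: float
    mc_variance: float
    se_mean: float
    se_variance: float
    z_mean: float
    z_variance: float
    seed: int
    T: float
    passed: bool


@dataclass(frozen=True)
class ValidationReport:
    records: list
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_json(self) -> str:
        return json.dumps({"passed": self.passed, "records": [asdict(r) for r in self.records]})


def default_validation_config(T: float = 200.0, seed: int = 0) -> dict:
    """Three synchrony conditions: uncorrelated, within-pool correlated,
    within- and across-correlated, at matched rates and weights."""
    base = dict(Ke=100, Ki=25, re=10.0, ri=10.0, we=0.01, wi=0.04)
    return {
        "neuron": {},
        "T": T,
        "seed": seed,
        "conditions": {
            "uncorrelated": dict(base, rho_e=0.0, rho_i=0.0),
            "within_correlated": dict(base, rho_e=0.03, rho_i=0.03),
            "within_across_correlated": dict(base, rho_e=0.03, rho_i=0.03, cross="maximal"),
        },
    }


def run_validation(config: dict | None = None, z_max: float = 3.0) -> ValidationReport:
    """Simulate each synchrony condition and compare trace moments to the
    exact closed forms; a condition passes when |z| <= z_max for both
    mean and variance."""
    if config is None:
        config = default_validation_config()
    neuron = NeuronSpec(**config.get("neuron", {}))
    T = float(config.get("T", 200.0))
    if T < 100.0 * neuron.tau:
        raise ValueError("validation run shorter than 100 tau gives meaningless z-scores")
    seed = int(config.get("seed", 0))
    records = []
    for idx, (name, pop) in enumerate(config["conditions"].items()):
        spec = PopulationSpec(**pop)
        model = spec.jump_model()
        theory = mo.stationary_moments(model, neuron)
        drive = sample_drive(model, T, seed=np.random.default_rng(seed + idx))
        est = trace_moments(simulate_exact(drive, neuron), burn_in=config.get("burn_in"))
        z_m = est.z_mean(theory.mean)
        z_v = est.z_variance(theory.variance)
        records.append(
            CheckRecord(
                name=name,
                analytic_mean=theory.mean,
                analytic_variance=theory.variance,
                mc_mean=est.mean,
                mc_variance=est.variance,
                se_mean=est.se_mean,
                se_variance=est.se_variance,
                z_mean=z_m,
                z_variance=z_v,
                seed=seed + idx,
                T=T,
                passed=bool(abs(z_m) <= z_max and abs(z_v) <= z_max),
            )
        )
    return ValidationReport(records=records, passed=all(r.passed for r in records))


# ---------------------------------------------------------------------------
# standard sweeps
# ---------------------------------------------------------------------------

_SWEEP_PRESETS = {
    # rate sweeps at fixed aggregate weight Ke we = Ki wi = 1
    7: dict(kind="rates", rho=0.0, cross="independent"),
    9: dict(kind="rates", rho=0.03, cross="independent"),
    10: dict(kind="rates", rho=0.03, cross="maximal"),
    # (Ke, we) sweep against a fixed inhibitory background
    8: dict(kind="weights", rho=0.0, cross="independent"),
}

_WEIGHT_REGIMES = {
    "large": dict(Ke=100, Ki=25, we=0.01, wi=0.04),
    "moderate": dict(Ke=1000, Ki=250, we=0.001, wi=0.004),
}


def reproduce_sweep(figure: int, n_points: int = 10, overrides: dict | None = None) -> pd.DataFrame:
    """Mean/variance grids over the standard parameter planes.

    Figures 7/9/10-style sweeps scan (re, ri) in 0-50 Hz for the large
    and moderate weight regimes at fixed Ke we = Ki wi = 1; figure 8
    scans (Ke, we) at re = ri = 20 Hz against a fixed inhibitory
    background. Exact moments are used wherever a closed-form jump model
    exists (independent pools; maximal coupling on the re = ri
    diagonal); cross-correlated off-diagonal points use the small-weight
    moments.
    """
    if figure not in _SWEEP_PRESETS:
        raise ValueError(f"unknown sweep preset {figure}; choose from {sorted(_SWEEP_PRESETS)}")
    preset = dict(_SWEEP_PRESETS[figure])
    if overrides:
        preset.update(overrides)
    neuron = NeuronSpec(**preset.get("neuron", {}))
    rho = preset["rho"]
    rows = []
    if preset["kind"] == "rates":
        rates = np.linspace(1.0, 50.0, n_points)
        for regime, pars in _WEIGHT_REGIMES.items():
            for re in rates:
                for ri in rates:
                    cross = preset["cross"]
                    if cross == "maximal" and not np.isclose(re, ri):
                        spec = PopulationSpec(
                            **pars, re=re, ri=ri, rho_e=rho, rho_i=rho, cross="independent"
                        )
                        mom = mo.small_weight_moments(spec, neuron, rho_ei=rho)
                    else:
                        spec = PopulationSpec(
                            **pars, re=re, ri=ri, rho_e=rho, rho_i=rho, cross=cross
                        )
                        mom = mo.stationary_moments(spec.jump_model(), neuron)
                    rows.append(
                        {
                            "regime": regime,
                            "re_Hz": re,
                            "ri_Hz": ri,
                            "Ke": spec.Ke,
                            "Ki": spec.Ki,
                            "we": spec.we,
                            "wi": spec.wi,
                            "rho_e": rho,
                            "rho_i": rho,
                            "rho_ei": rho if preset["cross"] == "maximal" else 0.0,
                            "mean_mV": mom.mean,
                            "var_mV2": mom.variance,
                            "method": mom.method,
                        }
                    )
    else:  # (Ke, we) sweep
        backgrounds = {
            "moderate_inhibition": dict(Ki=250, wi=0.004),
            "large_inhibition": dict(Ki=25, wi=0.04),
        }
        Ke_grid = np.unique(np.logspace(1, np.log10(2000.0), n_points).astype(int))
        we_grid = np.linspace(0.001, 0.02, n_points)
        for name, bg in backgrounds.items():
            for Ke in Ke_grid:
                for we in we_grid:
                    spec = PopulationSpec(
                        Ke=int(Ke), re=20.0, ri=20.0, we=we, rho_e=rho, rho_i=rho, **bg
                    )
                    mom = mo.stationary_moments(spec.jump_model(), neuron)
                    rows.append(
                        {
                            "regime": name,
                            "re_Hz": 20.0,
                            "ri_Hz": 20.0,
                            "Ke": int(Ke),
                            "Ki": spec.Ki,
                            "we": we,
                            "wi": spec.wi,
                            "rho_e": rho,
                            "rho_i": rho,
                            "rho_ei": 0.0,
                            "mean_mV": mom.mean,
                            "var_mV2": mom.variance,
                            "method": mom.method,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def generate_fixtures(outdir, seed: int = 0) -> dict:
    """Write a small deterministic fixture bundle (drive CSV, analytic
    moments JSON, manifest). Regeneration is bit-identical for a fixed
    seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = PopulationSpec(
        Ke=100, Ki=25, re=10.0, ri=10.0, we=0.01, wi=0.04, rho_e=0.03, rho_i=0.03
    )
    neuron = NeuronSpec()
    model = spec.jump_model()
    drive = sample_drive(model, T=5.0, seed=np.random.default_rng(seed))
    drive.to_csv(outdir / "drive.csv")
    theory = mo.stationary_moments(model, neuron)
    est = trace_moments(simulate_exact(drive, neuron), burn_in=0.5)
    manifest = {
        "seed": seed,
        "n_events": drive.n_events,
        "analytic_mean_mV": theory.mean,
        "analytic_var_mV2": theory.variance,
        "mc_mean_mV": est.mean,
        "mc_var_mV2": est.variance,
        "mc_se_mean": est.se_mean,
        "mc_se_var": est.se_variance,
        "population": spec.__dict__,
        "neuron": {"tau": neuron.tau, "Ve": neuron.Ve, "Vi": neuron.Vi},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    model_json = outdir / "jump_model.json"
    model_json.write_text(model.to_json())
    return manifest
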