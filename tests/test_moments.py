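"""Tests of the closed-form stationary moments, the small-weight
approximation and its synchrony corrections, and the scaling limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aoncb import (
    NeuronSpec,
    PoolSpec,
    PopulationSpec,
    ScalingLimitSpec,
    asynchronous_scaling_decay,
    efficacies,
    joint_jump_model_independent,
    joint_jump_model_maximal,
    relevance_threshold,
    scaling_limit_moments,
    small_weight_error,
    small_weight_moments,
    stationary_mean,
    stationary_moments,
    stationary_variance,
    synchrony_corrections,
)
from aoncb.moments import effective_driving_force


def random_model(rng):
    Ke = int(rng.integers(1, 30))
    Ki = int(rng.integers(0, 15))
    rho = float(rng.uniform(0.0, 0.6))
    if rng.random() < 0.5 and Ki > 0:
        return joint_jump_model_maximal(Ke, Ki, float(rng.uniform(1, 40)), 1 / rho - 1 if rho else math.inf, 0.05, 0.1)
    return joint_jump_model_independent(
        PoolSpec(K=Ke, r=float(rng.uniform(1, 40)), w=0.05, rho=rho),
        PoolSpec(K=Ki, r=float(rng.uniform(0, 40)) if Ki else 0.0, w=0.1, rho=rho / 2),
    )


class TestEfficacies:
    def test_asynchronous_exponential_form(self, neuron):
        """Without synchrony, ae1 = Ke re tau (1 - e^{-we})."""
        model = joint_jump_model_independent(
            PoolSpec(K=100, r=10.0, w=0.01), PoolSpec(K=25, r=10.0, w=0.04)
        )
        eff = efficacies(model, neuron.tau)
        assert eff.ae1 == pytest.approx(100 * 10 * neuron.tau * (1 - math.exp(-0.01)), rel=1e-12)
        assert eff.ai1 == pytest.approx(25 * 10 * neuron.tau * (1 - math.exp(-0.04)), rel=1e-12)
        assert eff.cei == 0.0

    def test_auxiliary_identity_on_random_models(self, neuron, rng):
        """ae12 = ae1 - ae2 (and inhibitory counterpart) exactly."""
        for _ in range(20):
            eff = efficacies(random_model(rng), neuron.tau)
            assert eff.ae12 == pytest.approx(eff.ae1 - eff.ae2, abs=1e-14)
            assert eff.ai12 == pytest.approx(eff.ai1 - eff.ai2, abs=1e-14)

    def test_effective_time_constant(self, neuron):
        model = joint_jump_model_independent(
            PoolSpec(K=100, r=10.0, w=0.01), PoolSpec(K=25, r=10.0, w=0.04)
        )
        eff = efficacies(model, neuron.tau)
        assert eff.tau_eff == pytest.approx(neuron.tau / (1 + eff.ae1 + eff.ai1))


class TestStationaryMoments:
    def test_mean_reduces_to_current_without_drive(self, neuron):
        eff = efficacies(
            joint_jump_model_independent(
                PoolSpec(K=1, r=1.0, w=1e-12), PoolSpec(K=0, r=0.0, w=0.0)
            ),
            neuron.tau,
        )
        nrn = NeuronSpec(I_over_G=4.0)
        assert stationary_mean(eff, nrn) == pytest.approx(4.0, abs=1e-9)

    def test_symmetric_drive_zero_mean(self):
        nrn = NeuronSpec(Ve=60.0, Vi=-60.0)
        model = joint_jump_model_independent(
            PoolSpec(K=10, r=10.0, w=0.02), PoolSpec(K=10, r=10.0, w=0.02)
        )
        mom = stationary_moments(model, nrn)
        assert mom.mean == pytest.approx(0.0, abs=1e-12)

    def test_variance_nonnegative_on_random_models(self, neuron, rng):
        for _ in range(30):
            mom = stationary_moments(random_model(rng), neuron)
            assert mom.variance >= 0.0
            assert neuron.Vi <= mom.mean <= neuron.Ve

    def test_variance_ordering_across_synchrony_conditions(self, neuron):
        """At matched rates/weights: uncorrelated <= within+across
        correlated <= within-only correlated."""
        for pars in (
            dict(Ke=100, Ki=25, we=0.01, wi=0.04),
            dict(Ke=1000, Ki=250, we=0.001, wi=0.004),
        ):
            for r in (10.0, 25.0, 50.0):
                uncorr = stationary_moments(
                    PopulationSpec(**pars, re=r, ri=r).jump_model(), neuron
                ).variance
                within = stationary_moments(
                    PopulationSpec(**pars, re=r, ri=r, rho_e=0.03, rho_i=0.03).jump_model(),
                    neuron,
                ).variance
                across = stationary_moments(
                    PopulationSpec(
                        **pars, re=r, ri=r, rho_e=0.03, rho_i=0.03, cross="maximal"
                    ).jump_model(),
                    neuron,
                ).variance
                assert 0.0 <= uncorr <= across <= within

    def test_mean_range_stays_biophysical(self, neuron):
        """With Ke we = Ki wi = 1 and matched rates up to 50 Hz the mean
        stays within the ~20 mV depolarization band."""
        means = []
        for r in np.linspace(1.0, 50.0, 8):
            spec = PopulationSpec(Ke=1000, Ki=250, re=r, ri=r, we=0.001, wi=0.004)
            means.append(stationary_moments(spec.jump_model(), neuron).mean)
        assert max(means) - min(means) <= 20.0
        assert max(means) <= 20.0


class TestSmallWeight:
    def test_mean_is_correlation_free(self, neuron):
        base = dict(Ke=1000, Ki=250, re=20.0, ri=20.0, we=0.001, wi=0.004)
        m0 = small_weight_moments(PopulationSpec(**base), neuron)
        m1 = small_weight_moments(
            PopulationSpec(**base, rho_e=0.03, rho_i=0.03), neuron
        )
        assert m0.mean == pytest.approx(m1.mean)

    def test_agreement_with_exact_at_weak_weights(self, neuron):
        for rho in (0.0, 0.03):
            spec = PopulationSpec(
                Ke=1000, Ki=250, re=20.0, ri=20.0, we=0.001, wi=0.004, rho_e=rho, rho_i=rho
            )
            sw = small_weight_moments(spec, neuron)
            exact = stationary_moments(spec.jump_model(), neuron)
            assert sw.mean == pytest.approx(exact.mean, rel=0.01)
            assert sw.variance == pytest.approx(exact.variance, rel=0.10)

    def test_driving_force_ratio_is_ninefold(self):
        """Ke we^2 Ve^2 / (Ki wi^2 Vi^2) = 9 at Ke we = Ki wi = 1,
        we = 0.01, wi = 0.04, near rest."""
        fe = effective_driving_force(100, 0.01, 60.0, 0.0)
        fi = effective_driving_force(25, 0.04, -10.0, 0.0)
        assert fe / fi == pytest.approx(9.0)

    def test_driving_force_scales_with_weight_at_fixed_aggregate(self):
        f_large = effective_driving_force(100, 0.01, 60.0, 0.0)
        f_moderate = effective_driving_force(1000, 0.001, 60.0, 0.0)
        assert f_large / f_moderate == pytest.approx(10.0)

    def test_rho_one_over_K_doubles_second_order_term(self, neuron):
        K = 200
        spec = PopulationSpec(
            Ke=K, Ki=0, re=10.0, ri=0.0, we=0.005, wi=0.0, rho_e=1.0 / K
        )
        factor = 1.0 + spec.rho_e * (K - 1)
        assert factor == pytest.approx(2.0 - 1.0 / K)

    @given(
        rho_e=st.floats(min_value=0.0, max_value=0.2),
        rho_i=st.floats(min_value=0.0, max_value=0.2),
        rho_ei=st.floats(min_value=0.0, max_value=0.1),
        re=st.floats(min_value=1.0, max_value=50.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_correction_decomposition_identity(self, rho_e, rho_i, rho_ei, re):
        """small-weight variance = asynchronous variance + within-pool
        correction + cross-pool correction, to machine precision."""
        neuron = NeuronSpec(tau=15e-3, Ve=60.0, Vi=-10.0)
        rho_ei = min(rho_ei, math.sqrt(rho_e * rho_i))
        spec = PopulationSpec(
            Ke=400, Ki=100, re=re, ri=20.0, we=0.002, wi=0.008, rho_e=rho_e, rho_i=rho_i
        )
        total = small_weight_moments(spec, neuron, rho_ei=rho_ei).variance
        base = small_weight_moments(
            PopulationSpec(Ke=400, Ki=100, re=re, ri=20.0, we=0.002, wi=0.008), neuron
        ).variance
        d_within, d_cross = synchrony_corrections(spec, neuron, rho_ei=rho_ei)
        assert d_within >= 0.0
        assert d_cross <= 0.0
        assert total == pytest.approx(base + d_within + d_cross, rel=1e-12, abs=1e-12)

    def test_corrections_vanish_without_correlations(self, neuron):
        spec = PopulationSpec(Ke=100, Ki=25, re=10.0, ri=10.0, we=0.01, wi=0.04)
        d_within, d_cross = synchrony_corrections(spec, neuron)
        assert d_within == 0.0
        assert d_cross == 0.0


class TestSmallWeightError:
    def test_vanishes_with_weight(self):
        assert small_weight_error(100, 1e-6, 0.05) < 1e-4

    def test_printed_three_percent_bounds(self):
        """At rho_e = 0.05 the linearized first-order efficacy errs by
        less than 3% for Ke <= 1000 at we = 0.001 and Ke <= 100 at
        we = 0.01."""
        assert small_weight_error(1000, 0.001, 0.05) < 0.03
        assert small_weight_error(100, 0.01, 0.05) < 0.03

    def test_monotone_in_weight(self):
        errs = [small_weight_error(500, w, 0.05) for w in (1e-4, 1e-3, 1e-2)]
        assert errs[0] < errs[1] < errs[2]


class TestScalingLimit:
    def test_discrete_models_converge_to_quadrature(self, neuron):
        """Finite-K models with we = Omega/K approach the degenerate-beta
        quadrature values with shrinking gap."""
        spec = ScalingLimitSpec(omega_e=1.0, rho_e=0.03, re=10.0)
        limit = scaling_limit_moments(spec, neuron)
        gaps = []
        for K in (100, 1000, 10000):
            model = joint_jump_model_independent(
                PoolSpec(K=K, r=10.0, w=1.0 / K, rho=0.03), PoolSpec(K=0, r=0.0, w=0.0)
            )
            mom = stationary_moments(model, neuron)
            gaps.append(abs(mom.variance - limit.variance))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.01 * limit.variance

    def test_small_aggregate_weight_expansion(self, neuron):
        """As Omega -> 0 the mean obeys E[V] ~ tau re Omega Ve / (1 + tau
        re Omega)."""
        spec = ScalingLimitSpec(omega_e=1e-3, rho_e=0.1, re=10.0)
        mom = scaling_limit_moments(spec, neuron)
        x = neuron.tau * 10.0 * 1e-3
        assert mom.mean == pytest.approx(neuron.Ve * x / (1 + x), rel=1e-3)

    def test_variance_vanishes_without_correlation(self, neuron):
        assert scaling_limit_moments(
            ScalingLimitSpec(omega_e=1.0, rho_e=0.0, re=10.0), neuron
        ).variance == 0.0
        # and decays toward zero as rho_e -> 0
        v = [
            scaling_limit_moments(
                ScalingLimitSpec(omega_e=1.0, rho_e=rho, re=10.0), neuron
            ).variance
            for rho in (0.1, 0.01, 0.001)
        ]
        assert v[0] > v[1] > v[2]
        assert v[2] < 0.15 * v[0]


class TestScalingDecay:
    @pytest.mark.parametrize("rule", ["1/K", "1/sqrtK", "1/logK"])
    def test_variance_vanishes_for_all_rules(self, neuron, rule):
        grid = [100, 400, 1600, 6400]
        frame = asynchronous_scaling_decay(rule, grid, neuron)
        v = frame["var_mV2"].to_numpy()
        assert np.all(np.diff(v) < 0)

    def test_one_over_K_halves_variance_asymptotically(self, neuron):
        frame = asynchronous_scaling_decay("1/K", [3200, 6400, 12800], neuron)
        v = frame["var_mV2"].to_numpy()
        assert v[1] / v[0] == pytest.approx(0.5, rel=0.02)
        assert v[2] / v[1] == pytest.approx(0.5, rel=0.02)

    def test_synchronous_classical_scaling_keeps_variance(self, neuron):
        """With rho_e > 0 and we = Omega/Ke the variance converges to the
        nonzero scaling-limit value instead of vanishing."""
        limit = scaling_limit_moments(ScalingLimitSpec(1.0, 0.03, 10.0), neuron).variance
        model = joint_jump_model_independent(
            PoolSpec(K=20000, r=10.0, w=1.0 / 20000, rho=0.03), PoolSpec(K=0, r=0.0, w=0.0)
        )
        assert stationary_moments(model, neuron).variance == pytest.approx(limit, rel=0.01)
        assert limit > 1.0


class TestRelevanceThreshold:
    def test_weak_correlation_criterion(self):
        assert relevance_threshold(0.01) == pytest.approx(100.0)
        assert math.isinf(relevance_threshold(0.0))
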