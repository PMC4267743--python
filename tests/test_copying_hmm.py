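import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import recombtest as rt
from recombtest.copying_hmm import (
    EMPTY,
    ModelParams,
    TransitionContext,
    conversion_transition,
    crossover_transition,
    emission_prob,
    estimate_theta,
    initial_state_probs,
)

from _oracles import enumerate_log_prob, enumerate_log_prob_crossover_only
from conftest import random_instance

PARAMS = ModelParams(rho=1.0, gamma=2.0, lam=0.5, theta_hat=0.5)


class TestEstimateTheta:
    def test_small_samples(self):
        assert estimate_theta(2) == 1.0
        assert estimate_theta(3) == pytest.approx(2.0 / 3.0)

    def test_harmonic_sum(self):
        expected = 1.0 / sum(1.0 / i for i in range(1, 20))
        assert estimate_theta(20) == pytest.approx(expected)
        assert estimate_theta(20) == pytest.approx(0.28187, abs=1e-5)

    def test_requires_two_haplotypes(self):
        with pytest.raises(ValueError):
            estimate_theta(1)


class TestTransitions:
    def test_crossover_frozen_inside_tract(self):
        ctx = TransitionContext(k=3, d=1.0)
        assert crossover_transition(ctx, PARAMS, 2, 2, g_next=1) == 1.0
        assert crossover_transition(ctx, PARAMS, 2, 3, g_next=1) == 0.0

    def test_crossover_no_recombination_limit(self):
        p0 = ModelParams(rho=0.0, gamma=0.0, lam=0.0, theta_hat=0.5)
        ctx = TransitionContext(k=4, d=2.0)
        assert crossover_transition(ctx, p0, 1, 1, EMPTY) == 1.0
        assert crossover_transition(ctx, p0, 1, 2, EMPTY) == 0.0

    def test_crossover_poisson_jump(self):
        ctx = TransitionContext(k=2, d=0.5)
        p = ModelParams(rho=1.0, gamma=0.0, lam=0.0, theta_hat=0.5)
        stay = math.exp(-0.25) + (1 - math.exp(-0.25)) / 2
        assert crossover_transition(ctx, p, 1, 1, EMPTY) == pytest.approx(stay)
        assert crossover_transition(ctx, p, 1, 2, EMPTY) == pytest.approx(1 - stay)

    def test_conversion_inert_without_gamma(self):
        p0 = ModelParams(rho=1.0, gamma=0.0, lam=0.0, theta_hat=0.5)
        ctx = TransitionContext(k=2, d=1.0)
        assert conversion_transition(ctx, p0, EMPTY, EMPTY) == 1.0
        assert conversion_transition(ctx, p0, EMPTY, 1) == 0.0

    def test_conversion_zero_distance_is_identity(self):
        ctx = TransitionContext(k=3, d=0.0)
        assert conversion_transition(ctx, PARAMS, EMPTY, EMPTY) == 1.0
        assert conversion_transition(ctx, PARAMS, 2, 2) == 1.0
        assert conversion_transition(ctx, PARAMS, 2, EMPTY) == 0.0

    def test_tract_end_probability(self):
        # ongoing tract ends, no renewal: exp(-gamma d/k) * (1 - exp(-d/lam))
        ctx = TransitionContext(k=2, d=0.25)
        p = ModelParams(rho=0.0, gamma=2.0, lam=0.5, theta_hat=0.5)
        expected = math.exp(-0.25) * (1 - math.exp(-0.5))
        assert conversion_transition(ctx, p, 1, EMPTY) == pytest.approx(expected)
        assert expected == pytest.approx(0.30643, abs=1e-5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        k=st.integers(min_value=1, max_value=25),
        d=st.floats(min_value=0.0, max_value=20.0),
        rho=st.floats(min_value=0.0, max_value=50.0),
        gamma=st.floats(min_value=0.0, max_value=50.0),
        lam=st.floats(min_value=0.01, max_value=10.0),
    )
    def test_kernels_are_row_stochastic(self, k, d, rho, gamma, lam):
        params = ModelParams(rho=rho, gamma=gamma, lam=lam, theta_hat=0.5)
        ctx = TransitionContext(k=k, d=d)
        g_states = [EMPTY] + list(range(1, k + 1))
        for from_g in g_states:
            row = sum(conversion_transition(ctx, params, from_g, g) for g in g_states)
            assert row == pytest.approx(1.0, abs=1e-12)
        for g_next in (EMPTY, 1):
            for from_x in range(1, k + 1):
                row = sum(
                    crossover_transition(ctx, params, from_x, x, g_next)
                    for x in range(1, k + 1)
                )
                assert row == pytest.approx(1.0, abs=1e-12)


class TestInitialDistribution:
    def test_gamma_zero_puts_all_mass_outside_tracts(self):
        p0 = ModelParams(rho=1.0, gamma=0.0, lam=0.0, theta_hat=0.5)
        init = initial_state_probs(4, p0)
        np.testing.assert_allclose(init[:, 0], 0.25)
        assert init[:, 1:].sum() == 0.0

    def test_normalised_for_any_params(self):
        for k in (1, 2, 7):
            init = initial_state_probs(k, PARAMS)
            assert init.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stationary_tract_occupancy(self):
        p = ModelParams(rho=0.0, gamma=1.0, lam=1.0, theta_hat=0.5)
        init = initial_state_probs(1, p)
        assert init[0, 0] == pytest.approx(0.5)


class TestEmission:
    def test_match_and_mismatch_sum_to_one(self):
        for k, th in [(1, 1.0), (5, 0.3), (19, 0.28)]:
            m = emission_prob(1, 1, k, th)
            mm = emission_prob(1, 0, k, th)
            assert m + mm == pytest.approx(1.0, abs=1e-14)

    def test_plug_in_value(self):
        assert emission_prob(0, 0, 1, 1.0) == pytest.approx(0.75)
        assert emission_prob(0, 1, 1, 1.0) == pytest.approx(0.25)

    def test_perfect_copying_limit(self):
        assert emission_prob(1, 1, 3, 1e-12) == pytest.approx(1.0)
        assert emission_prob(1, 0, 3, 1e-12) == pytest.approx(0.0, abs=1e-12)


class TestForwardAlgorithm:
    def test_single_site_single_donor(self, warm_kernels):
        t = np.array([1], dtype=np.int8)
        panel = np.array([[1]], dtype=np.int8)
        pos = np.array([3.0])
        p = ModelParams(rho=1.0, gamma=1.0, lam=1.0, theta_hat=1.0)
        assert rt.conditional_log_prob(t, panel, pos, p) == pytest.approx(
            math.log(0.75)
        )

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_exhaustive_path_enumeration(self, warm_kernels, trial):
        rng = np.random.default_rng(500 + trial)
        target, panel, pos, params = random_instance(rng)
        got = rt.conditional_log_prob(target, panel, pos, params)
        want = enumerate_log_prob(target, panel, pos, params)
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("trial", range(8))
    def test_crossover_only_matches_enumeration(self, warm_kernels, trial):
        rng = np.random.default_rng(900 + trial)
        target, panel, pos, _ = random_instance(rng)
        rho = float(rng.uniform(0, 4))
        got = rt.conditional_log_prob_crossover_only(target, panel, pos, rho, 0.4)
        want = enumerate_log_prob_crossover_only(target, panel, pos, rho, 0.4)
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("trial", range(50))
    def test_gamma_zero_reduces_to_crossover_only(self, warm_kernels, trial):
        rng = np.random.default_rng(1300 + trial)
        k = int(rng.integers(1, 8))
        S = int(rng.integers(1, 30))
        panel = rng.integers(0, 2, (k, S)).astype(np.int8)
        target = rng.integers(0, 2, S).astype(np.int8)
        pos = np.sort(rng.uniform(0, 20, S))
        rho = float(rng.uniform(0, 4))
        p0 = ModelParams(rho=rho, gamma=0.0, lam=0.0, theta_hat=0.4)
        full = rt.conditional_log_prob(target, panel, pos, p0)
        xo = rt.conditional_log_prob_crossover_only(target, panel, pos, rho, 0.4)
        assert full == pytest.approx(xo, rel=1e-10)

    def test_invariant_to_panel_ordering(self, warm_kernels, rng):
        k, S = 5, 15
        panel = rng.integers(0, 2, (k, S)).astype(np.int8)
        target = rng.integers(0, 2, S).astype(np.int8)
        pos = np.sort(rng.uniform(0, 20, S))
        base = rt.conditional_log_prob(target, panel, pos, PARAMS)
        for _ in range(5):
            perm = rng.permutation(k)
            assert rt.conditional_log_prob(
                target, panel[perm], pos, PARAMS
            ) == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize("trial", range(25))
    def test_identical_panel_copy_never_hurts(self, warm_kernels, trial):
        # a perfect donor can only raise the copying probability
        rng = np.random.default_rng(1700 + trial)
        target, panel, pos, params = random_instance(rng, k_max=5, S_max=10)
        lo = rt.conditional_log_prob(target, panel, pos, params)
        hi = rt.conditional_log_prob(target, np.vstack([panel, target]), pos, params)
        assert hi >= lo - 1e-12

    def test_rejects_empty_site_list(self):
        with pytest.raises(ValueError):
            rt.conditional_log_prob(
                np.zeros(0, dtype=np.int8),
                np.zeros((1, 0), dtype=np.int8),
                np.zeros(0),
                PARAMS,
            )

    def test_rejects_nonfinite_params(self):
        with pytest.raises(ValueError):
            ModelParams(rho=float("nan"), gamma=0.0, lam=0.0, theta_hat=0.5)
        with pytest.raises(ValueError):
            ModelParams(rho=1.0, gamma=1.0, lam=0.0, theta_hat=0.5)
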