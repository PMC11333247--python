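"""Evolution, stationary distributions and chain diagnostics."""

import numpy as np
import pytest

from epirisk.errors import InputDomainError
from epirisk.markov import (
    StateDistribution,
    evolve,
    is_regular,
    simulate_chain,
    stationary_eigenvector,
    steady_state,
)
from epirisk.transition import build_stm

SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


class TestStateDistribution:
    def test_invalid_distributions_rejected(self):
        with pytest.raises(InputDomainError, match="sum"):
            StateDistribution((0.5, 0.6))
        with pytest.raises(InputDomainError, match="negative"):
            StateDistribution((1.2, -0.2))

    def test_one_hot_and_uniform_constructors(self):
        assert StateDistribution.one_hot(4, 2).probs == (0.0, 1.0, 0.0, 0.0)
        assert StateDistribution.uniform(4).probs == (0.25,) * 4


class TestEvolve:
    def test_identity_stm_fixes_any_distribution(self):
        d = StateDistribution((0.1, 0.2, 0.3, 0.4))
        assert evolve(d, np.eye(4), k=5).probs == pytest.approx(d.probs)

    def test_zero_steps_returns_input(self, matrix, stages):
        d = StateDistribution.uniform(4)
        tm = build_stm(stages["t0"], matrix)
        assert evolve(d, tm, k=0).probs == pytest.approx(d.probs)

    def test_one_hot_single_step_reads_stm_row(self, matrix, stages):
        tm = build_stm(stages["t1"], matrix)
        d = evolve(StateDistribution.one_hot(4, 1), tm, k=1)
        assert np.allclose(d.probs, tm.stm[0])

    def test_uniform_fixed_point_of_doubly_stochastic(self):
        m = np.full((4, 4), 0.25)
        d = evolve(StateDistribution.uniform(4), m, k=1)
        assert np.allclose(d.probs, 0.25)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputDomainError, match="states"):
            evolve(StateDistribution.uniform(3), np.eye(4), k=1)

    def test_negative_steps_rejected(self):
        with pytest.raises(InputDomainError, match=">= 0"):
            evolve(StateDistribution.uniform(4), np.eye(4), k=-1)


class TestSteadyState:
    def test_published_stable_states(self, matrix, stages, goldens):
        for sid, stage in stages.items():
            result = steady_state(build_stm(stage, matrix))
            assert result.converged and result.regular
            assert result.distribution.rounded(3) == tuple(
                goldens["stable_state"][sid]
            ), sid

    def test_fixed_point_residual(self, matrix, stages):
        for stage in stages.values():
            tm = build_stm(stage, matrix)
            r = steady_state(tm)
            assert r.residual <= 1e-10
            assert np.abs(r.distribution.array @ tm.stm - r.distribution.array).sum() <= 1e-10

    def test_initial_independence_for_regular_chain(self, matrix, stages):
        tm = build_stm(stages["t2"], matrix)
        rng = np.random.default_rng(2024)
        baseline = steady_state(tm).distribution.array
        for _ in range(10):
            p = rng.dirichlet(np.ones(4))
            r = steady_state(tm, initial=StateDistribution(tuple(p)))
            assert np.abs(r.distribution.array - baseline).sum() < 1e-9

    def test_one_hot_initials_match_published_protocol(self, matrix, stages):
        # the published runs start from one-hot distributions; the limit agrees
        for start, sid in zip((1, 2, 3), ("t0", "t1", "t2")):
            tm = build_stm(stages[sid], matrix)
            r = steady_state(tm, initial=StateDistribution.one_hot(4, start))
            assert np.abs(
                r.distribution.array - steady_state(tm).distribution.array
            ).sum() < 1e-9

    def test_eigenvector_cross_check(self, matrix, stages):
        for stage in stages.values():
            tm = build_stm(stage, matrix)
            pi_power = steady_state(tm).distribution.array
            pi_eig = stationary_eigenvector(tm)
            assert np.abs(pi_power - pi_eig).sum() < 1e-8

    def test_periodic_swap_chain_from_uniform(self):
        r = steady_state(SWAP)
        assert np.allclose(r.distribution.probs, 0.5)
        assert not r.regular

    def test_periodic_oscillation_resolves_to_cesaro_average(self):
        r = steady_state(SWAP, initial=StateDistribution((1.0, 0.0)))
        assert not r.regular
        assert not r.converged
        assert np.allclose(r.distribution.probs, 0.5)

    def test_nonconvergence_reported_not_raised(self, matrix, stages):
        tm = build_stm(stages["t0"], matrix)
        r = steady_state(tm, tol=1e-16, max_iter=3)
        assert not r.converged
        assert r.iterations == 3


class TestRegularity:
    def test_fixture_stms_are_regular(self, matrix, stages):
        for stage in stages.values():
            regular, diag = is_regular(build_stm(stage, matrix))
            assert regular and diag["rows_converged"]

    def test_identity_not_regular(self):
        regular, _ = is_regular(np.eye(3))
        assert not regular

    def test_swap_not_regular(self):
        regular, _ = is_regular(SWAP)
        assert not regular


class TestSimulateChain:
    def test_absorbing_identity_occupancy(self):
        occ = simulate_chain(np.eye(4), 100, initial_state=2, seed=1)
        assert occ.tolist() == [0, 1, 0, 0]

    def test_determinism_per_seed(self, matrix, stages):
        tm = build_stm(stages["t0"], matrix)
        a = simulate_chain(tm, 5000, seed=42)
        b = simulate_chain(tm, 5000, seed=42)
        assert np.array_equal(a, b)
        c = simulate_chain(tm, 5000, seed=43)
        assert not np.array_equal(a, c)

    def test_occupancy_approaches_stationary(self, matrix, stages):
        tm = build_stm(stages["t0"], matrix)
        pi = steady_state(tm).distribution.array
        occ = simulate_chain(tm, 200_000, initial_state=1, seed=7)
        assert np.max(np.abs(occ - pi)) < 0.01

    def test_invalid_inputs_rejected(self, matrix, stages):
        tm = build_stm(stages["t0"], matrix)
        with pytest.raises(InputDomainError, match="n_steps"):
            simulate_chain(tm, 0)
        with pytest.raises(InputDomainError, match="initial_state"):
            simulate_chain(tm, 10, initial_state=9)
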