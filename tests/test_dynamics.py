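"""Tests of initialisation, the two per-step operations, full runs and the
fast-engine/reference-engine agreement."""

import numpy as np
import pytest

from spingroups import (FREE, SimConfig, SpinPopulation, attempt_breaking,
                        attempt_formation, breaking_probability,
                        formation_probability, init_population, run)


class TestInitPopulation:
    def test_deterministic_under_seed(self):
        a = init_population(4, 3, seed=11)
        b = init_population(4, 3, seed=11)
        np.testing.assert_array_equal(a.spins, b.spins)
        assert np.all(a.membership == FREE)

    def test_entries_are_spins_and_balanced(self):
        pop = init_population(1000, 10, seed=2)
        assert set(np.unique(pop.spins)) == {-1, 1}
        # binomial bound: column means within 4/sqrt(N) of zero
        assert np.all(np.abs(pop.spins.mean(axis=0)) < 4 / np.sqrt(1000))

    def test_minimal_population(self):
        pop = init_population(2, 1, seed=0)
        assert pop.spins.shape == (2, 1)

    @pytest.mark.parametrize("n,L", [(1, 3), (2, 0)])
    def test_invalid_dimensions(self, n, L):
        with pytest.raises(ValueError):
            init_population(n, L, seed=0)


class TestAttemptFormation:
    def test_no_op_when_too_few_free(self, homogeneous_pop, small_config):
        homogeneous_pop.membership[:] = 0  # pretend everyone is grouped
        rng = np.random.default_rng(0)
        assert attempt_formation(homogeneous_pop, small_config, rng) is None

    def test_forced_formation_in_homogeneous_population(
            self, homogeneous_pop, small_config, scripted_rng):
        """With pi_i = -1 and a homogeneous population, the candidate group
        has payoff 1 and forms whenever u < 1/(1+e^-4) ~ 0.982."""
        cfg = small_config.with_(pi_individual=-1.0)
        rng = scripted_rng([0.97])
        group = attempt_formation(homogeneous_pop, cfg, rng, step=5)
        assert group is not None
        assert group.payoff == 1.0
        assert group.birth_step == 5
        members = np.array(group.members)
        assert np.all(homogeneous_pop.membership[members] != FREE)
        homogeneous_pop.validate()

    def test_rejection_leaves_state_untouched(
            self, homogeneous_pop, small_config, scripted_rng):
        cfg = small_config.with_(pi_individual=-1.0)
        rng = scripted_rng([0.99])  # above W = 0.982 -> rejected
        assert attempt_formation(homogeneous_pop, cfg, rng) is None
        assert homogeneous_pop.n_free == 20

    def test_formation_suppressed_at_small_noise(
            self, homogeneous_pop, scripted_rng):
        """pi_i = +1 with pi_g < 1 and K -> 0: acceptance probability
        vanishes, so even u barely above zero is rejected."""
        pop = SpinPopulation(
            spins=np.array([[1, 1, 1], [-1, 1, 1]] * 3, dtype=np.int8),
            membership=np.full(6, FREE))
        cfg = SimConfig(n_agents=6, group_size=6, vec_len=3,
                        pi_individual=1.0, noise=1e-3, horizon=10)
        assert attempt_formation(pop, cfg, scripted_rng([1e-12])) is None


class TestAttemptBreaking:
    def test_no_op_without_groups(self, homogeneous_pop, small_config):
        rng = np.random.default_rng(0)
        assert attempt_breaking(homogeneous_pop, small_config, rng) is None

    def test_break_reverts_members_atomically(
            self, homogeneous_pop, small_config, scripted_rng):
        cfg = small_config.with_(pi_individual=1.0)
        attempt_formation(homogeneous_pop, cfg.with_(pi_individual=-1.0),
                          scripted_rng([0.0]), step=0)
        # payoff 1, pi_i = +1: break probability 1/(1+e^0) = 0.5
        broken = attempt_breaking(homogeneous_pop, cfg, scripted_rng([0.49]),
                                  step=3)
        assert broken is not None
        _, grp = broken
        assert grp.payoff == 1.0
        assert homogeneous_pop.n_free == 20
        homogeneous_pop.validate()

    def test_newborn_group_not_eligible_same_step(
            self, homogeneous_pop, small_config, scripted_rng):
        cfg = small_config.with_(pi_individual=-1.0)
        attempt_formation(homogeneous_pop, cfg, scripted_rng([0.0]), step=4)
        # u=0 would certainly break it, but the step-4 newborn is excluded
        assert attempt_breaking(homogeneous_pop, cfg, scripted_rng([0.0]),
                                step=4) is None
        assert attempt_breaking(homogeneous_pop, cfg, scripted_rng([0.0]),
                                step=5) is not None


class TestRun:
    def test_zero_horizon(self):
        cfg = SimConfig(n_agents=10, group_size=2, vec_len=2, horizon=0,
                        window=1)
        traj = run(cfg)
        assert traj.steps == 0
        assert traj.final.n_groups == 0

    @pytest.mark.parametrize("engine", ["fast", "reference"])
    def test_bit_identical_under_same_seed(self, engine):
        cfg = SimConfig(n_agents=30, group_size=3, vec_len=3, horizon=500,
                        pi_individual=0.1, seed=123)
        a, b = run(cfg, engine=engine), run(cfg, engine=engine)
        np.testing.assert_array_equal(a.group_count, b.group_count)
        np.testing.assert_array_equal(a.formation_steps, b.formation_steps)
        np.testing.assert_array_equal(a.breaking_steps, b.breaking_steps)
        np.testing.assert_array_equal(a.final.membership, b.final.membership)

    @pytest.mark.parametrize("engine", ["fast", "reference"])
    def test_structural_invariants(self, engine):
        """Partition invariant at the end, per-step group-count increments
        consistent with the event logs."""
        cfg = SimConfig(n_agents=40, group_size=4, vec_len=3, horizon=800,
                        pi_individual=0.2, seed=9)
        traj = run(cfg, engine=engine)
        traj.final.validate()
        # reconstruct the count series from the event logs
        delta = np.zeros(cfg.horizon, dtype=int)
        np.add.at(delta, traj.formation_steps, 1)
        np.add.at(delta, traj.breaking_steps, -1)
        np.testing.assert_array_equal(np.cumsum(delta), traj.group_count)
        assert np.all(np.abs(np.diff(traj.group_count)) <= 1)
        # breaking payoffs must all have been formed at some point
        assert set(np.round(traj.breaking_payoffs, 12)) <= set(
            np.round(traj.formation_payoffs, 12))

    def test_engines_agree_statistically(self):
        """Fast and reference engines share semantics: their equilibrium
        densities agree within replicate noise."""
        def mean_density(engine, seeds):
            vals = []
            for s in seeds:
                cfg = SimConfig(n_agents=60, group_size=2, vec_len=3,
                                pi_individual=0.0, horizon=3000, seed=s)
                vals.append(run(cfg, engine=engine).mean_density())
            return np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(seeds))

        m_fast, se_fast = mean_density("fast", range(6))
        m_ref, se_ref = mean_density("reference", range(6))
        assert abs(m_fast - m_ref) < 4 * np.hypot(se_fast, se_ref) + 0.02

    def test_deep_phase_limits(self):
        """pi_i = -1 drives the population into near-full grouping;
        pi_i = +1 keeps it nearly all free."""
        lo = SimConfig(n_agents=100, group_size=2, vec_len=3,
                       pi_individual=-1.0, horizon=1000, seed=21)
        hi = lo.with_(pi_individual=1.0)
        assert run(lo).mean_density(burn_in=500) > 0.9
        assert run(hi).mean_density(burn_in=500) < 0.1

    def test_unknown_engine(self):
        with pytest.raises(ValueError):
            run(SimConfig(n_agents=10, horizon=10, window=5), engine="nope")


class TestTwoStateMarkovOracle:
    def test_pair_occupancy_matches_stationary_distribution(self):
        """For N=2, G=2 and a homogeneous pair (payoff 1), the dynamics is
        a two-state chain: form with W(pi_i, 1, K) from the free state,
        break with 1-W from the grouped state.  The long-run fraction of
        time grouped must match the chain's stationary probability."""
        pi_i, K = 0.3, 0.5
        spins = np.tile(np.array([1, -1, 1], dtype=np.int8), (2, 1))
        pop = SpinPopulation(spins=spins, membership=np.full(2, FREE))
        cfg = SimConfig(n_agents=2, group_size=2, vec_len=3,
                        pi_individual=pi_i, noise=K, horizon=10, window=1)
        rng = np.random.default_rng(77)
        steps = 100_000
        grouped = 0
        for t in range(steps):
            attempt_formation(pop, cfg, rng, step=t)
            attempt_breaking(pop, cfg, rng, step=t)
            grouped += pop.n_groups
        occupancy = grouped / steps

        p_form = formation_probability(pi_i, 1.0, K)
        p_break = breaking_probability(pi_i, 1.0, K)
        P = np.array([[1 - p_form, p_form], [p_break, 1 - p_break]])
        evals, evecs = np.linalg.eig(P.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat /= stat.sum()
        # MC standard error for a 2-state chain of this length is ~0.004
        assert occupancy == pytest.approx(stat[1], abs=0.015)
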