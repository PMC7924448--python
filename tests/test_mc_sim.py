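"""Lennard-Jones energies, Metropolis MC, replica exchange, task-flow equivalence."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from spectaskflow import Runtime, UsageError, payload_equal
from spectaskflow import mc_sim as mc
from spectaskflow.mc_sim import EnergyError, MCConfig, REMCConfig


def brute_force_total(positions_list):
    """Oracle: direct double loop over every particle pair in the system."""
    flat = np.vstack(positions_list)
    total = 0.0
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            r2 = float(np.sum((flat[i] - flat[j]) ** 2))
            inv6 = 1.0 / r2**3
            total += 4.0 * (inv6**2 - inv6)
    return total


def toy_config(**kw):
    base = dict(num_domains=2, particles_per_domain=20, temperature=2.0,
                num_loops=3, spec_depth=3, seed=7)
    base.update(kw)
    return MCConfig(**base)


class TestEnergy:
    def test_two_particles_at_lj_minimum(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[2 ** (1 / 6), 0.0, 0.0]])
        e = mc.compute_energy([a, b])
        assert e[0, 1] == pytest.approx(-1.0)
        assert e[0, 1] == e[1, 0]

    def test_single_particle_system_has_zero_energy(self):
        e = mc.compute_energy([np.array([[1.0, 2.0, 3.0]])])
        assert mc.total_energy(e) == 0.0

    def test_total_matches_brute_force_pair_loop(self, rng):
        domains = [rng.uniform(0, 6, size=(n, 3)) for n in (4, 6, 5)]
        e = mc.compute_energy(domains)
        assert mc.total_energy(e) == pytest.approx(brute_force_total(domains), rel=1e-12)

    def test_coincident_particles_raise_with_location(self):
        a = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        b = np.array([[1.0, 0.0, 0.0]])
        with pytest.raises(EnergyError, match=r"\(1, 0\)"):
            mc.compute_energy([a, b])

    def test_empty_domain_list_rejected(self):
        with pytest.raises(UsageError):
            mc.compute_energy([])


class TestUpdateEnergy:
    def test_incremental_equals_full_recompute(self, rng):
        domains = [rng.uniform(0, 8, size=(10, 3)) for _ in range(4)]
        energy = mc.compute_energy(domains)
        new_pos = rng.uniform(0, 8, size=(10, 3))
        updated = mc.update_energy(energy, new_pos, 2, domains)
        moved = list(domains)
        moved[2] = new_pos
        full = mc.compute_energy(moved)
        assert np.allclose(updated, full, rtol=1e-9, atol=0)

    def test_null_move_leaves_matrix_unchanged(self, rng):
        domains = [rng.uniform(0, 8, size=(6, 3)) for _ in range(3)]
        energy = mc.compute_energy(domains)
        updated = mc.update_energy(energy, domains[1], 1, domains)
        assert payload_equal(updated, energy)

    def test_exactly_one_row_column_and_diagonal_may_change(self, rng):
        d_count = 5
        domains = [rng.uniform(0, 10, size=(4, 3)) for _ in range(d_count)]
        energy = mc.compute_energy(domains)
        updated = mc.update_energy(energy, rng.uniform(0, 10, size=(4, 3)), 1, domains)
        changed = np.argwhere(updated != energy)
        assert len(changed) <= 2 * (d_count - 1) + 1
        assert all(1 in pair for pair in changed)

    def test_out_of_range_index_rejected(self, rng):
        domains = [rng.uniform(0, 8, size=(3, 3)) for _ in range(2)]
        energy = mc.compute_energy(domains)
        with pytest.raises(UsageError):
            mc.update_energy(energy, domains[0], 5, domains)


class TestMoves:
    def test_same_stream_state_gives_identical_proposal(self):
        dom = np.zeros((8, 3))
        a = mc.move_domain(1.0, dom, np.random.default_rng(3), box=5.0)
        b = mc.move_domain(1.0, dom, np.random.default_rng(3), box=5.0)
        assert payload_equal(a, b)
        assert not np.shares_memory(a, dom)

    def test_proposals_stay_inside_the_box(self):
        gen = np.random.default_rng(0)
        pos = mc.move_domain(1.0, np.zeros((500, 3)), gen, box=3.5)
        assert np.all(pos >= 0.0) and np.all(pos < 3.5)

    def test_coordinates_are_uniform_by_ks(self):
        gen = np.random.default_rng(11)
        pos = mc.move_domain(1.0, np.zeros((4000, 3)), gen, box=2.0)
        stat = kstest(pos.ravel() / 2.0, "uniform")
        assert stat.pvalue > 0.01


class TestMetropolis:
    def test_downhill_always_accepted(self):
        assert mc.metropolis_probability(-5.0, 0.0, 1.0) == 1.0
        assert mc.metropolis_probability(3.0, 3.0, 0.5) == 1.0

    def test_unit_uphill_at_unit_temperature(self):
        assert mc.metropolis_probability(1.0, 0.0, 1.0) == pytest.approx(np.exp(-1))

    def test_probability_nonincreasing_in_energy_difference(self):
        deltas = np.linspace(-2, 10, 40)
        probs = [mc.metropolis_probability(d, 0.0, 1.7) for d in deltas]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(UsageError):
            mc.metropolis_probability(1.0, 0.0, 0.0)


class TestRunMC:
    def test_seed_reproducibility(self):
        s1, st1 = mc.run_mc(toy_config())
        s2, st2 = mc.run_mc(toy_config())
        assert mc.states_equal(s1, s2)
        assert st1.accepted == st2.accepted
        assert 0.0 <= st1.accept_ratio <= 1.0

    def test_energy_bookkeeping_consistent_with_recompute(self):
        state, stats = mc.run_mc(toy_config(num_loops=5))
        fresh = mc.compute_energy(state.positions)
        assert mc.total_energy(fresh) == pytest.approx(state.total_energy(), rel=1e-6)
        assert stats.energy_trajectory[-1] == pytest.approx(state.total_energy())

    def test_high_temperature_accepts_almost_everything(self):
        _, stats = mc.run_mc(toy_config(particles_per_domain=5, temperature=1e9,
                                        num_loops=5))
        assert stats.accept_ratio >= 0.9

    def test_frozen_system_rejects_every_uphill_proposal(self):
        """Start from particles parked at pairwise LJ minima: any random
        redistribution is uphill and a vanishing temperature rejects it."""
        r0 = 2 ** (1 / 6)
        a = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        b = a + np.array([r0, 0.0, 0.0])
        positions = [a.copy(), b.copy()]
        energy = mc.compute_energy(positions)
        gen = np.random.default_rng(5)
        for _ in range(20):
            accepted = mc.attempt_move(energy, positions, 0, gen, 1e-9, box=12.0)
            assert not accepted
        assert payload_equal(positions[0], a)

    def test_all_reject_mode_freezes_the_state(self):
        cfg = toy_config()
        init = mc.init_system(cfg)
        state, stats = mc.run_mc(cfg, all_reject=True)
        assert stats.accepted == 0
        assert mc.states_equal(state, init)


class TestMCTaskflow:
    @pytest.mark.parametrize(
        "engine,workers",
        [("sequential", 1), ("parallel", 1), ("parallel", 4), ("simulated", 8)],
    )
    def test_flow_matches_sequential_reference_bitwise(self, engine, workers):
        ref_state, ref_stats = mc.run_mc(toy_config())
        flow = mc.build_mc_taskflow(toy_config())
        state, stats, _ = flow.run(engine, workers)
        assert mc.states_equal(state, ref_state)
        assert stats.accepted == ref_stats.accepted

    @pytest.mark.parametrize("depth", [1, 2, 3, 5, 6])
    def test_any_spec_depth_preserves_the_result(self, depth):
        cfg = toy_config(spec_depth=depth)
        ref_state, _ = mc.run_mc(cfg)
        state, _, _ = mc.build_mc_taskflow(cfg).run("parallel", 4)
        assert mc.states_equal(state, ref_state)

    def test_depth_one_degenerates_to_certain_chain(self):
        flow = mc.build_mc_taskflow(toy_config(spec_depth=1))
        assert all(not n.uncertain for n in flow.runtime.graph.nodes)
        assert not flow.runtime.groups

    def test_sweep_restart_pattern_marks_every_depth_th_step_certain(self):
        cfg = toy_config(num_loops=2, spec_depth=2)
        flow = mc.build_mc_taskflow(cfg)
        flags = [h.node.uncertain for h in flow.step_handles]
        assert flags == [True, False, True, False]

    def test_all_reject_critical_path_is_one_task_per_sweep(self):
        """With speculation restarting each sweep and enough workers, an
        all-reject run needs only one move-task duration per sweep."""
        cfg = MCConfig(num_domains=5, particles_per_domain=4, num_loops=3,
                       spec_depth=5, seed=1)
        flow = mc.build_mc_taskflow(cfg, all_reject=True)
        _, _, trace = flow.run("simulated", 8)
        assert trace.makespan == cfg.num_loops  # copies/selects cost zero here
        baseline = mc.build_mc_taskflow(cfg, runtime=Runtime(speculation=False),
                                        all_reject=True)
        _, _, base_trace = baseline.run("simulated", 8)
        assert base_trace.makespan == cfg.num_loops * cfg.num_domains


def remc_toy(**kw):
    base = dict(num_replicas=3, num_domains=2, particles_per_domain=10,
                num_loops=6, exchange_period=3, spec_depth=2, seed=3,
                base_temperature=2.0)
    base.update(kw)
    return REMCConfig(**base)


class TestREMC:
    def test_exchange_list_alternates_parity(self):
        # 5 replicas, 1-based pairs (1,2),(3,4) then (2,3),(4,5)
        assert mc.exchange_list(1, 5) == [(0, 1), (2, 3)]
        assert mc.exchange_list(2, 5) == [(1, 2), (3, 4)]
        assert mc.exchange_list(3, 5) == [(0, 1), (2, 3)]

    def test_equal_energies_always_swap(self):
        assert mc._exchange_decision(5.0, 5.0, 1.0, u=1.0)
        assert mc._exchange_decision(5.0, 5.0, 1e-9, u=0.999999)

    def test_exchange_preserves_the_energy_multiset(self):
        """A single exchange phase at the very end only permutes the replica
        configurations relative to a no-exchange run."""
        with_x, _ = mc.run_remc(remc_toy(num_loops=3, exchange_period=3))
        without, _ = mc.run_remc(remc_toy(num_loops=3, exchange_period=99))
        e_with = sorted(s.total_energy() for s in with_x)
        e_without = sorted(s.total_energy() for s in without)
        assert e_with == pytest.approx(e_without, rel=1e-12)

    def test_temperature_ladder_validation(self):
        with pytest.raises(UsageError):
            REMCConfig(num_replicas=1)
        with pytest.raises(UsageError):
            REMCConfig(num_replicas=2, temperatures=(1.0,))
        with pytest.raises(UsageError):
            REMCConfig(num_replicas=2, temperatures=(1.0, -1.0))

    def test_seed_reproducibility_and_rates(self):
        s1, st1 = mc.run_remc(remc_toy())
        s2, st2 = mc.run_remc(remc_toy())
        assert all(mc.states_equal(a, b) for a, b in zip(s1, s2))
        assert st1.exchange_attempts == st2.exchange_attempts
        assert 0.0 <= st1.exchange_rate <= 1.0


class TestREMCTaskflow:
    @pytest.mark.parametrize(
        "engine,workers", [("sequential", 1), ("parallel", 4), ("simulated", 6)]
    )
    def test_flow_matches_sequential_reference_bitwise(self, engine, workers):
        ref_states, ref_stats = mc.run_remc(remc_toy())
        flow = mc.build_remc_taskflow(remc_toy())
        states, stats, _ = flow.run(engine, workers)
        assert all(mc.states_equal(a, b) for a, b in zip(states, ref_states))
        assert stats.exchange_accepts == ref_stats.exchange_accepts

    def test_replica_sweeps_do_not_interdepend_before_exchange(self):
        flow = mc.build_remc_taskflow(remc_toy(num_loops=2, exchange_period=99))
        ids = [
            {h.node.id for h in handles} | {h.node.twin.id for h in handles if h.node.twin}
            for handles in flow.step_handles
        ]
        graph = flow.runtime.graph
        for u, v in graph.edges:
            crossing = [
                r for r, s in enumerate(ids) if u in s or v in s
            ]
            assert len(set(crossing)) <= 1


class TestXYZRoundTrip:
    def test_write_then_read_recovers_positions(self, tmp_path, rng):
        from spectaskflow import serialize

        domains = [
            mc.ParticleDomain(i, rng.uniform(0, 4, size=(5, 3))) for i in range(3)
        ]
        path = tmp_path / "sys.xyz"
        serialize.write_xyz(path, domains, comment="toy")
        back = serialize.read_xyz(path)
        assert all(payload_equal(a.positions, b.positions) for a, b in zip(domains, back))
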