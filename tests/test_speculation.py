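"""Speculative-group construction, activation propagation, registry hygiene."""

import itertools

import pytest

from spectaskflow import (
    AccessMode,
    Box,
    GroupState,
    Runtime,
    TaskRole,
    always_disabled,
    payload_equal,
    threshold_policy,
)
from spectaskflow import executor as ex
from spectaskflow import fixtures as fx
from spectaskflow import speculation as spec
from spectaskflow.dag_core import InternalError

R, W, MW = AccessMode.READ, AccessMode.WRITE, AccessMode.MAYBE_WRITE


def _noop(*_a):
    return None


def _plain_result(program):
    rt = Runtime(speculation=False)
    out = program(rt)
    ex.run_sequential(rt)
    return rt, out


class TestUncertainInsertion:
    def test_first_uncertain_task_registers_one_duplicate_and_copy(self):
        rt = Runtime()
        x = rt.register_data(Box(0), name="x")
        rt.insert_task([(x, W)], _noop)
        rt.insert_task([(x, MW)], lambda _b: False, uncertain=True)
        assert len(rt.groups) == 1
        g = rt.groups[0]
        assert len(g.copy_tasks) == 1 and not g.speculative_tasks
        assert x.id in rt.registry

    def test_consumer_triggers_twin_and_select(self):
        rt = Runtime()
        x = rt.register_data(Box(0), name="x")
        rt.insert_task([(x, W)], _noop)
        rt.insert_task([(x, MW)], lambda _b: False, uncertain=True)
        rt.insert_task([(x, W)], _noop)
        g = rt.groups[1]
        assert len(g.speculative_tasks) == 1 and len(g.select_tasks) == 1
        assert g.parents == [rt.groups[0]]
        # the consumer ends the chain: its duplicate is consumed
        assert x.id not in rt.registry

    def test_uncertain_after_dead_group_restarts_without_twin(self):
        rt = Runtime(speculation_policy=always_disabled)
        x = rt.register_data(Box(0), name="x")
        rt.insert_task([(x, W)], _noop)
        u1 = rt.insert_task([(x, MW)], lambda _b: False, uncertain=True)
        rt.wait_all()  # policy kills the group at runtime
        assert rt.groups[0].state is GroupState.DISABLED
        u2 = rt.insert_task([(x, MW)], lambda _b: False, uncertain=True)
        assert u2.node.twin is None
        assert rt.groups[-1].parents == []

    def test_independent_uncertain_tasks_make_disjoint_groups(self):
        rt = Runtime()
        x, y = rt.register_data(Box(0)), rt.register_data(Box(1))
        rt.insert_task([(x, MW)], lambda _b: False, uncertain=True)
        rt.insert_task([(y, MW)], lambda _b: False, uncertain=True)
        assert len(rt.groups) == 2
        assert all(not g.parents for g in rt.groups)
        # no dependency crosses between the two groups' task sets
        sets = [{t.id for t in g.all_tasks()} for g in rt.groups]
        for u, v in rt.graph.edges:
            assert not ((u in sets[0]) ^ (v in sets[0]))


class TestGuardedNormalInsertion:
    def test_task_after_select_is_plain(self):
        rt = Runtime()
        x = rt.register_data(Box(0), name="x")
        rt.insert_task([(x, W)], _noop)
        rt.insert_task([(x, MW)], lambda _b: False, uncertain=True)
        rt.insert_task([(x, W)], _noop)  # consumer: twin + select
        d = rt.insert_task([(x, W)], _noop)  # after the select: plain
        assert d.node.group is None and d.node.twin is None

    def test_consumer_writing_foreign_datum_needs_extra_copy_and_select(self):
        rt = Runtime()
        fx.speculation_consumer_program(W)(rt)
        g = rt.groups[-1]
        # duplicate of x existed; y written by C gets its own copy + select
        assert len(g.copy_tasks) == 1
        assert len(g.select_tasks) == 2

    def test_consumer_reading_foreign_datum_shares_it_with_twin(self):
        rt = Runtime()
        x, y = fx.speculation_consumer_program(R)(rt)
        g = rt.groups[-1]
        assert len(g.copy_tasks) == 0 and len(g.select_tasks) == 1
        twin = g.speculative_tasks[0]
        assert any(h is y for h, _ in twin.accesses)  # same datum, concurrently


class TestSelectSemantics:
    def test_enabled_select_commits_the_duplicate(self):
        rt = Runtime()
        x, _ = fx.four_task_chain_program(False)(rt)  # B does not write
        ex.run_sequential(rt)
        g = rt.groups[1]
        assert g.select_tasks[0].ran
        assert not g.original_tasks[0].ran  # C's body never invoked

    def test_disabled_select_leaves_original_untouched(self):
        rt = Runtime()
        x, _ = fx.four_task_chain_program(True)(rt)  # B writes
        ex.run_sequential(rt)
        g = rt.groups[1]
        assert not g.select_tasks[0].ran
        assert g.original_tasks[0].ran

    @pytest.mark.parametrize("b_writes", [False, True])
    def test_select_output_feeds_downstream_task(self, b_writes):
        program = fx.four_task_chain_program(b_writes)
        _, (x_ref, _t) = _plain_result(program)
        rt = Runtime()
        x, _tasks = program(rt)
        ex.run_sequential(rt)
        assert payload_equal(x.payload, x_ref.payload)


class TestActivationPropagation:
    def test_no_write_then_twin_writes(self):
        """Chain A, B?, C?, D: B reports no-write so C is disabled and its
        select commits; C' then writes, so D's own speculation fails: D runs
        and D-level select is disabled."""
        rt = Runtime()
        x = rt.register_data(Box(1), name="x")
        rt.insert_task([(x, W)], lambda b: b.__setattr__("value", 3), name="A")
        rt.insert_task([(x, MW)], fx._forced_body(False), uncertain=True, name="B")
        rt.insert_task([(x, MW)], fx._forced_body(True), uncertain=True, name="C")
        rt.insert_task([(x, W)], lambda b: b.__setattr__("value", b.value + 1), name="D")
        ex.run_sequential(rt)
        g_b, g_c, g_d = rt.groups
        assert g_b.outcome is False
        assert not g_c.original_tasks[0].ran and g_c.select_tasks[0].ran
        assert g_c.speculative_tasks[0].did_write is True
        assert g_d.failed
        assert g_d.original_tasks[0].ran and not g_d.select_tasks[0].ran
        # value: A=3; B skip; C' doubles+writes (3*3+13=22); D adds 1
        ref_rt, _ = _plain_result(lambda r: _rebuild(r))
        assert x.payload.value == 23

    def test_failure_cascades_through_successor_groups(self):
        """First uncertain writes: every downstream original runs and every
        select is suppressed."""
        mask = [True, False, False]
        program = fx.uncertain_chain_program(mask)
        _, (x_ref, _t) = _plain_result(program)
        rt = Runtime()
        x, _tasks = program(rt)
        ex.run_parallel(rt, 4)
        assert payload_equal(x.payload, x_ref.payload)
        for g in rt.groups[1:]:
            assert g.failed
            assert all(not s.ran for s in g.select_tasks)
            assert all(o.ran for o in g.original_tasks)

    def test_mixed_outcomes_enable_exactly_the_valid_prefix(self):
        """No-write, no-write, write, write: the first two levels commit via
        selects, the rest fall back to originals."""
        mask = [False, False, True, True]
        program = fx.uncertain_chain_program(mask)
        _, (x_ref, _t) = _plain_result(program)
        rt = Runtime()
        x, _tasks = program(rt)
        ex.run_sequential(rt)
        assert payload_equal(x.payload, x_ref.payload)
        committed = [g.select_tasks[0].ran for g in rt.groups[1:] if g.select_tasks]
        # level 2 commits (its twin stands in for task 1), level 3 commits the
        # write of task 2's twin; groups after the first write fall back
        assert committed[0] and committed[1]
        assert not any(committed[2:])

    def test_double_completion_report_is_an_internal_error(self):
        rt = Runtime()
        x = rt.register_data(Box(0))
        th = rt.insert_task([(x, MW)], lambda _b: False, uncertain=True)
        ex.run_sequential(rt)
        with pytest.raises(InternalError):
            spec.on_uncertain_complete(rt, th.node, False)


def _rebuild(rt):
    x = rt.register_data(Box(1), name="x")
    rt.insert_task([(x, W)], lambda b: b.__setattr__("value", 3), name="A")
    rt.insert_task([(x, MW)], fx._forced_body(False), uncertain=True, name="B")
    rt.insert_task([(x, MW)], fx._forced_body(True), uncertain=True, name="C")
    rt.insert_task([(x, W)], lambda b: b.__setattr__("value", b.value + 1), name="D")
    return [x]


class TestDecisionPolicies:
    def test_always_on_enables_every_group(self):
        rt = Runtime()
        fx.uncertain_chain_program([False, False])(rt)
        ex.run_sequential(rt)
        assert all(g.state is GroupState.ENABLED for g in rt.groups)

    def test_always_off_matches_plain_makespan(self):
        program = fx.uncertain_chain_program([False, False, False])
        rt_plain = Runtime(speculation=False)
        x_plain, _ = program(rt_plain)
        t_plain = ex.run_simulated(rt_plain, 4)
        rt_off = Runtime(speculation_policy=always_disabled)
        x_off, _ = program(rt_off)
        t_off = ex.run_simulated(rt_off, 4)
        assert t_off.makespan == t_plain.makespan
        assert payload_equal(x_off.payload, x_plain.payload)

    def test_threshold_policy_declines_on_saturated_graph(self):
        rt = Runtime(speculation_policy=threshold_policy)
        pads = [rt.register_data(Box(i)) for i in range(8)]
        for p in pads:  # eight independent ready tasks saturate two workers
            rt.insert_task([(p, W)], lambda b: b.__setattr__("value", b.value + 1))
        x = rt.register_data(Box(1), name="x")
        rt.insert_task([(x, MW)], fx._forced_body(False), uncertain=True)
        rt.insert_task([(x, W)], lambda b: b.__setattr__("value", b.value * 2))
        ex.run_simulated(rt, 2)
        assert any(g.state is GroupState.DISABLED for g in rt.groups)
        assert x.payload.value == 2  # still correct via the original path


class TestRegistryHygiene:
    @pytest.mark.parametrize("seed", range(8))
    def test_at_most_one_live_duplicate_per_datum(self, seed):
        rt = Runtime()
        fx.random_program(seed, n_tasks=15, n_data=4)(rt)
        dups = [e.duplicate.id for e in rt.registry.values()]
        assert len(dups) == len(set(dups))
        for key, entry in rt.registry.items():
            assert entry.original.id == key

    def test_consecutive_chain_exposes_concurrency(self):
        """With spec depth k, twins of levels 2..k depend only on copy tasks,
        never on the running uncertain chain."""
        rt = Runtime()
        fx.uncertain_chain_program([False] * 4)(rt)
        by_id = rt.graph.nodes_by_id
        uncertain_ids = {
            n.id
            for n in rt.graph.nodes
            if n.role in (TaskRole.UNCERTAIN, TaskRole.NORMAL)
        }
        for g in rt.groups:
            for twin in g.speculative_tasks:
                preds = rt.graph.preds[twin.id]
                assert all(by_id[p].role is TaskRole.COPY for p in preds)
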